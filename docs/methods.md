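# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `ehgphase`. It is the companion to the API reference in
the module docstrings.

## Signal model and conditioning

An EHG recording enters the pipeline as a one-column plain-text amplitude
file in nanovolts with a known sampling rate. The analysis protocol
operates on 10-minute, 20 Hz series (12,000 samples) whose content lies in
the 0.2–1 Hz uterine band; raw 900 Hz exports are conditioned first:

* **Band-pass 0.2–1 Hz** — 4th-order Butterworth applied forward-backward
  (`sosfiltfilt`, odd-reflection padding). Zero-phase filtering matters
  here: the downstream statistic lives on difference *angles*, and a
  phase-distorting filter would bias it. No warm-up samples are trimmed,
  so the protocol length is preserved.
* **Decimation 900 → 20 Hz** — integer-factor (45) sample selection after
  the band-pass. Content is already limited to ≤ 1 Hz, far below the new
  Nyquist of 10 Hz, so a second anti-alias filter would only add
  distortion. Output length is `floor(N / 45)`.

## Phase Entropy

The second-order difference plot (SODP) is the scatter of
`X[n] = x[n+1] − x[n]` against `Y[n] = x[n+2] − x[n+1]`. Each point gets a
four-quadrant slope angle in the half-open range `[0, 2π)`; the plane is
split into `k` equal half-open sectors counted counterclockwise, sector
`i` accumulates the angle sum `S_θ[i]`, and

```
p(i) = S_θ[i] / Σ_j S_θ[j],
PhEn_k = −(1/log k) Σ_i p(i) log p(i).
```

Conventions and their reasons:

* **Normalization by the total angle sum.** Normalizing each `S_θ[i]` by a
  running partial sum instead does not produce a probability distribution
  (the weights neither sum to one nor bound the entropy by `log k`), and
  is inconsistent with the uniform-maximum property (PhEn = 1 exactly when
  `p(i)` is uniform). The total-sum reading is therefore canonical here;
  the running-sum variant remains available via
  `sector_profile(..., normalization="running")` for comparison.
* **Angle-weighted, not count-weighted.** Weighting sectors by their angle
  sums privileges high-angle sectors — a deliberate property of the
  statistic: a plot with all points equally spread still has PhEn < 1
  unless the *angle mass* is uniform.
* **Units and bases cancel.** `p(i)` is a ratio of angle sums, so degrees
  vs radians is immaterial; the `1/log k` factor cancels the logarithm
  base. Both facts are asserted by tests.
* **Origin points.** A point with `X = Y = 0` has no angle; such points
  are removed and counted (`n_excluded`). A fully constant series, whose
  SODP is entirely at the origin, is rejected as degenerate.
* **Boundary handling.** Angles are reduced modulo 2π with a guard that
  maps the rounding case `θ = 2π` back to 0, and sector indices are
  clipped to `[0, k−1]` so a point an ulp from the wrap-around cannot
  escape the grid.
* **k grid.** Default `k = 4, 8, ..., 36`: inside the stable range
  2 < k < 40 with k divisible by 4 so sector boundaries align with the
  quadrants. Arbitrary grids are accepted.

PhEn is exactly invariant under positive affine amplitude transforms in
exact arithmetic; in floating point the invariance holds to ~1e−12 (the
transform perturbs differences by rounding ulps, which can move a
boundary-adjacent point only with probability ~0).

## Multiscale Sample Entropy

Scale-τ coarse-graining takes non-overlapping τ-point window means
(length `floor(N/τ)`; scale 1 is the series itself). SampEn uses template
length `m = 2`, Chebyshev distance, the within-tolerance rule `d ≤ r`, and
the first `N − m` templates at both lengths, with self-matches excluded:
`SampEn = −log(A/B)`. The tolerance is `r = 0.15 × SD` of the *original*
(scale-1) series and is held fixed across scales — the standard multiscale
convention, which makes the curve invariant under affine rescaling of the
signal. When no template pairs match at either length, the value is
undefined and reported as missing (NaN, flagged, logged), never as zero.

Pair counting is O(N²) and runs through a numba-compiled kernel (a pure
numpy fallback is kept and tested against it); a 12,000-sample, 21-scale
curve takes ≈ 0.3 s.

## iAAFT surrogates and the nonlinearity decision

The null hypothesis is a stationary linear Gaussian process (possibly
under a static monotone transform). Surrogates are built by the iterative
amplitude-adjusted Fourier transform: starting from a random permutation,
alternate (a) imposing the original amplitude spectrum on the current
phases and (b) rank-remapping onto the original sorted values. The
amplitude-adjusted iterate is returned, so the surrogate's sorted values
equal the original's **bit-exactly**; the spectrum is approximate (< 1%
relative RMS error on AR(1) benchmarks).

Termination: rank-ordering stabilization (the iteration has reached its
fixed point), a plateau of the spectral discrepancy (relative improvement
below 1e−4 per iteration — in calibration experiments the plateau stop is
indistinguishable from running to the fixed point, while much cheaper on
long bursty signals), or the iteration cap (default 100).

Decision rule, exactly one-sided: with `n` surrogates, the threshold is
the `ceil(0.05 n)`-th smallest surrogate PhEn (nearest rank — the 10th of
200), and the series is flagged nonlinear at `k` when its own PhEn is
*strictly below* that threshold. Per-k decisions are reported uncorrected
across the grid. One surrogate ensemble is generated per series and
evaluated at every k (each surrogate's SODP is built once), which is both
cheaper and coherent across k. A master seed spawns independent
per-surrogate sub-seeds, so ensembles are reproducible and parallelizable.

Calibration: on linear Gaussian AR(1) controls (φ = 0.9, n = 2048) the
empirical rejection rate sits at or mildly above the nominal ≈ 5% level
(roughly 5–15% across seed batches). The slight anti-conservatism is
intrinsic to the statistic/surrogate pair on strongly autocorrelated
nulls at moderate length: the iAAFT fixed point leaves surrogates with
marginally whiter spectra than the original, which raises their Phase
Entropy and nudges the original toward the lower tail. End-point matching
and extra iterations do not remove it; it shrinks with series length.
Detections should therefore be read as "nonlinear at a level near, not
exactly at, 5%".

## Time reversal

`time_reverse` reverses the sample order. Geometrically the reversed
series' SODP is the original point set mapped `(x, y) → (−y, −x)` (a
tested invariant), so any PhEn difference between a series and its
reversal is pure time-irreversibility signal. The cohort pipeline compares
original vs reversed PhEn per stage and k with Wilcoxon signed-rank tests.

## Synthetic cohort generator

The generator emulates the *conditioned* recording the analysis consumes:
600 s at 20 Hz in nanovolts, power concentrated in 0.2–1 Hz. Each record
is a sum of

* a **baseline**: unit-variance Gaussian noise band-limited to the low end
  of the EHG band (0.2–0.45 Hz), scaled to 10 nV — the slow quiescent
  basal activity;
* **contraction bursts**: a broader-band carrier (0.34–1 Hz, the fast-wave
  range that appears during contractions) under an asymmetric rise/decay
  envelope (peak at 35% of the 45 s burst) at non-overlapping uniform
  random onsets.

Stage presets: third-trimester-like (2 bursts, 50 nV) and
parturition-like (4 bursts, 200 nV, matching the 3–4 contractions per
10 min that define active labor). Cohorts draw per-subject log-normal
multipliers (SD 0.25) for burst amplitude and baseline noise, shared
between the subject's two stages, so paired tests have genuine
within-subject signal.

Nonlinearity and irreversibility are injected at the waveform level:

* the burst carrier is skewed by a quadratic lag coupling
  `c[n] + a (c[n−1]² − 1)` with `a = envelope_asymmetry` (default 0.3),
  emulating the asymmetric depolarization/repolarization shape of
  action-potential bursts. This matters because an angle-based statistic
  is *blind* to slow positive amplitude modulation: an asymmetric envelope
  alone rescales (X, Y) jointly and leaves every SODP angle unchanged, and
  a Gaussian carrier (or any static transform of it) is time-reversible.
  The lag coupling gives the carrier genuine forward/backward asymmetry
  that both the reversal comparison and the surrogate test can see;
* optionally (default on), bursts pass through a smooth saturation
  `A tanh(x/A)` that soft-clips the largest excursions.

The spectral separation of the two components (narrowband slow baseline
vs broader fast-wave bursts) is what orders the stages: the
burst-dominated parturition-like records spread their difference angles
over more sectors (higher PhEn), while their large regular bursts are more
predictable at coarse scales (lower multiscale SampEn) — reproducing the
expected opposite orderings of the two entropies.

What the generator does **not** model: biophysical myometrial dynamics
(action-potential or cell-coupling models), electrode/motion artifacts,
maternal ECG residue, nonstationary baseline drift, or between-contraction
variability in burst morphology. Tests that pass on these synthetics
therefore validate the *statistical machinery* — not clinical claims about
real EHG.

Linear AR(1) Gaussian controls (`generate_linear_control`, default
φ = 0.9, unit innovations, 500-sample burn-in) realize the surrogate-test
null exactly and are used for type-I calibration.

## Cohort statistics

Per k (and per scale τ), the two stages are compared with a paired
two-sided test on the within-subject difference: Student's t when the
differences pass a Shapiro normality check at 0.05, Wilcoxon signed-rank
otherwise; p-values are Bonferroni-corrected over the grid
(`p_adj = min(1, p × n_grid)`). Nonlinearity proportions are compared per
k with a 2×2 chi-squared test without continuity correction (expected
counts < 5 log a warning; an empty margin reports statistic 0, p 1).
Reversal uses per-stage Wilcoxon signed-rank per k, uncorrected. Subjects
with a degenerate recording are excluded with a logged reason; all-zero
paired differences mark the test degenerate rather than crashing. The
comparison stage consumes only the tidy per-subject tables, never signal
files.

This per-k paired-testing scheme deliberately replaces a two-way
repeated-measures ANOVA with post hoc contrasts: the per-k contrasts are
what is actually interpreted, and the simplification avoids RM-ANOVA
machinery orthogonal to the entropy methods themselves.

## Problem sizes

Defaults follow the recording protocol (24 paired subjects, 12,000-sample
signals, k = 4..36, τ = 1..21, 200 surrogates, 100 iAAFT iterations,
α = 0.05). The heavier validation checks run at reduced but still
protocol-shaped sizes chosen once: type-I calibration on 100 (tests) or 50
(acceptance script) AR(1) controls of n = 2048 at 200 surrogates;
detection power on 50 parturition-like records at 50 surrogates; the
acceptance-script cohort at 50 surrogates per series. The script completes
in minutes on one CPU.

## Known limitations

* The vendor software's 0.2–1 Hz filter is unspecified; the Butterworth
  reimplementation is phase-neutral but not guaranteed amplitude-identical
  to it, so absolute PhEn values on vendor-exported data may differ
  slightly.
* SampEn at large scales on short series can be undefined (no matches);
  it is reported missing, and group means over few subjects may thin out.
* The surrogate test's empirical level is validated for the AR(1) null at
  the protocol ensemble size; small ensembles inflate it (see above), and
  strongly non-Gaussian *linear* processes are outside the validated
  range.
* The running-sum normalization variant is provided for comparison only;
  its output is not a bounded entropy.
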