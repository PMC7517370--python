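"""iAAFT surrogates, the surrogate test of nonlinearity, and time reversal.

The null hypothesis is that the series was produced by a stationary linear
Gaussian process (possibly observed through a static monotone transform).
Iterative Amplitude Adjusted Fourier Transform (iAAFT) surrogates retain
the original amplitude distribution exactly and the amplitude spectrum
approximately, while phase randomization destroys any nonlinear temporal
structure.  A series is deemed nonlinear at a given sector count k when its
Phase Entropy falls below the empirical fifth percentile of the PhEn values
of a surrogate ensemble (one-sided, lower tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSignalError, InsufficientLengthError, ParameterError
from .phase_entropy import SODP, build_sodp, phase_entropy, sector_profile
from .preprocess import Signal

__all__ = [
    "SurrogateTestResult",
    "iaaft_surrogate",
    "nonlinearity_test",
    "nonlinearity_tests",
    "time_reverse",
]

SeedLike = int | np.random.SeedSequence | np.random.Generator | None


@dataclass(frozen=True)
class SurrogateTestResult:
    """Outcome of the surrogate test at one sector count k.

    ``threshold`` is the empirical fifth percentile (nearest-rank: the
    ceil(0.05 n)-th smallest surrogate value); ``nonlinear`` is True exactly
    when ``phen_original < threshold``.
    """

    k: int
    phen_original: float
    phen_surrogates: np.ndarray
    threshold: float
    nonlinear: bool
    n_surrogates: int
    seed: int | None


_SPECTRUM_PLATEAU_RTOL = 1e-4


def _iaaft_values(
    x: np.ndarray, max_iter: int, rng: np.random.Generator
) -> np.ndarray:
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    target_norm = float(np.sqrt(np.mean(target_amp**2)))
    s = rng.permutation(x)
    prev_order = None
    prev_err = None
    for _ in range(max_iter):
        spec = np.fft.rfft(s)
        mag = np.abs(spec)
        # spectral discrepancy of the current amplitude-adjusted iterate;
        # stop once it no longer improves (it is non-increasing in practice)
        err = float(np.sqrt(np.mean((mag - target_amp) ** 2))) / target_norm
        if prev_err is not None and err > prev_err * (1.0 - _SPECTRUM_PLATEAU_RTOL):
            break
        prev_err = err
        # spectrum adjustment: impose the original amplitude spectrum,
        # keep the current phases
        mag[mag == 0.0] = 1.0
        s = np.fft.irfft(target_amp * (spec / mag), n=x.size)
        # amplitude adjustment: rank-remap onto the original values, so the
        # returned iterate preserves the amplitude distribution exactly
        order = np.argsort(s)
        s = np.empty_like(s)
        s[order] = sorted_x
        if prev_order is not None and np.array_equal(order, prev_order):
            break
        prev_order = order
    return s


def iaaft_surrogate(
    signal: Signal, max_iter: int = 100, seed: SeedLike = None
) -> Signal:
    """One iAAFT surrogate of a signal; deterministic given the seed.

    Iteration alternates spectrum adjustment and amplitude adjustment and
    stops when the rank ordering stabilizes or after ``max_iter`` rounds;
    the amplitude-adjusted iterate is returned, so the sorted surrogate
    values equal the sorted original values bit-exactly.
    """
    if len(signal) < 16:
        raise InsufficientLengthError("iAAFT needs at least 16 samples")
    x = signal.values
    if np.ptp(x) == 0.0:
        raise DegenerateSignalError("cannot build surrogates of a constant series")
    if max_iter < 1:
        raise ParameterError(f"max_iter must be >= 1, got {max_iter}")
    rng = np.random.default_rng(seed)
    return signal.replace(values=_iaaft_values(x, max_iter, rng), provenance="surrogate")


def _fifth_percentile_nearest_rank(sorted_values: np.ndarray) -> float:
    n = sorted_values.size
    rank = int(np.ceil(0.05 * n))  # 10th smallest of 200
    return float(sorted_values[max(rank, 1) - 1])


def nonlinearity_tests(
    signal: Signal,
    k_values: tuple[int, ...],
    n_surrogates: int = 200,
    seed: SeedLike = None,
    max_iter: int = 100,
) -> dict[int, SurrogateTestResult]:
    """Surrogate test at several k values sharing one surrogate ensemble.

    A master seed spawns one independent sub-seed per surrogate, so results
    are reproducible and the ensemble could be generated in parallel.  The
    ensemble (and each surrogate's SODP) is built once and profiled at every
    requested k, which is both cheaper and statistically coherent across k.
    """
    if n_surrogates < 1:
        raise ParameterError(f"n_surrogates must be >= 1, got {n_surrogates}")
    k_values = tuple(int(k) for k in k_values)
    sodp = build_sodp(signal)
    phen_orig = {k: phase_entropy(sector_profile(sodp, k)) for k in k_values}

    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = master.spawn(n_surrogates)
    x = signal.values
    if np.ptp(x) == 0.0:
        raise DegenerateSignalError("cannot build surrogates of a constant series")
    phen_surr = {k: np.empty(n_surrogates) for k in k_values}
    for j, child in enumerate(children):
        surr = _iaaft_values(x, max_iter, np.random.default_rng(child))
        surr_sodp = build_sodp(surr)
        for k in k_values:
            phen_surr[k][j] = phase_entropy(sector_profile(surr_sodp, k))

    seed_int = seed if isinstance(seed, int) else None
    results: dict[int, SurrogateTestResult] = {}
    for k in k_values:
        ensemble = phen_surr[k]
        threshold = _fifth_percentile_nearest_rank(np.sort(ensemble))
        results[k] = SurrogateTestResult(
            k=k,
            phen_original=phen_orig[k],
            phen_surrogates=ensemble,
            threshold=threshold,
            nonlinear=bool(phen_orig[k] < threshold),
            n_surrogates=n_surrogates,
            seed=seed_int,
        )
    return results


def nonlinearity_test(
    signal: Signal,
    k: int,
    n_surrogates: int = 200,
    seed: SeedLike = None,
    max_iter: int = 100,
) -> SurrogateTestResult:
    """Surrogate test of nonlinearity at a single sector count k.

    Rejects the linear-Gaussian null (flags the series nonlinear) when the
    original PhEn is strictly below the empirical fifth percentile of the
    surrogate PhEn distribution.
    """
    return nonlinearity_tests(
        signal, (int(k),), n_surrogates=n_surrogates, seed=seed, max_iter=max_iter
    )[int(k)]


def time_reverse(signal: Signal) -> Signal:
    """The series in reverse temporal order; metadata preserved."""
    return signal.replace(values=signal.values[::-1].copy(), provenance="reversed")


def reverse_sodp_map(sodp: SODP) -> tuple[np.ndarray, np.ndarray]:
    """The point map (x, y) -> (-y, -x) linking a series' SODP to its
    time-reversed counterpart (as multisets)."""
    return -sodp.y, -sodp.x
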