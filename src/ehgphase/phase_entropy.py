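"""Phase Entropy over the second-order difference plot (SODP).

The SODP is the Poincare-type scatter of successive first differences,

    X[n] = x[n+1] - x[n],      Y[n] = x[n+2] - x[n+1].

Each point gets a slope angle theta in [0, 2pi) measured counterclockwise
from the positive X axis.  The plane is split into k equal angular sectors
(span 2pi/k, half-open, counted counterclockwise).  Each sector i collects
the sum of the angles of its points, S_theta[i]; the weights

    p(i) = S_theta[i] / sum_j S_theta[j]

form a probability distribution biased toward high-angle sectors, and the
Phase Entropy at coarse-graining k is the normalized Shannon entropy

    PhEn_k = -(1 / log k) * sum_i p(i) log p(i),

a dimensionless value in [0, 1].  Low PhEn marks concentrated, compressible
dynamics; PhEn is 1 exactly when p(i) is uniform.  Because angles depend
only on ratios of differences, PhEn is invariant under positive affine
transforms of the signal, and the base of the logarithm cancels against the
1/log(k) normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSignalError, InsufficientLengthError, ParameterError
from .preprocess import Signal

__all__ = [
    "SODP",
    "SectorProfile",
    "PhEnCurve",
    "build_sodp",
    "slope_angle",
    "sector_profile",
    "phase_entropy",
    "phen_curve",
    "default_k_grid",
]

_TWO_PI = 2.0 * math.pi


def default_k_grid() -> tuple[int, ...]:
    """Multiples of 4 from 4 to 36: the 2 < k < 40, k divisible by 4 grid."""
    return tuple(range(4, 37, 4))


@dataclass(frozen=True)
class SODP:
    """Second-order difference plot: point cloud and per-point slope angles.

    ``n_excluded`` counts exact-origin points (X = Y = 0), whose angle is
    undefined and which are therefore dropped.  For a source series of N
    samples, ``len(x) + n_excluded == N - 2``.
    """

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    n_excluded: int = 0

    def __len__(self) -> int:
        return int(self.theta.size)


@dataclass(frozen=True)
class SectorProfile:
    """Per-sector angle sums, counts and probabilities for one k."""

    k: int
    s_theta: np.ndarray
    counts: np.ndarray
    p: np.ndarray


@dataclass(frozen=True)
class PhEnCurve:
    """Phase Entropy as a function of the sector count k for one signal."""

    k_values: tuple[int, ...]
    phen: np.ndarray
    subject_id: str = ""
    stage: str = ""
    n_points: int = 0
    n_excluded: int = 0


def build_sodp(signal: Signal | np.ndarray) -> SODP:
    """Construct the SODP of a series: points (X[n], Y[n]) with angles.

    Raises :class:`InsufficientLengthError` for fewer than 3 samples and
    :class:`DegenerateSignalError` when every point sits at the origin
    (constant series).
    """
    values = signal.values if isinstance(signal, Signal) else np.asarray(signal, float)
    if values.size < 3:
        raise InsufficientLengthError(
            f"SODP needs at least 3 samples, got {values.size}"
        )
    d = np.diff(values)
    x = d[:-1]
    y = d[1:]
    at_origin = (x == 0.0) & (y == 0.0)
    n_excluded = int(at_origin.sum())
    if n_excluded:
        keep = ~at_origin
        x, y = x[keep], y[keep]
    if x.size == 0:
        raise DegenerateSignalError(
            "all SODP points lie at the origin (constant series)"
        )
    theta = np.arctan2(y, x)
    np.mod(theta, _TWO_PI, out=theta)
    # -eps mod 2pi can round up to exactly 2pi; keep the angle range half-open
    theta[theta >= _TWO_PI] = 0.0
    return SODP(x=x, y=y, theta=theta, n_excluded=n_excluded)


def slope_angle(x: float, y: float) -> float:
    """Four-quadrant slope angle of (x, y) from the origin, in [0, 2pi)."""
    if x == 0.0 and y == 0.0:
        raise DegenerateSignalError("slope angle undefined at the origin")
    t = math.atan2(y, x) % _TWO_PI
    return 0.0 if t >= _TWO_PI else t


def sector_profile(
    sodp: SODP, k: int, normalization: str = "total"
) -> SectorProfile:
    """Partition the SODP into k angular sectors and accumulate angle mass.

    A point with angle t falls in sector ``floor(t * k / 2pi) + 1`` (1-based;
    sectors are half-open ``[2pi(i-1)/k, 2pi i/k)``).  ``S_theta[i]`` is the
    sum of angles in sector i and ``p(i) = S_theta[i] / sum_j S_theta[j]``.

    ``normalization="running"`` instead divides each ``S_theta[i]`` by the
    running sum ``S_theta[1] + ... + S_theta[i]``; the resulting weights are
    not a probability distribution and are provided for comparison only.
    """
    if int(k) != k or k < 2:
        raise ParameterError(f"sector count k must be an integer >= 2, got {k}")
    k = int(k)
    if len(sodp) == 0:
        raise DegenerateSignalError("cannot profile an empty SODP")
    if normalization not in ("total", "running"):
        raise ParameterError(f"unknown normalization {normalization!r}")
    idx = np.floor(sodp.theta * (k / _TWO_PI)).astype(np.intp)
    np.clip(idx, 0, k - 1, out=idx)  # guard boundary rounding
    counts = np.bincount(idx, minlength=k)
    s_theta = np.bincount(idx, weights=sodp.theta, minlength=k)
    if normalization == "total":
        total = s_theta.sum()
        if total <= 0.0:
            raise DegenerateSignalError("total angle mass is zero")
        p = s_theta / total
    else:
        running = np.cumsum(s_theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(running > 0.0, s_theta / running, 0.0)
    return SectorProfile(k=k, s_theta=s_theta, counts=counts, p=p)


def phase_entropy(profile: SectorProfile) -> float:
    """Normalized Shannon entropy of the sector distribution, in [0, 1].

    Uses the convention 0 * log 0 = 0.  With the canonical total-sum
    normalization the value is bounded by 1 (uniform p) and is 0 exactly
    when a single sector carries all the angle mass.
    """
    p = profile.p
    nz = p[p > 0.0]
    h = -float(np.sum(nz * np.log(nz))) / math.log(profile.k)
    # clamp tiny negative round-off from a fully concentrated distribution
    return 0.0 if abs(h) < 1e-15 else h


def phen_curve(
    signal: Signal,
    k_grid: tuple[int, ...] | None = None,
    normalization: str = "total",
) -> PhEnCurve:
    """Phase Entropy of the whole series at each k of the grid.

    The SODP is built once and re-profiled per k, in grid order.
    """
    if k_grid is None:
        k_grid = default_k_grid()
    k_grid = tuple(int(k) for k in k_grid)
    if any(k < 2 for k in k_grid):
        raise ParameterError("all k values must be >= 2")
    sodp = build_sodp(signal)
    phen = np.array(
        [phase_entropy(sector_profile(sodp, k, normalization)) for k in k_grid]
    )
    return PhEnCurve(
        k_values=k_grid,
        phen=phen,
        subject_id=signal.subject_id,
        stage=signal.stage,
        n_points=len(sodp),
        n_excluded=sodp.n_excluded,
    )
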