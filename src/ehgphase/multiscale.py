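"""Multiscale entropy: coarse-graining and Sample Entropy.

The scale-tau coarse-grained series is the sequence of non-overlapping
tau-point window means; scale 1 is the original series.  Sample Entropy
with template length m and tolerance r is

    SampEn = -log(A / B)

where B counts pairs of distinct m-length templates within Chebyshev
distance r and A counts the same for (m+1)-length templates (self-matches
excluded).  Following the usual multiscale-entropy convention, the
tolerance is held fixed across scales at ``r_factor`` times the standard
deviation of the original (scale-1) series, so the measure is invariant
under affine rescaling of the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import InsufficientLengthError, ParameterError
from .preprocess import Signal

logger = logging.getLogger(__name__)

try:  # compiled pair counting; the numpy path below is the fallback
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _count_template_pairs_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    w = sliding_window_view(x, m + 1)  # row i = x[i : i + m + 1]
    n = w.shape[0]  # N - m templates
    a = 0
    b = 0
    for i in range(n - 1):
        diff = np.abs(w[i + 1 :] - w[i])
        within_m = diff[:, :m].max(axis=1) <= r
        nb = int(within_m.sum())
        if nb:
            b += nb
            a += int((diff[within_m, m] <= r).sum())
    return a, b


if njit is not None:

    @njit(cache=False)
    def _count_template_pairs(x, m, r):  # pragma: no cover - compiled
        n = x.shape[0] - m
        a = 0
        b = 0
        for i in range(n - 1):
            for j in range(i + 1, n):
                match = True
                for t in range(m):
                    if abs(x[i + t] - x[j + t]) > r:
                        match = False
                        break
                if match:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b

else:  # pragma: no cover
    _count_template_pairs = _count_template_pairs_numpy

__all__ = ["MSECurve", "coarse_grain", "sample_entropy", "mse_curve"]


@dataclass(frozen=True)
class MSECurve:
    """SampEn per scale tau = 1..tau_max for one signal.

    Scales at which SampEn is undefined (no template matches) hold NaN and
    are flagged False in ``defined``.
    """

    scales: tuple[int, ...]
    sampen: np.ndarray
    m: int
    r_factor: float
    subject_id: str = ""
    stage: str = ""

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.sampen)


def coarse_grain(values: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping window means at scale tau; length floor(N / tau)."""
    if int(tau) != tau or tau < 1:
        raise ParameterError(f"scale tau must be an integer >= 1, got {tau}")
    tau = int(tau)
    values = np.asarray(values, dtype=np.float64)
    if values.size < tau:
        raise InsufficientLengthError(
            f"series of length {values.size} too short for scale {tau}"
        )
    n = values.size // tau
    if tau == 1:
        return values.copy()
    return values[: n * tau].reshape(n, tau).mean(axis=1)


def sample_entropy(values: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample Entropy of a series; NaN when no matches exist at either length.

    ``r`` defaults to 0.15 times the series' standard deviation.  Matching
    uses the Chebyshev (max-coordinate) distance with the within-tolerance
    rule ``d <= r``; the first N - m templates are compared at both lengths
    so every m-template has an (m+1)-point extension.
    """
    x = np.asarray(values, dtype=np.float64)
    if int(m) != m or m < 1:
        raise ParameterError(f"template length m must be an integer >= 1, got {m}")
    m = int(m)
    if x.size <= m + 1:
        raise InsufficientLengthError(
            f"sample entropy with m={m} needs more than {m + 1} samples, "
            f"got {x.size}"
        )
    if r is None:
        r = 0.15 * float(np.std(x))
    if r <= 0:
        raise ParameterError(f"tolerance r must be positive, got {r}")

    a, b = _count_template_pairs(x, m, r)
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def mse_curve(
    signal: Signal,
    tau_max: int = 21,
    m: int = 2,
    r_factor: float = 0.15,
) -> MSECurve:
    """SampEn of the coarse-grained series at every scale 1..tau_max.

    The tolerance r = r_factor * SD(original series) is fixed across scales.
    Undefined scales are recorded as NaN (never as zero) with a warning.
    """
    if tau_max < 1:
        raise ParameterError(f"tau_max must be >= 1, got {tau_max}")
    sd = float(np.std(signal.values))
    if sd == 0.0:
        raise ParameterError("cannot set tolerance from a constant series")
    r = r_factor * sd
    scales = tuple(range(1, tau_max + 1))
    sampen = np.empty(len(scales))
    for j, tau in enumerate(scales):
        coarse = coarse_grain(signal.values, tau)
        if coarse.size <= m + 1:
            raise InsufficientLengthError(
                f"scale {tau} leaves only {coarse.size} points (need > {m + 1})"
            )
        sampen[j] = sample_entropy(coarse, m=m, r=r)
        if not np.isfinite(sampen[j]):
            logger.warning(
                "SampEn undefined (no matches) for subject=%r stage=%r scale=%d",
                signal.subject_id,
                signal.stage,
                tau,
            )
    return MSECurve(
        scales=scales,
        sampen=sampen,
        m=m,
        r_factor=r_factor,
        subject_id=signal.subject_id,
        stage=signal.stage,
    )
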