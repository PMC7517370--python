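"""Signal container, text-file I/O and signal conditioning.

Raw single-channel EHG is exported as a one-column plain-text amplitude file
(nanovolts).  Conditioning reproduces the standard acquisition chain: a
0.2-1 Hz band-pass (the dominant EHG frequency band, which also excludes
motion, respiration and maternal ECG components) followed by decimation from
the 900 Hz acquisition rate down to 20 Hz.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .exceptions import (
    DegenerateSignalError,
    InsufficientLengthError,
    ParameterError,
    ParseError,
)

logger = logging.getLogger(__name__)

__all__ = ["Signal", "read_signal", "write_signal", "bandpass_filter", "downsample"]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled amplitude series with acquisition metadata.

    Parameters
    ----------
    values
        Amplitude samples in nanovolts, in temporal order.
    fs
        Sampling rate in Hz; must be positive.
    subject_id
        Opaque subject label.
    stage
        Recording condition: ``"TT"`` (third trimester), ``"P"`` (active
        parturition), ``"control"`` or ``"synthetic"``.
    provenance
        Free-text processing note (``raw``, ``filtered``, ``downsampled``,
        ``reversed``, ``surrogate``, ...).
    """

    values: np.ndarray
    fs: float
    subject_id: str = ""
    stage: str = "synthetic"
    provenance: str = "raw"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if values.ndim != 1:
            raise ParameterError("signal values must be one-dimensional")
        if values.size and not np.all(np.isfinite(values)):
            raise ParameterError("signal values must be finite")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def replace(self, **changes) -> "Signal":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


def read_signal(
    path: str | Path,
    fs: float,
    subject_id: str = "",
    stage: str = "synthetic",
) -> Signal:
    """Read a one-column plain-text amplitude file (nV).

    Lines beginning with ``#`` and blank lines are skipped.  A non-numeric
    line raises :class:`ParseError` naming the 1-based line number; an empty
    file (no data lines) raises :class:`DegenerateSignalError`.
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {stripped!r} on line {lineno}"
                ) from None
    if not values:
        raise DegenerateSignalError(f"{path}: file contains no data lines")
    return Signal(np.array(values), fs=fs, subject_id=subject_id, stage=stage)


def write_signal(signal: Signal, path: str | Path, header: str | None = None) -> None:
    """Write a signal as a one-column text file that round-trips bit-exactly.

    Values are written with 17 significant digits so ``float(repr)`` recovers
    the original IEEE doubles.
    """
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for v in signal.values:
            fh.write(f"{v:.17g}\n")


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(signal: Signal, low: float = 0.2, high: float = 1.0) -> Signal:
    """Zero-phase 4th-order Butterworth band-pass, default 0.2-1 Hz.

    Applied forward-backward (``sosfiltfilt``), so the filter is phase
    neutral -- important because the downstream statistics are angle based.
    No warm-up samples are trimmed; the output has the input's length.
    """
    if not (0 < low < high < signal.fs / 2):
        raise ParameterError(
            f"band edges must satisfy 0 < low < high < fs/2; "
            f"got low={low}, high={high}, fs={signal.fs}"
        )
    if len(signal) < 16:
        raise InsufficientLengthError("band-pass filtering needs >= 16 samples")
    sos = _bandpass_sos(low, high, signal.fs)
    filtered = sps.sosfiltfilt(sos, signal.values)
    return signal.replace(values=filtered, provenance="filtered")


def downsample(signal: Signal, target_fs: float = 20.0) -> Signal:
    """Decimate to ``target_fs`` by integer-factor sample selection.

    The preceding 0.2-1 Hz band-pass already bounds spectral content far
    below the new Nyquist (10 Hz at 20 Hz), so plain selection avoids a
    second anti-alias filter.  Output length is ``floor(N * target_fs / fs)``.
    """
    ratio = signal.fs / target_fs
    factor = round(ratio)
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ParameterError(
            f"sampling rate {signal.fs} Hz is not an integer multiple of "
            f"target rate {target_fs} Hz"
        )
    if factor == 1:
        return signal
    n_out = len(signal) // factor
    values = signal.values[: n_out * factor : factor].copy()
    return signal.replace(values=values, fs=target_fs, provenance="downsampled")
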