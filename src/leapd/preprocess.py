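"""Per-channel signal conditioning.

Every channel that enters LPC encoding passes through the same fixed
chain: 60-Hz notch -> zero-phase band-pass -> unit-power normalization.
Normalization comes last so the encoder always sees a unit-power signal
regardless of how much energy the band-pass removed.  All operations are
deterministic; only :func:`truncate_fraction` changes the length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "Band",
    "normalize_unit_power",
    "notch_line",
    "bandpass_zero_phase",
    "truncate_fraction",
    "condition_channel",
]

#: quality factor of the IIR line-noise notch (narrow: ~1.7 Hz at 60 Hz)
NOTCH_Q = 35.0
#: order of the Butterworth band-pass (applied forward-backward)
BANDPASS_ORDER = 4


@dataclass(frozen=True)
class Band:
    """A pass-band in Hz. Must satisfy 0 < f_lo < f_hi < Nyquist at use time."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError(f"invalid band: ({self.f_lo}, {self.f_hi}) Hz")

    def validate(self, sample_rate: float) -> None:
        if self.f_hi >= sample_rate / 2.0:
            raise ValueError(
                f"band ({self.f_lo}, {self.f_hi}) Hz exceeds Nyquist for "
                f"sample rate {sample_rate} Hz"
            )


def _as_1d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D time series")
    if not np.all(np.isfinite(x)):
        raise ValueError("time series contains non-finite values")
    return x


def normalize_unit_power(x) -> np.ndarray:
    """Remove the mean and scale to unit mean-square power.

    Raises ``ValueError`` for signals that are constant after mean
    removal (power cannot be normalized).
    """
    x = _as_1d(x)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    x = x - x.mean()
    p = np.mean(x**2)
    if p <= 0.0 or not np.isfinite(p):
        raise ValueError("zero-variance signal cannot be normalized to unit power")
    return x / np.sqrt(p)


def notch_line(x, sample_rate: float, line_freq: float = 60.0) -> np.ndarray:
    """Remove narrowband line noise with a zero-phase second-order IIR notch."""
    x = _as_1d(x)
    if not (0.0 < line_freq < sample_rate / 2.0):
        raise ValueError(
            f"line frequency {line_freq} Hz must lie below Nyquist "
            f"({sample_rate / 2.0} Hz)"
        )
    b, a = sps.iirnotch(line_freq, NOTCH_Q, fs=sample_rate)
    return sps.filtfilt(b, a, x, padtype="even")


def bandpass_zero_phase(x, sample_rate: float, band: Band) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    x = _as_1d(x)
    band.validate(sample_rate)
    sos = sps.butter(
        BANDPASS_ORDER, [band.f_lo, band.f_hi], btype="bandpass", fs=sample_rate,
        output="sos",
    )
    # reflect-pad one impulse-response length to suppress startup transients
    padlen = min(x.size - 1, 3 * (2 * BANDPASS_ORDER + 1))
    return sps.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def truncate_fraction(x, fraction: float) -> np.ndarray:
    """Keep the first ``floor(fraction * N)`` samples, fraction in (0, 1]."""
    x = np.asarray(x)
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = int(np.floor(fraction * x.shape[-1]))
    return x[..., :n]


def condition_channel(
    x,
    sample_rate: float,
    band: Band,
    line_freq: float | None = 60.0,
) -> np.ndarray:
    """Full conditioning chain: notch -> band-pass -> unit-power normalization.

    ``line_freq=None`` skips the notch (e.g. recordings with no mains
    contamination).
    """
    x = _as_1d(x)
    if line_freq is not None:
        x = notch_line(x, sample_rate, line_freq)
    x = bandpass_zero_phase(x, sample_rate, band)
    return normalize_unit_power(x)
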