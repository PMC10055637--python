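"""Linear predictive coding of band-limited EEG channels.

A conditioned channel is summarised by an order-``p`` autoregressive
predictor: ``x_n ≈ a_1 x_{n-1} + ... + a_p x_{n-p}``.  The coefficient
vector captures the channel's spectral envelope — dominant oscillatory
modes appear as pole pairs — in a handful of numbers.  Coefficients are
obtained from the biased autocorrelation via the Levinson–Durbin
recursion, which guarantees a stable (minimum-phase) predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Band, condition_channel

__all__ = [
    "LPCVector",
    "autocorr_biased",
    "levinson_durbin",
    "lpc_encode",
    "lpc_spectrum",
]


@dataclass(frozen=True)
class LPCVector:
    """Order-``p`` predictor coefficients for one channel/band.

    ``coefficients`` follow the predictor convention
    ``x̂_n = Σ_i a_i x_{n-i}``; ``error_variance`` is the final
    prediction-error variance σ² of the recursion.
    """

    order: int
    coefficients: np.ndarray
    error_variance: float
    band: Band | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if coef.shape != (self.order,):
            raise ValueError(
                f"coefficient vector length {coef.shape} != order {self.order}"
            )
        if self.error_variance < 0:
            raise ValueError("error variance must be nonnegative")


def autocorr_biased(x, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation ``r_k = (1/N) Σ_n x_n x_{n+k}``.

    The 1/N normalisation (rather than 1/(N-k)) makes the autocorrelation
    sequence positive semi-definite, which keeps Levinson–Durbin stable.
    Computed via FFT; returns lags ``0..max_lag``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D time series")
    n = x.size
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be < signal length {n}")
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    X = np.fft.rfft(x, nfft)
    r = np.fft.irfft(X * np.conj(X), nfft)[: max_lag + 1]
    return r / n


def levinson_durbin(r, order: int) -> tuple[np.ndarray, float]:
    """Solve the Yule–Walker equations by the Levinson–Durbin recursion.

    Parameters
    ----------
    r : array of autocorrelations ``r_0 .. r_p`` (at least ``order + 1``).
    order : predictor order ``p``.

    Returns
    -------
    (coefficients ``a_1..a_p`` in predictor convention, error variance σ²).

    Raises
    ------
    ValueError
        If ``r_0 <= 0`` or the autocorrelation sequence is numerically
        non-positive-definite (the prediction-error variance collapses
        to zero or below during the recursion).
    """
    r = np.asarray(r, dtype=float)
    if r.size < order + 1:
        raise ValueError(f"need {order + 1} autocorrelation lags, got {r.size}")
    if r[0] <= 0:
        raise ValueError(f"r_0 must be positive, got {r[0]}")

    a = np.zeros(order)
    err = float(r[0])
    for m in range(order):
        k = (r[m + 1] - np.dot(a[:m], r[m:0:-1])) / err
        a_new = a.copy()
        a_new[m] = k
        if m:
            a_new[:m] = a[:m] - k * a[m - 1 :: -1]
        a = a_new
        err *= 1.0 - k * k
        if err <= 0 or not np.isfinite(err):
            raise ValueError(
                "autocorrelation sequence is numerically non-positive-definite"
            )
    return a, err


def lpc_encode(
    x,
    sample_rate: float,
    band: Band,
    order: int,
    channel: str | None = None,
    line_freq: float | None = 60.0,
) -> LPCVector:
    """Condition a raw channel and encode it as an LPC coefficient vector.

    Applies notch -> band-pass -> unit-power normalization, then fits the
    whole recording as a single analysis frame (no windowing: the method
    produces one index per recording, and with minutes of data taper bias
    is negligible).  Scale-invariant by construction: ``lpc_encode(5x)``
    equals ``lpc_encode(x)``.
    """
    y = condition_channel(x, sample_rate, band, line_freq=line_freq)
    r = autocorr_biased(y, order)
    a, err = levinson_durbin(r, order)
    return LPCVector(
        order=order, coefficients=a, error_variance=err, band=band, channel=channel
    )


def lpc_spectrum(v: LPCVector, sample_rate: float, freqs) -> np.ndarray:
    """All-pole power spectrum ``S(f) = σ² / |1 - Σ_k a_k e^{-i2πfk/fs}|²``."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > sample_rate):
        raise ValueError("frequencies must lie in [0, sample_rate]")
    k = np.arange(1, v.order + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / sample_rate)
    denom = np.abs(1.0 - phase @ v.coefficients) ** 2
    # a stable predictor keeps the denominator strictly positive
    return v.error_variance / denom
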