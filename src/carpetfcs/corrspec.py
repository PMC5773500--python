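"""ACF / pCF computation on line-scan carpets.

The pair correlation function between two pixel columns a distance ``d``
apart, at lag ``tau``, is

    pCF(tau, d) = <F(t, r) F(t + tau, r + d)> / (<F(t, r)> <F(t, r + d)>) - 1

with ``d = 0`` and equal channels giving the autocorrelation function.
Means in the denominator are taken over the same overlapping support as
the numerator (t in [0, T - tau)), which removes the finite-length bias
of the naive full-series normalization.  The production path evaluates
all integer lags at once with a zero-padded (linear, not circular) FFT;
:func:`direct_correlation_oracle` is the brute-force O(T*L) reference it
must match.

Lag grids are quasi-logarithmic multi-tau style (fixed number of points
per octave) from one line period to ``n_lines / 8``, matching the
log-time pair-correlation carpets this analysis is displayed on and
bounding estimator variance at long lags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "CorrelationCurve",
    "CorrelationCarpet",
    "make_lag_grid",
    "correlate_series",
    "direct_correlation_oracle",
    "pcf_column",
    "pcf_carpet",
    "acf_carpet",
    "detrend_column",
    "integrate_curve",
    "curve_peak_lag",
]


@dataclass
class CorrelationCurve:
    """One correlation curve on a lag grid (lags in lines, times in s)."""

    values: np.ndarray
    lags: np.ndarray
    lag_times_s: np.ndarray
    distance_px: int = 0
    valid: bool = True


@dataclass
class CorrelationCarpet:
    """Per-column correlation curves stacked into an (n_columns, n_lags) matrix.

    ``mode`` is ``"auto"`` (d = 0, same channel), ``"pair"`` (d > 0, same
    channel) or ``"cross_channel_pair"``; ``direction`` is the sign of d
    along the line.  ``valid`` flags columns whose curves are usable
    (in-bounds partner pixel and positive means).
    """

    values: np.ndarray
    lags: np.ndarray
    lag_times_s: np.ndarray
    distance_px: int
    mode: str
    valid: np.ndarray
    separation_nm: float
    direction: int = 1

    @property
    def n_columns(self) -> int:
        return self.values.shape[0]


def make_lag_grid(
    n_lines: int,
    points_per_octave: int = 8,
    min_lag: int = 1,
    max_lag: int | None = None,
) -> np.ndarray:
    """Quasi-logarithmic integer lag grid (multi-tau style).

    Strictly increasing unique integers from ``min_lag`` to
    ``max_lag`` (default ``n_lines // 8``), ``points_per_octave`` points
    per factor of two.
    """
    if max_lag is None:
        max_lag = max(n_lines // 8, min_lag)
    max_lag = min(max_lag, n_lines - 1)
    if min_lag < 1 or max_lag < min_lag:
        raise ValueError("need 1 <= min_lag <= max_lag < n_lines")
    n_oct = np.log2(max_lag / min_lag) if max_lag > min_lag else 0.0
    n_pts = max(int(np.ceil(n_oct * points_per_octave)) + 1, 1)
    lags = np.unique(np.round(min_lag * 2.0 ** (np.arange(n_pts) * (n_oct / max(n_pts - 1, 1)))).astype(int))
    return lags[(lags >= min_lag) & (lags <= max_lag)]


def _cross_sums_fft(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """sum_t a[t] * b[t + tau] for tau = 0..max_lag via zero-padded FFT."""
    n = len(a)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fa = np.fft.rfft(a, nfft)
    fb = np.fft.rfft(b, nfft)
    cc = np.fft.irfft(np.conj(fa) * fb, nfft)
    return cc[: max_lag + 1]


def correlate_series(
    a: Sequence[float],
    b: Sequence[float] | None = None,
    lags: np.ndarray | Sequence[int] | None = None,
) -> tuple[np.ndarray, bool]:
    """Normalized correlation of two equal-length series at integer lags.

    Returns ``(values, valid)``: valid is False (values zero) when either
    series has a non-positive mean on some overlapping support, in which
    case the curve is flagged rather than propagating NaNs.
    """
    a = np.asarray(a, float)
    b = a if b is None else np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    lags = np.asarray(lags if lags is not None else make_lag_grid(len(a)), int)
    if lags.size and lags.max() >= len(a):
        raise ValueError("max lag must be < series length")
    if lags.size and lags.min() < 0:
        raise ValueError("lags must be >= 0")
    T = len(a)
    cross = _cross_sums_fft(a, b, int(lags.max()) if lags.size else 0)
    ca = np.concatenate([[0.0], np.cumsum(a)])
    cb = np.concatenate([[0.0], np.cumsum(b)])
    values = np.zeros(len(lags))
    valid = True
    for i, tau in enumerate(lags):
        n_ov = T - tau
        num = cross[tau] / n_ov
        mean_a = ca[n_ov] / n_ov            # a[0 : T - tau]
        mean_b = (cb[T] - cb[tau]) / n_ov   # b[tau : T]
        if mean_a <= 0 or mean_b <= 0:
            valid = False
            break
        values[i] = num / (mean_a * mean_b) - 1.0
    if not valid:
        values[:] = 0.0
    return values, valid


def direct_correlation_oracle(
    series_a: Sequence[float],
    series_b: Sequence[float],
    lags: Sequence[int],
) -> np.ndarray:
    """Brute-force evaluation of the pair correlation by explicit summation.

    O(T * L) reference implementation, kept free of FFTs and cumulative
    sums so the production path can be validated against it.
    """
    a = [float(v) for v in series_a]
    b = [float(v) for v in series_b]
    T = len(a)
    out = []
    for tau in lags:
        tau = int(tau)
        num = 0.0
        ma = 0.0
        mb = 0.0
        n = T - tau
        for t in range(n):
            num += a[t] * b[t + tau]
            ma += a[t]
            mb += b[t + tau]
        num /= n
        ma /= n
        mb /= n
        out.append(num / (ma * mb) - 1.0)
    return np.asarray(out)


def pcf_column(
    carpet,
    column: int,
    d: int = 0,
    channel_a: int = 0,
    channel_b: int | None = None,
    lags: np.ndarray | None = None,
) -> CorrelationCurve:
    """pCF(tau, d) between ``column`` (channel_a) and ``column + d`` (channel_b).

    With ``channel_a == channel_b`` and ``d == 0`` this is the column ACF;
    with different channels it is the cross-channel pair correlation.
    """
    if channel_b is None:
        channel_b = channel_a
    n_pixels = carpet.n_pixels
    if not (0 <= column < n_pixels and 0 <= column + d < n_pixels):
        raise ValueError(f"column {column} with offset {d} outside 0..{n_pixels - 1}")
    if lags is None:
        lags = make_lag_grid(carpet.n_lines)
    a = carpet.data[:, column, channel_a].astype(float)
    b = carpet.data[:, column + d, channel_b].astype(float)
    values, valid = correlate_series(a, b, lags)
    return CorrelationCurve(
        values=values,
        lags=np.asarray(lags, int),
        lag_times_s=np.asarray(lags, float) * carpet.line_period_s,
        distance_px=d,
        valid=valid,
    )


def pcf_carpet(
    carpet,
    d: int = 20,
    channels: tuple[int, int] = (0, 0),
    lags: np.ndarray | None = None,
) -> CorrelationCarpet:
    """Stack :func:`pcf_column` over every column; invalid columns flagged.

    ``d`` may be negative (correlate with the upstream pixel).  Records
    the physical pixel-pair separation ``|d| * pixel_size_nm``.
    """
    if lags is None:
        lags = make_lag_grid(carpet.n_lines)
    lags = np.asarray(lags, int)
    n_pixels = carpet.n_pixels
    values = np.zeros((n_pixels, len(lags)))
    valid = np.zeros(n_pixels, bool)
    for col in range(n_pixels):
        if not (0 <= col + d < n_pixels):
            continue
        curve = pcf_column(carpet, col, d, channels[0], channels[1], lags)
        values[col] = curve.values
        valid[col] = curve.valid
    if channels[0] != channels[1]:
        mode = "cross_channel_pair"
    elif d == 0:
        mode = "auto"
    else:
        mode = "pair"
    return CorrelationCarpet(
        values=values,
        lags=lags,
        lag_times_s=lags.astype(float) * carpet.line_period_s,
        distance_px=d,
        mode=mode,
        valid=valid,
        separation_nm=abs(d) * carpet.pixel_size_nm,
        direction=int(np.sign(d)) if d else 1,
    )


def acf_carpet(carpet, channel: int = 0, lags: np.ndarray | None = None) -> CorrelationCarpet:
    """Autocorrelation carpet: :func:`pcf_carpet` at d = 0 (same code path)."""
    return pcf_carpet(carpet, d=0, channels=(channel, channel), lags=lags)


def detrend_column(
    series: Sequence[float],
    method: str = "additive",
    window: int = 1000,
) -> np.ndarray:
    """Remove a slow trend (bleaching / drift guard) while preserving the mean.

    The trend is a centered boxcar moving average.  ``additive`` subtracts
    it and restores the mean; ``multiplicative`` rescales by mean/trend
    (appropriate for exponential bleaching).  Off by default in the
    pipeline.
    """
    series = np.asarray(series, float)
    if window <= 1:
        raise ValueError("window must be > 1")
    if window >= len(series):
        raise ValueError("window must be smaller than the series length")
    trend = uniform_filter1d(series, size=window, mode="nearest")
    if method == "additive":
        # adding the trend's own mean back preserves the series mean exactly
        return series - trend + trend.mean()
    if method == "multiplicative":
        safe = np.where(trend > 0, trend, np.inf)
        return series * (series.mean() / safe)
    raise ValueError(f"unknown detrend method {method!r}")


def integrate_curve(
    values: np.ndarray,
    lag_times_s: np.ndarray,
    tau_window: tuple[float, float] | None = None,
    mode: str = "mean",
) -> float:
    """Summarize a correlation curve over a lag-time window.

    ``mode="sum"`` is the correlation integral; ``"mean"`` the window
    average (grid-density independent).
    """
    sel = np.ones(len(values), bool)
    if tau_window is not None:
        sel = (lag_times_s >= tau_window[0]) & (lag_times_s <= tau_window[1])
    if not sel.any():
        return 0.0
    return float(values[sel].sum() if mode == "sum" else values[sel].mean())


def curve_peak_lag(
    values: np.ndarray,
    lag_times_s: np.ndarray,
    smooth: int = 5,
) -> float:
    """Lag time of the curve maximum after light boxcar smoothing."""
    v = uniform_filter1d(np.asarray(values, float), size=max(1, smooth), mode="nearest")
    return float(lag_times_s[int(np.argmax(v))])
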