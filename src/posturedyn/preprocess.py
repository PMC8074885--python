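"""Signal conditioning: low-pass filtering, moving-average smoothing,
stride time-normalization and middle-stride selection.

All operations are deterministic: identical input yields bit-identical
output.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .errors import InsufficientDataError, ParameterError
from .io_config import ForcePlateRecord


def lowpass_butterworth(
    record: ForcePlateRecord,
    cutoff: float = 15.0,
    order: int = 2,
    channels: tuple[str, ...] = ("copx", "copy"),
) -> ForcePlateRecord:
    """Zero-phase Butterworth low-pass of the COP channels.

    The filter is applied forward-backward (``filtfilt``), the norm in
    posturography since it leaves sway geometry free of phase distortion;
    ``cutoff``/``order`` describe the single-pass design, so the effective
    attenuation order doubles.  Fz is left untouched by default.
    """
    nyq = record.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyq:g}) Hz"
        )
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    b, a = butter(order, cutoff / nyq)
    new = {ch: filtfilt(b, a, record.channel(ch)) for ch in channels}
    return record.replace(**new)


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    Output has the same length as the input.  For even windows the span is
    left-heavy by one sample (indices ``i-(w-1)//2 .. i+w//2`` inclusive).
    ``window=1`` is the identity.
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    n = x.size
    if window > n:
        raise ParameterError(f"window {window} exceeds series length {n}")
    if window == 1:
        return x.copy()
    half_l = (window - 1) // 2
    half_r = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(n)
    lo = np.maximum(i - half_l, 0)
    hi = np.minimum(i + half_r + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


@dataclass
class NormalizedStrideSeries:
    """A signal resampled to a fixed number of points per stride.

    ``values`` holds ``n_strides * points_per_stride`` samples, strides
    concatenated in temporal order; normalized time advances by one stride
    every ``points_per_stride`` samples.
    """

    values: np.ndarray
    points_per_stride: int
    n_strides: int
    source_channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_strides * self.points_per_stride:
            raise ParameterError(
                "values length inconsistent with n_strides * points_per_stride"
            )

    def as_strides(self) -> np.ndarray:
        """Return a (n_strides, points_per_stride) view."""
        return self.values.reshape(self.n_strides, self.points_per_stride)


def normalize_strides(
    series: np.ndarray,
    strikes: np.ndarray,
    points_per_stride: int = 200,
    source_channel: str = "",
) -> NormalizedStrideSeries:
    """Time-normalize each stride to a fixed point count by cubic spline.

    ``strikes`` are sample indices of consecutive same-side heel-strikes;
    stride *k* spans ``strikes[k] .. strikes[k+1]``.  Each stride is
    resampled to ``points_per_stride`` samples on an endpoint-exclusive
    grid, so concatenated strides tile normalized time without duplicating
    the shared boundary sample.  Natural boundary conditions.
    """
    x = np.asarray(series, dtype=float)
    strikes = np.asarray(strikes, dtype=int)
    if strikes.size < 2:
        raise InsufficientDataError(
            f"need >= 2 same-side heel-strikes, got {strikes.size}"
        )
    if np.any(np.diff(strikes) <= 0):
        raise ParameterError("strike indices must be strictly increasing")
    if strikes[0] < 0 or strikes[-1] >= x.size:
        raise ParameterError("strike indices out of range")
    out = np.empty((strikes.size - 1) * points_per_stride)
    for k, (a, b) in enumerate(zip(strikes[:-1], strikes[1:])):
        seg = x[a:b + 1]
        cs = CubicSpline(np.arange(seg.size), seg, bc_type="natural")
        grid = np.linspace(0.0, seg.size - 1.0, points_per_stride,
                           endpoint=False)
        out[k * points_per_stride:(k + 1) * points_per_stride] = cs(grid)
    return NormalizedStrideSeries(
        values=out,
        points_per_stride=points_per_stride,
        n_strides=strikes.size - 1,
        source_channel=source_channel,
    )


def select_middle_strides(
    series: NormalizedStrideSeries, n: int
) -> NormalizedStrideSeries:
    """Keep the contiguous central block of ``n`` strides.

    When the excess is odd the block starts one stride earlier (ties break
    toward the beginning of the trial).
    """
    avail = series.n_strides
    if n > avail:
        raise InsufficientDataError(
            f"requested {n} strides but only {avail} available"
        )
    start = (avail - n) // 2
    pps = series.points_per_stride
    vals = series.values[start * pps:(start + n) * pps].copy()
    return NormalizedStrideSeries(
        values=vals, points_per_stride=pps, n_strides=n,
        source_channel=series.source_channel,
    )
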