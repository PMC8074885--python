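"""Heel-strike detection from treadmill force-plate data and robust
spatiotemporal step metrics.

A heel-strike shows up in the net vertical force as a surge exceeding
body weight (weight acceptance) that follows a rapid lateral shift of the
whole-body centre of pressure toward the landing foot.  The event sample
is the point of maximal inclination (steepest rise) of the smoothed Fz on
the surge's rising limb; the side is the direction of the preceding COPX
shift (+X rightward -> right heel-strike).

Step metrics are summarized by median and MAD
(``MAD(x) = median(|x_i - median(x)|)``) rather than mean/SD: single
missed or spurious events produce gross outlier steps, and the
median/MAD pair is insensitive to them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .errors import DetectionError, InsufficientDataError, ParameterError
from .io_config import ForcePlateRecord
from .preprocess import moving_average

logger = logging.getLogger(__name__)


@dataclass
class GaitEventSeries:
    """Detected heel-strikes: sample indices, foot side per strike (+1
    right / -1 left), sampling rate, and any detection fault notes."""

    strike_idx: np.ndarray
    sides: np.ndarray
    fs: float
    faults: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.strike_idx = np.asarray(self.strike_idx, dtype=int)
        self.sides = np.asarray(self.sides, dtype=int)
        if self.strike_idx.size != self.sides.size:
            raise ParameterError("strike_idx and sides must align")
        if np.any(np.diff(self.strike_idx) <= 0):
            raise ParameterError("strike indices must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.strike_idx.size

    @property
    def times(self) -> np.ndarray:
        """Strike times in seconds."""
        return self.strike_idx / self.fs

    def side_strikes(self, side: str) -> np.ndarray:
        """Strike indices of one foot ('left' or 'right')."""
        want = 1 if side == "right" else -1
        return self.strike_idx[self.sides == want]

    def alternation_ok(self) -> bool:
        return bool(np.all(np.diff(self.sides) != 0))


@dataclass
class StepMetrics:
    """Per-step times (s) and widths (mm) with median/MAD summaries."""

    step_times: np.ndarray
    step_widths: np.ndarray
    median_time: float
    mad_time: float
    median_width: float
    mad_width: float
    n_excluded: int


def mad(x: np.ndarray) -> float:
    """Median absolute deviation from the median (no consistency factor)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def _step_period_estimate(copx_s: np.ndarray, fs: float) -> float:
    """Step period (s) from the dominant stride frequency of COPX.

    COPX alternates once per stride, so its spectral peak sits at the
    stride frequency; the step period is half a stride.  The search band
    0.2-2 Hz covers stride rates from very slow to running cadence.
    """
    f, pxx = periodogram(copx_s - copx_s.mean(), fs)
    band = (f > 0.2) & (f < 2.0)
    if not band.any() or pxx[band].max() <= 0:
        raise DetectionError("no dominant stride frequency in COPX")
    f_stride = f[band][np.argmax(pxx[band])]
    return 1.0 / (2.0 * f_stride)


def detect_heel_strikes(
    record: ForcePlateRecord,
    body_weight: float | None = None,
    *,
    smooth_window: int = 10,
    copx_mad_k: float = 3.0,
    lookback_frac: float = 0.4,
    prominence_frac: float = 0.10,
    min_separation_frac: float = 0.5,
) -> GaitEventSeries:
    """Detect heel-strikes from the net Fz and COPX channels.

    Candidate surges are contiguous excursions of the smoothed Fz above
    body weight with peak prominence of at least ``prominence_frac`` x
    body weight.  A surge qualifies as a heel-strike only when the robust
    COPX derivative exceeds ``copx_mad_k`` x MAD within a look-back window
    of ``lookback_frac`` x (median step period) before the surge onset;
    the event sample is the maximal first difference of the smoothed Fz
    between surge onset (preceding local minimum) and surge peak, and the
    side is the sign of the COPX shift.

    Raises :class:`DetectionError` when no surge crosses body weight
    (e.g. a quiet-standing record).
    """
    fs = record.fs
    bw = record.body_weight() if body_weight is None else float(body_weight)
    if bw <= 0:
        raise ParameterError("body weight must be positive")
    fz_s = moving_average(record.fz, smooth_window)
    copx_s = moving_average(record.copx, smooth_window)

    # upward crossings of body weight
    above = fz_s > bw
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if up.size == 0:
        raise DetectionError("no vertical-force surge exceeds body weight")

    step_period = _step_period_estimate(copx_s, fs)
    look = max(1, int(round(lookback_frac * step_period * fs)))
    min_sep = int(round(min_separation_frac * step_period * fs))

    # robust threshold on the COPX rate of change
    dcopx = np.gradient(copx_s) * fs
    thr = copx_mad_k * mad(dcopx)
    # centred derivative with an odd smoothing window keeps event
    # localization free of the half-sample bias of one-sided differences
    dfz = moving_average(np.gradient(fz_s), smooth_window | 1)

    events: list[int] = []
    sides: list[int] = []
    for c in up:
        below = np.flatnonzero(~above[c:])
        end = c + (int(below[0]) if below.size else fz_s.size - c - 1)
        peak = c + int(np.argmax(fz_s[c:end + 1]))
        if fz_s[peak] - bw < prominence_frac * bw:
            continue
        onset = c
        while onset > 1 and dfz[onset - 1] > 0:
            onset -= 1
        w0 = max(0, onset - look)
        if w0 >= onset:
            continue
        seg = dcopx[w0:onset + 1]
        j = int(np.argmax(np.abs(seg)))
        if abs(seg[j]) < thr:
            continue
        ev = onset + int(np.argmax(dfz[onset:peak + 1]))
        if events and ev - events[-1] < min_sep:
            continue
        events.append(ev)
        sides.append(1 if seg[j] > 0 else -1)

    if not events:
        raise DetectionError(
            "surges found but none qualified (no preceding COPX transition)"
        )
    faults = []
    sides_arr = np.array(sides)
    if np.any(np.diff(sides_arr) == 0):
        bad = np.flatnonzero(np.diff(sides_arr) == 0).tolist()
        faults.append(f"side_alternation_violated_at:{bad[:20]}")
        logger.warning("detect_heel_strikes: side alternation violated at "
                       "event pairs %s", bad[:20])
    return GaitEventSeries(strike_idx=np.array(events), sides=sides_arr,
                           fs=fs, faults=faults)


def step_metrics(
    events: GaitEventSeries,
    copx: np.ndarray,
    n_trim: int = 10,
) -> StepMetrics:
    """Step times/widths between consecutive heel-strikes, robustly
    summarized after dropping the first and last ``n_trim`` steps.

    Step width is the absolute difference of the (whole-body) COPX at
    consecutive strike instants — a proxy for lateral foot placement,
    biased by the double-support COP blend, but the only width observable
    from a single net COP trajectory.
    """
    idx = events.strike_idx
    if idx.size < 2 * n_trim + 2:
        raise InsufficientDataError(
            f"{idx.size} strikes cannot support n_trim={n_trim} "
            f"(need >= {2 * n_trim + 2})"
        )
    x = np.asarray(copx, dtype=float)
    times = np.diff(idx) / events.fs
    widths = np.abs(np.diff(x[idx]))
    n_steps = times.size
    keep = slice(n_trim, n_steps - n_trim if n_trim else n_steps)
    t_kept = times[keep]
    w_kept = widths[keep]
    if t_kept.size == 0:
        raise InsufficientDataError("no steps remain after trimming")
    return StepMetrics(
        step_times=t_kept,
        step_widths=w_kept,
        median_time=float(np.median(t_kept)),
        mad_time=mad(t_kept),
        median_width=float(np.median(w_kept)),
        mad_width=mad(w_kept),
        n_excluded=n_steps - t_kept.size,
    )
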