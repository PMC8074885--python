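"""Stabilogram diffusion analysis (SDA) and sway geometry.

The centre of pressure under quiet standing behaves, over short
intervals, like a correlated random walk.  SDA characterizes it by the
mean square displacement

    <dr^2>(dt) = sum_{i=1..N-m} (r_{i+m} - r_i)^2 / (N - m),

computed for every integer sample interval m (dt = m/fs), per axis and
for the planar resultant (which is exactly the sum of the two axis
curves).  The short-term diffusion coefficient is half the slope of the
mean-square-displacement-versus-interval line in the short-interval
regime, per axis (D_xs, D_ys) and planar (D_rs), all in mm^2 s^-1.
Sway geometry adds the per-axis ranges and their difference
SRD = ML - AP, an isotropy indicator (zero for isotropic sway).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, ParameterError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MSDCurve:
    """Mean square displacement vs time interval, per axis and planar."""

    dt: np.ndarray        # s, strictly increasing
    msd_x: np.ndarray     # mm^2
    msd_y: np.ndarray     # mm^2
    msd_r: np.ndarray     # mm^2, equals msd_x + msd_y
    n_pairs: np.ndarray   # ordered pairs averaged per interval

    def __post_init__(self) -> None:
        for name in ("dt", "msd_x", "msd_y", "msd_r"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.dt) <= 0):
            raise ValidationError("dt grid must be strictly increasing")
        if np.any(self.msd_x < 0) or np.any(self.msd_y < 0):
            raise ValidationError("mean square displacement must be >= 0")
        # planar additivity is an exact identity of the displacement sum
        if not np.allclose(self.msd_r, self.msd_x + self.msd_y,
                           rtol=0, atol=1e-9 * max(1.0, float(self.msd_r.max(initial=0.0)))):
            raise ValidationError("msd_r != msd_x + msd_y")


@dataclass
class DiffusionResult:
    """Fitted short-term diffusion coefficients (mm^2 s^-1)."""

    dxs: float
    dys: float
    drs: float
    fit_window: tuple[float, float]
    r2_x: float
    r2_y: float
    r2_r: float
    critical_point: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class SwaySummary:
    """Sway ranges (mm), their difference, and log-transformed coefficients."""

    range_ml: float
    range_ap: float
    srd: float
    ln_dxs: float
    ln_dys: float
    ln_drs: float
    flags: list[str] = field(default_factory=list)


def mean_square_displacement(
    copx: np.ndarray,
    copy: np.ndarray,
    fs: float,
    max_dt: float = 2.0,
) -> MSDCurve:
    """Mean square COP displacement for every interval up to ``max_dt``.

    For interval m samples, the average runs over all N - m ordered pairs.
    """
    x = np.asarray(copx, dtype=float)
    y = np.asarray(copy, dtype=float)
    if x.size != y.size:
        raise ParameterError("copx and copy must have equal length")
    n = x.size
    if n < 2:
        raise ParameterError("need at least 2 samples")
    max_m = int(np.floor(max_dt * fs))
    if max_m < 1 or max_m >= n:
        raise ParameterError(
            f"max_dt={max_dt}s gives {max_m} intervals; need 1 <= m < {n}"
        )
    msd_x = np.empty(max_m)
    msd_y = np.empty(max_m)
    n_pairs = np.empty(max_m, dtype=int)
    for m in range(1, max_m + 1):
        dx = x[m:] - x[:-m]
        dy = y[m:] - y[:-m]
        msd_x[m - 1] = np.mean(dx * dx)
        msd_y[m - 1] = np.mean(dy * dy)
        n_pairs[m - 1] = n - m
    dt = np.arange(1, max_m + 1) / fs
    return MSDCurve(dt=dt, msd_x=msd_x, msd_y=msd_y,
                    msd_r=msd_x + msd_y, n_pairs=n_pairs)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of y on x."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def fit_short_term_coefficients(
    curve: MSDCurve,
    fit_window: tuple[float, float] = (0.02, 0.5),
    critical_point: float | None = None,
) -> DiffusionResult:
    """Half-slope of the MSD-vs-interval line inside ``fit_window``.

    The same window is applied to the x, y and planar curves, so the
    planar coefficient equals the sum of the axis coefficients by
    linearity of least squares.  Negative slopes are reported as-is and
    flagged, never clamped.
    """
    lo, hi = fit_window
    mask = (curve.dt >= lo) & (curve.dt <= hi)
    if mask.sum() < 3:
        raise FitError(
            f"fit window [{lo}, {hi}] s contains {int(mask.sum())} grid points; "
            "need >= 3"
        )
    dt = curve.dt[mask]
    sx, r2x = _ols_slope(dt, curve.msd_x[mask])
    sy, r2y = _ols_slope(dt, curve.msd_y[mask])
    sr, r2r = _ols_slope(dt, curve.msd_r[mask])
    flags = []
    for name, s in (("dxs", sx), ("dys", sy), ("drs", sr)):
        if s < 0:
            flags.append(f"negative_slope:{name}")
    return DiffusionResult(
        dxs=sx / 2.0, dys=sy / 2.0, drs=sr / 2.0,
        fit_window=(lo, hi), r2_x=r2x, r2_y=r2y, r2_r=r2r,
        critical_point=critical_point, flags=flags,
    )


def detect_critical_point(
    curve: MSDCurve,
    min_improvement: float = 0.05,
) -> float | None:
    """Changepoint of a continuous two-segment linear fit to the planar MSD.

    Scans every interior grid point as a candidate breakpoint of the model
    ``msd ~ b0 + b1*dt + b2*max(dt - break, 0)`` and keeps the one that
    minimizes the residual sum of squares.  Returns ``None`` when the best
    two-segment fit improves on a single line by less than
    ``min_improvement`` (relative RSS reduction), or when the single line
    is already an essentially exact fit.
    """
    dt = curve.dt
    y = curve.msd_r
    n = dt.size
    if n < 5:
        return None
    X1 = np.column_stack([np.ones(n), dt])
    beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss1 = float(np.sum((y - X1 @ beta1) ** 2))
    scale = float(np.sum(y ** 2))
    if rss1 <= 1e-12 * max(scale, 1e-300):
        return None  # single line already exact
    best_b, best_rss = None, np.inf
    hinge = np.empty(n)
    for i in range(2, n - 2):
        b = dt[i]
        np.maximum(dt - b, 0.0, out=hinge)
        X = np.column_stack([np.ones(n), dt, hinge])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        if rss < best_rss:
            best_b, best_rss = b, rss
    if best_b is None or 1.0 - best_rss / rss1 < min_improvement:
        return None
    return float(best_b)


def sway_summary(
    copx: np.ndarray,
    copy: np.ndarray,
    diffusion: DiffusionResult,
) -> SwaySummary:
    """Per-axis sway ranges, SRD = ML - AP, and ln-transformed coefficients.

    Non-positive coefficients cannot be log-transformed; they are recorded
    as NaN with a flag.
    """
    x = np.asarray(copx, dtype=float)
    y = np.asarray(copy, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("empty series")
    range_ml = float(x.max() - x.min())
    range_ap = float(y.max() - y.min())
    flags = []
    lns = {}
    for name, v in (("dxs", diffusion.dxs), ("dys", diffusion.dys),
                    ("drs", diffusion.drs)):
        if v > 0:
            lns[name] = float(np.log(v))
        else:
            lns[name] = float("nan")
            flags.append(f"ln_skipped_nonpositive:{name}")
            logger.warning("sway_summary: %s = %g is non-positive; "
                           "ln recorded as missing", name, v)
    return SwaySummary(
        range_ml=range_ml, range_ap=range_ap, srd=range_ml - range_ap,
        ln_dxs=lns["dxs"], ln_dys=lns["dys"], ln_drs=lns["drs"],
        flags=flags,
    )


def analyze_standing(
    record,
    config=None,
) -> tuple[DiffusionResult, SwaySummary, MSDCurve]:
    """Full standing-trial chain: low-pass -> MSD -> fit -> sway summary.

    The short-term fit window is truncated at the detected critical point
    when that point falls inside it (the short-term regime ends there).
    """
    from .io_config import RunConfig
    from .preprocess import lowpass_butterworth

    cfg = config or RunConfig()
    filt = lowpass_butterworth(record, cfg.filter_cutoff_hz, cfg.filter_order)
    max_dt = min(cfg.sda_max_dt_s, (record.n_samples - 1) / record.fs)
    curve = mean_square_displacement(filt.copx, filt.copy, record.fs, max_dt)
    crit = detect_critical_point(curve, cfg.sda_min_improvement)
    lo, hi = cfg.sda_fit_window_s
    if (cfg.sda_truncate_at_critical and crit is not None
            and lo < crit < hi):
        hi = crit
    diff = fit_short_term_coefficients(curve, (lo, hi), critical_point=crit)
    summary = sway_summary(filt.copx, filt.copy, diff)
    return diff, summary, curve
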