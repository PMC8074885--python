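"""Delay-embedding machinery and the local divergence exponent (lambda*).

The maximal Lyapunov exponent of a dynamical system measures the
exponential rate at which initially close trajectories separate,
``d(t) = d0 * exp(lambda * t)``.  From a single scalar measurement the
state space is reconstructed by the method of delays; for each
reconstructed state the nearest neighbour outside a temporal exclusion
(Theiler) window is found, and the mean natural-log distance between
originally-neighbouring pairs is tracked as both advance in time.  The
finite-time exponent lambda* is the least-squares slope of this average
log-divergence curve.  Rather than fixing the fit to a time span, the
fit region is bounded by magnitude: from the curve's first attainment of
10 % of its (min-max normalized) range to its first attainment of 90 %.

For gait, each channel (Fz, COPX, COPY) is embedded separately in a
5-dimensional space built from stride-normalized series (200 samples per
stride), and lambda* is reported per stride.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import EstimationError, FitError, ParameterError
from .preprocess import NormalizedStrideSeries

logger = logging.getLogger(__name__)

#: distances below this fraction of the state RMS are treated as zero:
#: they reflect floating-point / interpolation texture, not dynamics.
DISTANCE_FLOOR_REL = 1e-6

#: a divergence curve whose total range is below this is flat (lambda*=0)
FLAT_CURVE_RANGE = 1e-9


@dataclass
class EmbeddingParams:
    """Delay-embedding settings: delay (samples), dimension, and the
    Theiler exclusion window (samples) for neighbour search."""

    delay: int
    dim: int = 5
    theiler: int = 0

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ParameterError("delay must be >= 1")
        if self.dim < 1:
            raise ParameterError("dim must be >= 1")
        if self.theiler < 0:
            raise ParameterError("theiler must be >= 0")


@dataclass
class DivergenceResult:
    """Average log-divergence curve and the fitted exponent."""

    lags: np.ndarray            # forward lag, samples
    mean_log_div: np.ndarray    # mean natural-log distance
    fit_lo_idx: int
    fit_hi_idx: int
    lambda_star: float          # per reported time unit (stride by default)
    r2: float
    params: EmbeddingParams | None = None
    channel: str = ""
    samples_per_unit: int = 1
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# delay selection: first minimum of lagged mutual information
# ---------------------------------------------------------------------------

def mutual_information_profile(
    series: np.ndarray,
    max_lag: int,
    n_bins: int | None = None,
) -> np.ndarray:
    """Histogram mutual information (nats) at lags 1..max_lag.

    Equal-width marginal bins, ``ceil(sqrt(N/5))`` of them by default.
    Returns an array of length ``max_lag`` (index 0 <-> lag 1).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag < 1 or max_lag >= n:
        raise ParameterError("max_lag must satisfy 1 <= max_lag < len(series)")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise EstimationError("series is constant; mutual information undefined")
    if n_bins is None:
        n_bins = int(np.ceil(np.sqrt(n / 5)))
    codes = np.minimum(((x - lo) / (hi - lo) * n_bins).astype(np.int64),
                       n_bins - 1)
    out = np.empty(max_lag)
    for tau in range(1, max_lag + 1):
        a, b = codes[:-tau], codes[tau:]
        joint = np.bincount(a * n_bins + b,
                            minlength=n_bins * n_bins).reshape(n_bins, n_bins)
        joint = joint / a.size
        px = joint.sum(axis=1)
        py = joint.sum(axis=0)
        nz = joint > 0
        out[tau - 1] = float(
            np.sum(joint[nz] * np.log(joint[nz]
                                      / (px[:, None] * py[None, :])[nz]))
        )
    return out


def mutual_information_delay(
    series: np.ndarray,
    max_lag: int,
    smooth: int = 11,
    persist: int = 10,
    return_details: bool = False,
):
    """Embedding delay from the first minimum of lagged mutual information.

    The MI profile is lightly smoothed (moving average, ``smooth`` lags)
    and the first strict local minimum that *persists* — stays below the
    profile for the following ``persist`` lags — and dips below the lag-1
    value by more than the histogram bias floor ``(B-1)^2 / (2N)`` is
    returned.  Fallbacks, in order: the first lag where MI drops to
    ``MI(1)/e``; the smoothed profile's global minimum (deterministic
    signals whose MI never collapses); lag 1.

    With ``return_details=True`` also returns a dict with the profile and
    which rule fired (``local_min`` / ``threshold`` / ``default``).
    """
    from .preprocess import moving_average

    x = np.asarray(series, dtype=float)
    prof = mutual_information_profile(x, max_lag)
    n = x.size
    n_bins = int(np.ceil(np.sqrt(n / 5)))
    floor = (n_bins - 1) ** 2 / (2 * n)
    w = min(smooth, max(1, prof.size // 4))
    if w % 2 == 0:
        w += 1
    if w > 1:
        kernel = np.ones(w) / w
        sm = np.convolve(prof, kernel, mode="valid")
        offset = 1 + (w - 1) // 2
    else:
        sm = prof
        offset = 1
    delay, method = None, None
    m = sm.size
    for i in range(1, m - 1):
        upper = min(i + 1 + persist, m)
        if (sm[i] < sm[i - 1]
                and np.all(sm[i] < sm[i + 1:upper])
                and sm[0] - sm[i] > floor):
            delay, method = i + offset, "local_min"
            break
    if delay is None:
        below = np.flatnonzero(sm <= sm[0] / np.e)
        if below.size:
            delay, method = int(below[0]) + offset, "threshold"
        elif sm.size:
            # no qualified minimum and no 1/e drop (e.g. noiseless
            # deterministic signals, where MI stays high at every lag):
            # use the location of the smoothed profile's global minimum
            delay, method = int(np.argmin(sm)) + offset, "global_min"
        else:
            delay, method = 1, "default"
    if return_details:
        return delay, {"profile": prof, "smoothed": sm, "method": method,
                       "bias_floor": floor}
    return delay


# ---------------------------------------------------------------------------
# false nearest neighbours (diagnostic)
# ---------------------------------------------------------------------------

def false_nearest_neighbors(
    series: np.ndarray,
    delay: int,
    dims: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    rtol: float = 15.0,
    atol: float = 2.0,
    theiler: int = 1,
) -> dict[int, float]:
    """Kennel-style false-nearest-neighbour fraction per candidate dimension.

    A neighbour in dimension d is *false* when adding the (d+1)-th delay
    coordinate inflates the pair distance by more than ``rtol`` relative
    to its d-dimensional distance, or pushes it beyond ``atol`` standard
    deviations of the series.  Diagnostic only: the analysis dimension is
    fixed by configuration, this merely checks it is sufficient.
    """
    x = np.asarray(series, dtype=float)
    sigma = float(np.std(x))
    if sigma == 0:
        raise EstimationError("constant series")
    out: dict[int, float] = {}
    for d in dims:
        span = d * delay  # need the (d+1)-th coordinate for the test
        n_vec = x.size - span
        if n_vec < 10:
            raise EstimationError(
                f"series too short for dimension {d} at delay {delay}"
            )
        states = np.column_stack([x[j * delay:j * delay + n_vec]
                                  for j in range(d)])
        extra = x[span:span + n_vec]
        tree = cKDTree(states)
        # duplicate states (distance below numerical texture) carry no
        # geometric information; skip them when picking the neighbour.
        # k grows until (almost) every state has an admissible neighbour.
        floor = DISTANCE_FLOOR_REL * float(np.sqrt(np.mean(states ** 2)))
        rows = np.arange(n_vec)
        k = min(2 * theiler + 12, n_vec)
        while True:
            dist, idx = tree.query(states, k=k, workers=1)
            nn = np.full(n_vec, -1)
            nd = np.full(n_vec, np.inf)
            for col in range(1, k):
                cand = idx[:, col]
                ok = ((nn < 0) & (np.abs(cand - rows) > theiler)
                      & (dist[:, col] > floor))
                nn[ok] = cand[ok]
                nd[ok] = dist[ok, col]
            valid = nn >= 0
            if valid.mean() >= 0.9 or k >= n_vec:
                break
            k = min(4 * k, n_vec)
        if valid.sum() < 10:
            raise EstimationError(
                f"too few valid neighbour pairs in dimension {d}"
            )
        i = rows[valid]
        j = nn[valid]
        extra_gap = np.abs(extra[i] - extra[j])
        dist_d1 = np.sqrt(nd[valid] ** 2 + extra_gap ** 2)
        false = (extra_gap / nd[valid] > rtol) | (dist_d1 / sigma > atol)
        out[d] = float(np.mean(false))
    return out


# ---------------------------------------------------------------------------
# embedding and divergence
# ---------------------------------------------------------------------------

def delay_embed(series: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """State matrix whose rows are (x_i, x_{i+tau}, ..., x_{i+(dim-1)tau})."""
    x = np.asarray(series, dtype=float)
    span = (params.dim - 1) * params.delay
    n_vec = x.size - span
    if n_vec < 1:
        raise ParameterError(
            f"series of length {x.size} too short for dim={params.dim}, "
            f"delay={params.delay}"
        )
    return np.column_stack([x[j * params.delay:j * params.delay + n_vec]
                            for j in range(params.dim)])


def rosenstein_curve(
    states: np.ndarray,
    theiler: int,
    max_lag: int,
    min_pairs: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Average log divergence of nearest-neighbour state pairs vs lag.

    For each state the nearest Euclidean neighbour with temporal
    separation greater than ``theiler`` is located (exact k-d tree
    search).  At each forward lag the mean natural-log distance over the
    surviving pairs (both members still inside the series) is recorded;
    the curve is truncated when fewer than ``min_pairs`` survive.
    Distances are floored at ``1e-6 x RMS`` of the states — separations
    below numerical texture carry no dynamical information.
    """
    st = np.asarray(states, dtype=float)
    m = st.shape[0]
    if m < 100:
        raise EstimationError(f"need >= 100 state vectors, got {m}")
    tree = cKDTree(st)
    k = min(2 * theiler + 2, m)
    dist, idx = tree.query(st, k=k, workers=1)
    rows = np.arange(m)
    nn = np.full(m, -1)
    for col in range(1, k):
        cand = idx[:, col]
        ok = (nn < 0) & (np.abs(cand - rows) > theiler)
        nn[ok] = cand[ok]
    valid = nn >= 0
    if valid.mean() < 0.5:
        raise EstimationError(
            f"no admissible neighbour for {100 * (1 - valid.mean()):.0f}% "
            "of states (Theiler window too wide for this series)"
        )
    i0 = rows[valid]
    j0 = nn[valid]
    eps = DISTANCE_FLOOR_REL * float(np.sqrt(np.mean(st ** 2)))
    eps = max(eps, 1e-300)
    curve = []
    for lag in range(max_lag + 1):
        alive = (i0 + lag < m) & (j0 + lag < m)
        if int(alive.sum()) < min_pairs:
            break
        d = np.linalg.norm(st[i0[alive] + lag] - st[j0[alive] + lag], axis=1)
        curve.append(float(np.mean(np.log(np.maximum(d, eps)))))
    if len(curve) < 3:
        raise EstimationError("divergence curve shorter than 3 lags")
    curve = np.asarray(curve)
    # when separations never exceed 100x the numerical floor, the curve
    # carries no resolvable divergence — report it flat at the floor
    if curve.max() < np.log(eps) + np.log(100.0):
        curve = np.full_like(curve, np.log(eps))
    return np.arange(len(curve)), curve


def fit_lambda_star(
    lags: np.ndarray,
    mean_log_div: np.ndarray,
    lo: float = 0.10,
    hi: float = 0.90,
    samples_per_unit: int = 200,
) -> DivergenceResult:
    """Least-squares slope of the divergence curve over its 10-90 % climb.

    The curve is min-max normalized only to *locate* the fit region —
    from the first attainment of level ``lo`` to the first attainment of
    ``hi`` — and the slope is fitted on the raw curve, then scaled by
    ``samples_per_unit`` (200 points per stride -> per-stride units; use
    round(1/dt) for signals sampled in physical time).  A curve whose
    total range is below numerical resolution is reported as flat
    (lambda* = 0).
    """
    lags = np.asarray(lags, dtype=float)
    y = np.asarray(mean_log_div, dtype=float)
    if lags.size != y.size or lags.size < 3:
        raise FitError("curve must have >= 3 aligned points")
    if not 0 <= lo < hi <= 1:
        raise ParameterError("need 0 <= lo < hi <= 1")
    y_rng = float(y.max() - y.min())
    if y_rng < FLAT_CURVE_RANGE:
        return DivergenceResult(
            lags=lags, mean_log_div=y, fit_lo_idx=0, fit_hi_idx=y.size - 1,
            lambda_star=0.0, r2=1.0, samples_per_unit=samples_per_unit,
            flags=["flat_curve"],
        )
    c = (y - y.min()) / y_rng
    i_lo = int(np.argmax(c >= lo))
    i_hi = int(np.argmax(c >= hi))
    if i_hi - i_lo + 1 < 3:
        raise FitError(
            f"fit region [{i_lo}, {i_hi}] has fewer than 3 samples"
        )
    sl = slice(i_lo, i_hi + 1)
    slope, intercept = np.polyfit(lags[sl], y[sl], 1)
    pred = slope * lags[sl] + intercept
    ss_tot = float(np.sum((y[sl] - y[sl].mean()) ** 2))
    r2 = 1.0 - float(np.sum((y[sl] - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    lam = float(slope) * samples_per_unit
    if not np.isfinite(lam):
        raise FitError("non-finite slope")
    return DivergenceResult(
        lags=lags, mean_log_div=y, fit_lo_idx=i_lo, fit_hi_idx=i_hi,
        lambda_star=lam, r2=r2, samples_per_unit=samples_per_unit,
    )


def lambda_for_trial(
    record,
    events,
    channels: tuple[str, ...] = ("fz", "copx", "copy"),
    config=None,
) -> dict[str, DivergenceResult]:
    """Full per-trial divergence chain for the requested channels.

    smooth -> stride-normalize (same-side strikes) -> middle-n strides ->
    per-channel MI delay -> fixed-dimension embedding -> Rosenstein curve
    -> magnitude-bounded fit.  Each channel is embedded separately (their
    natural delays differ widely).
    """
    from .io_config import RunConfig
    from .preprocess import (moving_average, normalize_strides,
                             select_middle_strides)

    cfg = config or RunConfig()
    side_strikes = events.side_strikes(cfg.stride_side)
    out: dict[str, DivergenceResult] = {}
    pps = cfg.points_per_stride
    for ch in channels:
        x = moving_average(record.channel(ch), cfg.smooth_window)
        nss = normalize_strides(x, side_strikes, pps, source_channel=ch)
        nss = select_middle_strides(nss, cfg.n_strides)
        delay = mutual_information_delay(
            nss.values, cfg.mi_max_lag, cfg.mi_smooth, cfg.mi_persist
        )
        params = EmbeddingParams(delay=delay, dim=cfg.embed_dim,
                                 theiler=cfg.theiler_window)
        states = delay_embed(nss.values, params)
        lags, curve = rosenstein_curve(
            states, params.theiler, int(cfg.div_max_strides * pps)
        )
        res = fit_lambda_star(lags, curve, cfg.fit_lo, cfg.fit_hi, pps)
        res.params = params
        res.channel = ch
        out[ch] = res
        logger.debug("lambda_for_trial: %s delay=%d lambda*=%.4f r2=%.3f",
                     ch, delay, res.lambda_star, res.r2)
    return out
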