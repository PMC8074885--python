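"""Seeded force-plate data generators with known ground truth.

Two families of records are produced:

* **Quiet standing** (`gen_sway`): planar COP sway as independent
  per-axis stochastic processes with programmable diffusion
  coefficients.  Pure Brownian motion gives a single linear
  mean-square-displacement regime (MSD = 2 D dt per axis); an
  Ornstein-Uhlenbeck variant adds the mean reversion that produces the
  classic two-regime (persistent, then saturating) stabilogram
  diffusion shape, with the regime transition placed at a requested
  interval via internal calibration of the relaxation timescale.

* **Treadmill walking** (`gen_gait`): net (whole-body) vertical GRF and
  COP.  Each step contributes a zero-mean force modulation profile with
  a steep weight-acceptance rise just after the strike and an M-shaped
  top (~1.19 body weight peaks, ~0.89 trough), so the cycle-averaged
  force equals body weight (impulse balance) and exactly one
  body-weight crossing occurs per step.  COPX alternates between
  +/- width/2 with a smooth lateral transition that *precedes* each
  strike (the anticipatory weight shift), plus a small phase-locked
  within-step ripple — real COP is never piecewise-constant, and a
  strictly flat COPX is degenerate under delay embedding.  COPY sweeps
  forward each step and flies back (treadmill butterfly).  Optional
  per-cycle chaotic amplitude modulation (logistic map, r = 3.9) gives
  the record a controllable positive divergence of cycle amplitudes;
  optional additive Gaussian sensor noise is scaled to channel range.

Every generator is a pure function of its spec (seed included).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import lfilter

from .errors import ParameterError, PostureError
from .io_config import ForcePlateRecord, write_forceplate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# quiet standing
# ---------------------------------------------------------------------------

@dataclass
class SwaySpec:
    """Parameters of a synthetic quiet-standing trial.

    ``d_ml`` / ``d_ap`` are the per-axis diffusion coefficients
    (mm^2 s^-1).  With ``regime_switch`` set (seconds), the axes follow
    an Ornstein-Uhlenbeck process whose relaxation timescale is
    calibrated so that the *analytic* MSD curve's two-segment breakpoint
    falls at ``regime_switch``; ``ou_timescale`` sets the relaxation
    time directly instead.  With neither, sway is pure Brownian.
    """

    d_ml: float = 2.0
    d_ap: float = 1.0
    regime_switch: float | None = None
    ou_timescale: float | None = None
    fs: float = 100.0
    duration: float = 30.0
    body_weight_n: float = 700.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_ml < 0 or self.d_ap < 0:
            raise ParameterError("diffusion coefficients must be >= 0")
        if self.fs <= 0 or self.duration <= 0:
            raise ParameterError("fs and duration must be positive")
        if self.duration * self.fs < 100:
            raise ParameterError("trial must span at least 100 samples")


def _analytic_breakpoint(tau: float, fs: float, max_dt: float) -> float:
    """Two-segment breakpoint of the analytic OU MSD curve (unit D)."""
    from .posturography import MSDCurve, detect_critical_point

    max_m = int(np.floor(max_dt * fs))
    dt = np.arange(1, max_m + 1) / fs
    y = 2.0 * tau * (1.0 - np.exp(-dt / tau))  # MSD / D
    curve = MSDCurve(dt=dt, msd_x=y / 2, msd_y=y / 2, msd_r=y,
                     n_pairs=np.full(max_m, 1000))
    b = detect_critical_point(curve, min_improvement=0.0)
    return float(b) if b is not None else max_dt


def _ou_tau_for_breakpoint(target: float, fs: float, max_dt: float) -> float:
    """Relaxation timescale whose analytic MSD breaks at ``target`` s."""
    lo, hi = 0.02, 20.0
    f = lambda tau: _analytic_breakpoint(tau, fs, max_dt) - target
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:  # target outside attainable breakpoints
        raise ParameterError(
            f"regime_switch={target}s not attainable on a {max_dt}s MSD grid"
        )
    return float(brentq(f, lo, hi, xtol=1e-4))


def gen_sway(spec: SwaySpec, msd_max_dt: float = 2.0) -> ForcePlateRecord:
    """Generate one quiet-standing record from a :class:`SwaySpec`."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    tau = spec.ou_timescale
    if tau is None and spec.regime_switch is not None:
        tau = _ou_tau_for_breakpoint(spec.regime_switch, spec.fs, msd_max_dt)

    def axis(d: float) -> np.ndarray:
        if d == 0:
            return np.zeros(n)
        incr = rng.normal(0.0, np.sqrt(2.0 * d / spec.fs), n)
        if tau is None:
            return np.cumsum(incr)
        a = 1.0 - 1.0 / (tau * spec.fs)
        if a <= 0:
            raise ParameterError("ou timescale too short for this rate")
        return lfilter([1.0], [1.0, -a], incr)

    copx = axis(spec.d_ml)
    copy_ = axis(spec.d_ap)
    fz = np.full(n, spec.body_weight_n)
    meta = {
        "kind": "sway", "seed": spec.seed,
        "body_weight_n": spec.body_weight_n,
        "truth_d_ml": spec.d_ml, "truth_d_ap": spec.d_ap,
        "truth_ou_timescale": tau,
        "truth_regime_switch": spec.regime_switch,
    }
    return ForcePlateRecord(time=t, fz=fz, copx=copx, copy=copy_,
                            fs=spec.fs, meta=meta)


# ---------------------------------------------------------------------------
# treadmill walking
# ---------------------------------------------------------------------------

@dataclass
class GaitSpec:
    """Parameters of a synthetic treadmill-walking trial.

    Defaults describe steady adult treadmill walking: cadence 110
    steps/min, step width 100 mm, step-time SD 12 ms, sensor noise 2 %
    of channel range, and a moderate chaotic cycle-amplitude modulation
    (``chaos_gain`` = 0.2; 0 gives strictly periodic cycles).
    """

    body_weight: float = 700.0       # N
    cadence: float = 110.0           # steps / min
    step_width_mm: float = 100.0
    step_time_sd: float = 0.012      # s
    step_width_sd: float = 6.0       # mm, cycle-to-cycle placement noise
    noise_sd_frac: float = 0.02      # fraction of channel range
    n_strides: int = 170
    chaos_gain: float = 0.2
    fs: float = 300.0
    seed: int = 0
    copy_sweep_mm: float = 140.0     # forward COPY excursion per step
    copx_ripple_mm: float = 2.0      # within-step lateral ripple

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ParameterError("cadence must be positive")
        if self.n_strides < 4:
            raise ParameterError("need at least 4 strides")
        if self.noise_sd_frac < 0:
            raise ParameterError("noise_sd_frac must be >= 0")
        if self.body_weight <= 0 or self.fs <= 0:
            raise ParameterError("body_weight and fs must be positive")
        if self.step_time_sd < 0 or self.chaos_gain < 0:
            raise ParameterError("step_time_sd and chaos_gain must be >= 0")
        if self.step_width_sd < 0:
            raise ParameterError("step_width_sd must be >= 0")


@dataclass
class GaitTruth:
    """Ground-truth tables carried alongside a generated gait record."""

    strike_times: np.ndarray   # s, exact (maximal-inclination convention)
    strike_idx: np.ndarray     # nearest sample indices
    sides: np.ndarray          # +1 right / -1 left
    step_durations: np.ndarray  # s, programmed per step
    step_width_mm: float        # programmed mean width
    step_widths: np.ndarray = None  # per-step |COPX level difference|
    spec: GaitSpec = field(repr=False, default=None)

    @property
    def step_times(self) -> np.ndarray:
        """Programmed intervals between consecutive strikes."""
        return np.diff(self.strike_times)


# knots (phase, relative force) of the per-step net-GRF modulation;
# cosine-interpolated, then mean-subtracted so each cycle integrates to
# body weight.  Steep rise over phase 0.07-0.20 = weight acceptance.
_FZ_KNOTS = ((0.0, -0.12), (0.07, -0.15), (0.20, 0.15), (0.33, 0.05),
             (0.45, 0.10), (0.60, -0.02), (0.80, -0.10), (1.0, -0.12))
_PROFILE_RES = 2000


def _cos_interp(phi: np.ndarray, knots) -> np.ndarray:
    out = np.empty_like(phi)
    for (u0, v0), (u1, v1) in zip(knots[:-1], knots[1:]):
        m = (phi >= u0) & (phi <= u1)
        tt = (phi[m] - u0) / (u1 - u0)
        out[m] = v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * tt))
    return out


def _fz_profile() -> tuple[np.ndarray, np.ndarray, float]:
    """Zero-mean per-step profile and its maximal-inclination phase."""
    phi = np.linspace(0.0, 1.0, _PROFILE_RES + 1)
    base = _cos_interp(phi, _FZ_KNOTS)
    p0 = base - base.mean()
    c_star = float(phi[np.argmax(np.diff(p0))])
    return phi, p0, c_star


def gen_gait(spec: GaitSpec) -> tuple[ForcePlateRecord, GaitTruth]:
    """Generate a walking record plus ground-truth event tables.

    Truth strike times use the same convention as the detector: the
    instant of maximal upward inclination of the noiseless net Fz within
    each step's weight-acceptance rise (a fixed phase of the analytic
    profile).
    """
    rng = np.random.default_rng(spec.seed)
    t0 = 60.0 / spec.cadence
    n_steps = 2 * spec.n_strides
    durs = rng.normal(t0, spec.step_time_sd, n_steps)
    durs = np.clip(durs, 0.5 * t0, 1.5 * t0)
    widths = rng.normal(spec.step_width_mm, spec.step_width_sd, n_steps)
    widths = np.clip(widths, 0.2 * spec.step_width_mm,
                     1.8 * spec.step_width_mm)
    pad = 0.6 * t0
    strikes = pad + np.concatenate([[0.0], np.cumsum(durs[:-1])])
    total = strikes[-1] + durs[-1] + pad
    n = int(np.ceil(total * spec.fs))
    t = np.arange(n) / spec.fs
    sides = np.tile([1, -1], spec.n_strides)

    # per-cycle chaotic gains (logistic map; seeded initial condition)
    gains = np.ones(n_steps)
    if spec.chaos_gain > 0:
        z = np.empty(n_steps)
        zi = rng.uniform(0.2, 0.8)
        for i in range(n_steps):
            zi = 3.9 * zi * (1.0 - zi)
            z[i] = zi
        gains = 1.0 + spec.chaos_gain * (2.0 * z - 1.0)

    phi_grid, p0, c_star = _fz_profile()

    # step phase per sample
    edges = np.concatenate([strikes, [strikes[-1] + durs[-1]]])
    step_of = np.searchsorted(edges, t, side="right") - 1
    inside = (step_of >= 0) & (step_of < n_steps)
    phi = np.zeros(n)
    phi[inside] = ((t[inside] - strikes[step_of[inside]])
                   / durs[step_of[inside]])

    # net vertical GRF
    fz = np.full(n, 1.0)
    fz[inside] = 1.0 + gains[step_of[inside]] * np.interp(
        phi[inside], phi_grid, p0)
    pre = t < strikes[0]
    fz[pre] = 1.0 + np.interp(1.0 - (strikes[0] - t[pre]) / t0, phi_grid, p0)
    post = step_of >= n_steps
    fz[post] = 1.0 + p0[0]  # hold at the trough level, no spurious surge
    fz *= spec.body_weight

    # COPX: anticipatory lateral transition finishing just before each
    # strike, plus a small phase-locked within-step ripple.  The plateau
    # level of step i is side_i * width_i / 2.
    levels = sides * widths / 2.0
    lev_prev = np.concatenate([[-levels[0]], levels[:-1]])
    copx = np.full(n, lev_prev[0])
    for i, s in enumerate(strikes):
        d_i = durs[i]
        tr0, tr1 = s - 0.25 * d_i, s - 0.05 * d_i
        seg = (t >= tr0) & (t < tr1)
        u = (t[seg] - tr0) / (tr1 - tr0)
        copx[seg] = (lev_prev[i]
                     + (levels[i] - lev_prev[i]) * 0.5
                     * (1.0 - np.cos(np.pi * u)))
        nxt = (strikes[i + 1] - 0.25 * durs[i + 1]
               if i + 1 < n_steps else np.inf)
        copx[(t >= tr1) & (t < nxt)] = levels[i]
    copx = copx + spec.copx_ripple_mm * np.sin(2.0 * np.pi * phi)

    # COPY: forward sweep per step, cosine flyback over the last 15 %
    cy = np.zeros(n)
    m1 = inside & (phi < 0.85)
    cy[m1] = -0.5 + phi[m1] / 0.85
    m2 = inside & (phi >= 0.85)
    cy[m2] = 0.5 - (1.0 - np.cos(np.pi * (phi[m2] - 0.85) / 0.15)) / 2.0
    cy[~inside & (t < strikes[0])] = -0.5
    cy[~inside & (t >= strikes[0])] = -0.5
    copy_ = cy * spec.copy_sweep_mm
    if spec.chaos_gain > 0:
        amp = np.ones(n)
        amp[inside] = gains[step_of[inside]]
        copy_ = copy_ * amp

    # ground truth before noise
    strike_times = strikes + c_star * durs
    truth = GaitTruth(
        strike_times=strike_times,
        strike_idx=np.round(strike_times * spec.fs).astype(int),
        sides=sides.copy(),
        step_durations=durs.copy(),
        step_width_mm=spec.step_width_mm,
        step_widths=np.abs(np.diff(levels)),
        spec=spec,
    )

    if spec.noise_sd_frac > 0:
        for arr in (fz, copx, copy_):
            rng_span = float(arr.max() - arr.min())
            arr += rng.normal(0.0, spec.noise_sd_frac * rng_span, n)

    meta = {
        "kind": "gait", "seed": spec.seed,
        "body_weight_n": spec.body_weight,
        "truth_cadence": spec.cadence,
        "truth_step_width_mm": spec.step_width_mm,
        "truth_step_time_sd": spec.step_time_sd,
        "truth_chaos_gain": spec.chaos_gain,
        "truth_noise_sd_frac": spec.noise_sd_frac,
    }
    record = ForcePlateRecord(time=t, fz=fz, copx=copx, copy=copy_,
                              fs=spec.fs, meta=meta)
    return record, truth


# ---------------------------------------------------------------------------
# multi-condition experiments
# ---------------------------------------------------------------------------

def _trial_seed(master: int, *key: int) -> int:
    """Stable per-trial seed derived from the master seed (< 2^31)."""
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def gen_experiment(
    base_spec,
    effect_map: dict[str, dict],
    n_subjects: int,
    n_trials: int,
    seed: int,
    out_dir: str | Path | None = None,
    force: bool = False,
):
    """Generate a subjects x conditions x trials dataset.

    ``effect_map`` maps condition label -> spec-field overrides applied on
    top of ``base_spec`` (a :class:`SwaySpec` or :class:`GaitSpec`).  The
    per-trial seed is derived deterministically from ``seed`` and the
    (subject, condition, trial) coordinates, so the whole dataset — and
    its manifest — is reproducible from the master seed.

    With ``out_dir`` set, per-trial CSVs named ``S{s}_{cond}_{t}.csv``
    and a ``manifest.tsv`` are written; otherwise records are returned in
    memory as ``(subject, condition, trial, record, truth_or_none)``.
    """
    import dataclasses as _dc

    is_gait = isinstance(base_spec, GaitSpec)
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not force:
            raise PostureError(
                f"output directory {out_dir} is not empty (use force=True)"
            )
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    results = []
    conditions = list(effect_map)
    for s in range(1, n_subjects + 1):
        for ci, cond in enumerate(conditions):
            overrides = dict(effect_map[cond])
            for trial in range(1, n_trials + 1):
                tseed = _trial_seed(seed, s, ci, trial)
                spec = _dc.replace(base_spec, seed=tseed, **overrides)
                if is_gait:
                    record, truth = gen_gait(spec)
                else:
                    record, truth = gen_sway(spec), None
                record.meta.update(subject=f"S{s}", condition=cond,
                                   trial=trial)
                row = {"subject": f"S{s}", "condition": cond, "trial": trial,
                       "seed": tseed}
                row.update({f"truth_{k}": v for k, v in overrides.items()})
                if out_dir is not None:
                    fname = f"S{s}_{cond}_{trial}.csv"
                    write_forceplate(record, out_dir / fname)
                    row["file"] = fname
                else:
                    results.append((f"S{s}", cond, trial, record, truth))
                rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
        logger.info("gen_experiment: wrote %d trials to %s", len(rows), out_dir)
        return manifest
    return results, manifest
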