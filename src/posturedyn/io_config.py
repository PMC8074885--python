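"""Force-plate record I/O and run configuration.

A :class:`ForcePlateRecord` carries synchronized vertical ground reaction
force (Fz, N) and planar centre-of-pressure coordinates (COPX medio-lateral,
COPY anterior-posterior, both mm) on a uniform time grid.  All analyses in
this package consume this one container.  Units are fixed internally to
N / mm / s; loaders convert on the way in.

Sign convention: +X is rightward, +Y is forward.  The convention is
arbitrary — every metric downstream is range-based or sign-invariant —
but it is stated so that event side labels (left/right heel-strike) are
interpretable.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParameterError, SamplingError, ValidationError

logger = logging.getLogger(__name__)

#: default mapping from canonical channel names to file column names
DEFAULT_COLUMNS: dict[str, str] = {
    "time": "time",
    "fz": "fz",
    "copx": "copx",
    "copy": "copy",
}

_TIME_TOL = 1e-6  # relative tolerance on the sample interval


@dataclass
class ForcePlateRecord:
    """Synchronized force-plate time series.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, uniform grid.
    fz : array of float
        Vertical ground reaction force, N.
    copx, copy : array of float
        Centre-of-pressure coordinates, mm (medio-lateral / anterior-posterior).
    fs : float
        Sampling rate, Hz.
    meta : dict
        Free-form metadata (subject, condition, trial, body_weight_n, ...).
    """

    time: np.ndarray
    fz: np.ndarray
    copx: np.ndarray
    copy: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fz = np.asarray(self.fz, dtype=float)
        self.copx = np.asarray(self.copx, dtype=float)
        self.copy = np.asarray(self.copy, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValidationError("record needs at least 2 samples")
        for name in ("fz", "copx", "copy"):
            if getattr(self, name).size != n:
                raise ValidationError(
                    f"channel {name!r} has {getattr(self, name).size} samples, "
                    f"expected {n}"
                )
        if not self.fs > 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        for name in ("time", "fz", "copx", "copy"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                bad = np.flatnonzero(~np.isfinite(arr))
                raise ValidationError(
                    f"channel {name!r} contains non-finite values at rows "
                    f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}"
                )
        step = 1.0 / self.fs
        dt = np.diff(self.time)
        if np.any(np.abs(dt - step) > _TIME_TOL * max(step, 1.0)):
            worst = float(np.abs(dt - step).max())
            raise SamplingError(
                f"time grid deviates from 1/fs={step:g} s by up to {worst:g} s"
            )

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n/fs)."""
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        if name not in ("fz", "copx", "copy"):
            raise ParameterError(f"unknown channel {name!r}")
        return getattr(self, name)

    def replace(self, **kwargs) -> "ForcePlateRecord":
        """Return a copy with some fields replaced (channels are copied)."""
        out = dataclasses.replace(self, **kwargs)
        return out

    def body_weight(self) -> float:
        """Body weight in N.

        Taken from ``meta['body_weight_n']`` when present, otherwise
        estimated as the median of Fz — over many gait cycles (or quiet
        standing) the median vertical force approximates body weight.
        """
        bw = self.meta.get("body_weight_n")
        if bw is not None:
            return float(bw)
        return float(np.median(self.fz))


def read_forceplate(
    path: str | Path,
    fs_expected: float | None = None,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    unit_scale: Mapping[str, float] | None = None,
) -> ForcePlateRecord:
    """Read a delimited-text force-plate file into a validated record.

    Parameters
    ----------
    path : path
        CSV/TSV file with a header row naming the time/fz/copx/copy columns.
    fs_expected : float, optional
        If given, the rate inferred from the time column must match within
        the grid tolerance.
    column_map : mapping, optional
        Maps canonical names (``time``, ``fz``, ``copx``, ``copy``) to the
        file's column names.  Defaults to identity.
    delimiter : str, optional
        Field delimiter; inferred from the suffix when omitted
        (``.tsv`` -> tab, otherwise comma).
    unit_scale : mapping, optional
        Multiplicative factors applied per canonical channel to convert to
        N / mm / s (e.g. ``{"copx": 1000.0}`` for metres -> mm).
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=delimiter)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing column(s) {missing}; found {list(df.columns)}"
        )
    data = {k: df[v].to_numpy(dtype=float) for k, v in cols.items()}
    nan_rows = np.flatnonzero(
        ~np.all(np.isfinite(np.column_stack(list(data.values()))), axis=1)
    )
    if nan_rows.size:
        raise ValidationError(
            f"{path.name}: non-finite values in rows "
            f"{nan_rows[:20].tolist()}{'...' if nan_rows.size > 20 else ''}"
        )
    if unit_scale:
        for k, s in unit_scale.items():
            data[k] = data[k] * float(s)
    t = data["time"]
    dt = np.diff(t)
    if t.size < 2:
        raise ValidationError(f"{path.name}: fewer than 2 samples")
    step = float(np.median(dt))
    if step <= 0:
        raise SamplingError(f"{path.name}: non-increasing time column")
    fs = 1.0 / step
    if fs_expected is not None and abs(fs - fs_expected) > _TIME_TOL * fs_expected:
        raise SamplingError(
            f"{path.name}: inferred rate {fs:g} Hz != expected {fs_expected:g} Hz"
        )
    meta = {"source": str(path)}
    logger.debug("io_config.read_forceplate: %s (%d samples, %.6g Hz)",
                 path.name, t.size, fs)
    return ForcePlateRecord(
        time=t, fz=data["fz"], copx=data["copx"], copy=data["copy"],
        fs=fs, meta=meta,
    )


def write_forceplate(
    record: ForcePlateRecord,
    path: str | Path,
    delimiter: str | None = None,
    float_format: str = "%.10g",
) -> None:
    """Write a record back to delimited text (inverse of `read_forceplate`)."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame(
        {"time": record.time, "fz": record.fz,
         "copx": record.copx, "copy": record.copy}
    )
    df.to_csv(path, sep=delimiter, index=False, float_format=float_format)


#: stable column order of tidy results tables
RESULT_COLUMNS = ("subject", "condition", "trial", "parameter", "value", "flags")


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy results table as TSV with a stable column order.

    Rows carry subject / condition / trial / parameter / value (plus an
    optional ``flags`` column).  An empty table produces a header-only file.
    """
    path = Path(path)
    df = table.copy()
    if "flags" not in df.columns:
        df["flags"] = ""
    extra = [c for c in df.columns if c not in RESULT_COLUMNS]
    df = df[[*RESULT_COLUMNS, *extra]] if len(df) else pd.DataFrame(
        columns=[*RESULT_COLUMNS, *extra]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    logger.info("io_config.write_results: %d rows -> %s", len(df), path)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable analysis settings, with defaults reproducing the
    reference pipeline (15 Hz / order-2 low-pass, 10-point smoothing,
    200 points per stride, middle 150 strides, embedding dimension 5,
    10-90 % divergence fit bounds, first/last 10 steps excluded)."""

    # low-pass filter for standing COP
    filter_cutoff_hz: float = 15.0
    filter_order: int = 2
    # stabilogram diffusion analysis
    sda_max_dt_s: float = 2.0
    sda_fit_window_s: tuple[float, float] = (0.02, 0.5)
    sda_min_improvement: float = 0.05
    sda_truncate_at_critical: bool = True
    # walking preprocessing
    smooth_window: int = 10
    points_per_stride: int = 200
    n_strides: int = 150
    stride_side: str = "right"
    # heel-strike detection
    hs_copx_mad_k: float = 3.0
    hs_lookback_frac: float = 0.4
    hs_prominence_frac: float = 0.10
    hs_min_separation_frac: float = 0.5
    # step metrics
    n_trim_steps: int = 10
    # embedding / divergence
    embed_dim: int = 5
    mi_max_lag: int = 200
    mi_smooth: int = 11
    mi_persist: int = 10
    theiler: int | None = None  # None -> points_per_stride
    div_max_strides: float = 10.0
    fit_lo: float = 0.10
    fit_hi: float = 0.90
    channels: tuple[str, ...] = ("fz", "copx", "copy")
    # bookkeeping
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def check(cond: bool, msg: str) -> None:
            if not cond:
                raise ParameterError(f"RunConfig: {msg}")

        check(self.filter_cutoff_hz > 0, "filter_cutoff_hz must be > 0")
        check(self.filter_order >= 1, "filter_order must be >= 1")
        check(self.sda_max_dt_s > 0, "sda_max_dt_s must be > 0")
        lo, hi = self.sda_fit_window_s
        check(0 <= lo < hi, "sda_fit_window_s must satisfy 0 <= lo < hi")
        check(0 <= self.sda_min_improvement < 1, "sda_min_improvement in [0,1)")
        check(self.smooth_window >= 1, "smooth_window must be >= 1")
        check(self.points_per_stride >= 10, "points_per_stride must be >= 10")
        check(self.n_strides >= 2, "n_strides must be >= 2")
        check(self.stride_side in ("left", "right"), "stride_side left|right")
        check(self.hs_copx_mad_k > 0, "hs_copx_mad_k must be > 0")
        check(0 < self.hs_lookback_frac <= 2, "hs_lookback_frac in (0,2]")
        check(0 <= self.hs_prominence_frac < 1, "hs_prominence_frac in [0,1)")
        check(self.n_trim_steps >= 0, "n_trim_steps must be >= 0")
        check(self.embed_dim >= 2, "embed_dim must be >= 2")
        check(self.mi_max_lag >= 3, "mi_max_lag must be >= 3")
        check(self.theiler is None or self.theiler >= 0, "theiler must be >= 0")
        check(self.div_max_strides > 0, "div_max_strides must be > 0")
        check(0 <= self.fit_lo < self.fit_hi <= 1, "0 <= fit_lo < fit_hi <= 1")
        for ch in self.channels:
            check(ch in ("fz", "copx", "copy"), f"unknown channel {ch!r}")

    @property
    def theiler_window(self) -> int:
        return self.points_per_stride if self.theiler is None else self.theiler

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sda_fit_window_s", "channels"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["sda_fit_window_s"] = list(d["sda_fit_window_s"])
        d["channels"] = list(d["channels"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
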