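"""Batch orchestration: directories of trials in, tidy parameter tables out.

Each trial contributes one row per parameter; per-trial failures are
flagged and the run continues, so one corrupted file never sinks a
batch.  Statistical modelling is deliberately out of scope — the tidy
table is the hand-off point for external mixed-model analysis.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path

import pandas as pd

from . import __version__
from .dynamics import lambda_for_trial
from .errors import PostureError
from .gait_events import detect_heel_strikes, step_metrics
from .io_config import ForcePlateRecord, RunConfig, read_forceplate, write_results
from .posturography import analyze_standing
from .preprocess import moving_average

logger = logging.getLogger(__name__)

#: filenames look like SUBJ_COND_TRIAL.csv
_NAME_RE = re.compile(r"^(?P<subject>[^_]+)_(?P<cond>.+)_(?P<trial>\d+)$")


def parse_trial_name(path: Path) -> tuple[str, str, str]:
    m = _NAME_RE.match(path.stem)
    if m:
        return m.group("subject"), m.group("cond"), m.group("trial")
    return path.stem, "unknown", "1"


def _rows(subject, condition, trial, values: dict, flags: str = ""):
    return [
        {"subject": subject, "condition": condition, "trial": trial,
         "parameter": k, "value": v, "flags": flags}
        for k, v in values.items()
    ]


def _iter_trials(input_dir, config):
    input_dir = Path(input_dir)
    files = sorted(input_dir.glob("*.csv")) + sorted(input_dir.glob("*.tsv"))
    files = [f for f in files if f.stem != "manifest"]
    if not files:
        raise PostureError(f"no trial files found in {input_dir}")
    for f in files:
        yield (f, *parse_trial_name(f))


def standing_record_rows(record: ForcePlateRecord, subject, condition, trial,
                         config: RunConfig) -> list[dict]:
    """Analysis rows for one standing trial (already loaded)."""
    diff, summary, _curve = analyze_standing(record, config)
    values = {
        "dxs": diff.dxs, "dys": diff.dys, "drs": diff.drs,
        "ln_dxs": summary.ln_dxs, "ln_dys": summary.ln_dys,
        "ln_drs": summary.ln_drs,
        "range_ml": summary.range_ml, "range_ap": summary.range_ap,
        "srd": summary.srd, "r2_r": diff.r2_r,
        "critical_point": (diff.critical_point
                           if diff.critical_point is not None else float("nan")),
    }
    flags = ";".join(diff.flags + summary.flags)
    return _rows(subject, condition, trial, values, flags)


def run_standing(
    input_dir,
    config: RunConfig | None = None,
    out_path=None,
) -> pd.DataFrame:
    """Process a directory of standing trials into a tidy table."""
    cfg = config or RunConfig()
    rows = []
    n_fail = 0
    for f, subject, condition, trial in _iter_trials(input_dir, cfg):
        try:
            record = read_forceplate(f)
            rows.extend(standing_record_rows(record, subject, condition,
                                             trial, cfg))
        except PostureError as exc:
            n_fail += 1
            logger.error("standing trial %s failed: %s", f.name, exc)
            rows.append({"subject": subject, "condition": condition,
                         "trial": trial, "parameter": "error",
                         "value": float("nan"),
                         "flags": f"failed:{type(exc).__name__}:{exc}"})
    table = pd.DataFrame(rows)
    if out_path is not None:
        write_results(table, out_path)
        _write_sidecar(out_path, cfg, n_fail)
    return table


def walking_record_rows(record: ForcePlateRecord, subject, condition, trial,
                        config: RunConfig) -> list[dict]:
    """Analysis rows for one walking trial (already loaded)."""
    events = detect_heel_strikes(
        record,
        smooth_window=config.smooth_window,
        copx_mad_k=config.hs_copx_mad_k,
        lookback_frac=config.hs_lookback_frac,
        prominence_frac=config.hs_prominence_frac,
        min_separation_frac=config.hs_min_separation_frac,
    )
    copx_s = moving_average(record.copx, config.smooth_window)
    metrics = step_metrics(events, copx_s, config.n_trim_steps)
    values = {
        "n_strikes": float(events.n_events),
        "median_step_time": metrics.median_time,
        "mad_step_time": metrics.mad_time,
        "median_step_width": metrics.median_width,
        "mad_step_width": metrics.mad_width,
    }
    flags = list(events.faults)
    lam = lambda_for_trial(record, events, config.channels, config)
    for ch, res in lam.items():
        values[f"lambda_{ch}"] = res.lambda_star
        values[f"lambda_{ch}_r2"] = res.r2
        values[f"delay_{ch}"] = float(res.params.delay)
        flags.extend(f"{ch}:{fl}" for fl in res.flags)
    return _rows(subject, condition, trial, values, ";".join(flags))


def run_walking(
    input_dir,
    config: RunConfig | None = None,
    out_path=None,
) -> pd.DataFrame:
    """Process a directory of walking trials into a tidy table."""
    cfg = config or RunConfig()
    rows = []
    n_fail = 0
    for f, subject, condition, trial in _iter_trials(input_dir, cfg):
        try:
            record = read_forceplate(f)
            rows.extend(walking_record_rows(record, subject, condition,
                                            trial, cfg))
        except PostureError as exc:
            n_fail += 1
            logger.error("walking trial %s failed: %s", f.name, exc)
            rows.append({"subject": subject, "condition": condition,
                         "trial": trial, "parameter": "error",
                         "value": float("nan"),
                         "flags": f"failed:{type(exc).__name__}:{exc}"})
    table = pd.DataFrame(rows)
    if out_path is not None:
        write_results(table, out_path)
        _write_sidecar(out_path, cfg, n_fail)
    return table


def _write_sidecar(out_path, cfg: RunConfig, n_failures: int) -> None:
    """Echo full configuration next to a results table (provenance)."""
    out_path = Path(out_path)
    meta = {
        "package": "posturedyn",
        "version": __version__,
        "n_trial_failures": n_failures,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
    }
    sidecar = out_path.with_suffix(out_path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
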