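"""End-to-end pipeline: simulate -> detect -> fit, exchanged via files.

Stages share no hidden state: the simulation stage writes spike/event
CSVs and a ground-truth table, detection reads them back, and the fit
stage consumes the detection output.  Every output carries the config
hash and seed so a run is reproducible byte-for-byte from its YAML
config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect as det
from . import io as dio
from . import simulate as sim
from .fits import fit_gaussian_window

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is invalid (pre-flight failure)."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_CONFIG = {
    "scenario": "mea",
    "seed": 0,
    "time_scale": 10.0,
    "mea": {
        "pds": [7, 10, 11, 12, 13, 14, 15, 16, 19, 22, 25],
        "n_electrodes": 50,
        "noise": 1.0,
        "window": [0.26, 12.99, 0.65],
    },
    "detection": {},
    "fits": [{"model": "gaussian"}],
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    merged = {**DEFAULT_CONFIG, **cfg}
    merged["mea"] = {**DEFAULT_CONFIG["mea"], **(cfg.get("mea") or {})}
    if merged["scenario"] not in ("mea",):
        raise ConfigError(f"unknown scenario {merged['scenario']!r}")
    if not merged["mea"]["pds"]:
        raise ConfigError("mea.pds must not be empty")
    for key in ("spike_table", "events"):  # optional pre-existing inputs
        if key in cfg and not Path(cfg[key]).exists():
            raise ConfigError(f"configured file does not exist: {cfg[key]}")
    unknown = set(merged["detection"]) - {f.name for f in det.DetectionConfig.__dataclass_fields__.values()}
    if unknown:
        raise ConfigError(f"unknown detection option(s): {sorted(unknown)}")
    return merged


def _write_csv(df: pd.DataFrame, path: Path, chash: str, seed: int) -> None:
    with open(path, "w") as f:
        f.write(f"# config_hash={chash} seed={seed}\n")
        df.to_csv(f, index=False)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute simulate -> detect -> fit; returns the summary dict.

    Outputs under ``out_dir``: per-PD spike/event/ground-truth CSVs,
    ``response_calls.csv``, ``rr_table.csv``, ``window_fit.json`` and
    ``summary.json``.  A stage failure aborts with the stage name;
    partial outputs are preserved.
    """
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = int(config["seed"])
    ts = float(config["time_scale"])
    mea = config["mea"]

    # --- simulate
    sim_dir = out / "sim"
    sim_dir.mkdir(exist_ok=True)
    try:
        truth_frames = []
        for i, pd_day in enumerate(mea["pds"]):
            trains, schedule, truth = sim.simulate_mea_session(
                pd_day,
                n_electrodes=int(mea["n_electrodes"]),
                window=tuple(mea["window"]),
                noise=float(mea["noise"]),
                seed=seed + i,
                time_scale=ts,
            )
            dio.write_spike_table(trains, sim_dir / f"spikes_pd{pd_day:02d}.csv")
            dio.write_events(schedule, sim_dir / f"events_pd{pd_day:02d}.csv")
            truth_frames.append(truth)
        truth_all = pd.concat(truth_frames, ignore_index=True)
        _write_csv(truth_all, sim_dir / "ground_truth.csv", chash, seed)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    # --- detect
    try:
        cfg = det.DetectionConfig(**config["detection"]).compressed(ts)
        calls_rows = []
        rr_rows = []
        for pd_day in mea["pds"]:
            trains = dio.load_spike_table(sim_dir / f"spikes_pd{pd_day:02d}.csv")
            schedule = dio.load_events(sim_dir / f"events_pd{pd_day:02d}.csv")
            onset = float(schedule.onsets("drug_on")[0])
            dlg = [t for t in trains if t.region == "DLG"]
            calls = det.detect_session(dlg, onset, cfg)
            for c in calls:
                calls_rows.append(dict(pd=pd_day, unit_id=c.unit_id, responsive=c.responsive,
                                       direction=c.direction, amplitude=c.amplitude,
                                       baseline_mean=c.baseline_mean, baseline_sd=c.baseline_sd))
            rr_rows.append(dict(pd=pd_day,
                                rr=det.responsiveness_ratio(calls, int(mea["n_electrodes"]))))
        calls_df = pd.DataFrame(calls_rows)
        rr_df = pd.DataFrame(rr_rows)
        _write_csv(calls_df, out / "response_calls.csv", chash, seed)
        _write_csv(rr_df, out / "rr_table.csv", chash, seed)
    except Exception as e:  # noqa: BLE001
        raise StageError("detect", e) from e

    # --- fit
    summary: dict = {"config_hash": chash, "seed": seed, "rr_by_pd": rr_df.to_dict("records")}
    try:
        for spec_ in config["fits"]:
            if spec_["model"] == "gaussian":
                fit = fit_gaussian_window(rr_df["pd"], rr_df["rr"])
                report = {"model": "gaussian", "kappa": fit.kappa, "mu": fit.mu,
                          "sigma": fit.sigma, "se": fit.se, "tvalues": fit.tvalues,
                          "n": fit.n, "config_hash": chash, "seed": seed}
                dio.write_fit_report(report, out / "window_fit.json")
                summary["window_fit"] = {k: report[k] for k in ("kappa", "mu", "sigma")}
    except Exception as e:  # noqa: BLE001
        raise StageError("fit", e) from e

    # confusion of detector calls vs ground truth
    merged = calls_df.merge(truth_all[truth_all.region == "DLG"], on=["pd", "unit_id"],
                            suffixes=("_call", "_truth"))
    tp = int(((merged.responsive_call) & (merged.responsive_truth)).sum())
    fp = int(((merged.responsive_call) & (~merged.responsive_truth)).sum())
    fn = int(((~merged.responsive_call) & (merged.responsive_truth)).sum())
    tn = int(((~merged.responsive_call) & (~merged.responsive_truth)).sum())
    summary["confusion"] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    dio.write_fit_report(summary, out / "summary.json")
    return summary
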