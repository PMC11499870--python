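"""End-to-end orchestration: simulate → analyze → summarize.

A single YAML file configures every stage (see :func:`validate_config`
for the schema); :func:`run_pipeline` executes a subset of stages in
dependency order inside one output directory, logging each stage and
writing exactly one ``manifest.json`` capturing command, config hash,
seeds and outputs so that deterministic stages reproduce byte-for-byte
from the manifest inputs.

Stages
------
simulate-imaging   synthetic experiment          → experiment.h5 (+ truth sidecars)
analyze-tuning     per-session PO tables         → tuning.csv
drift-stats        drift records, shuffles       → drift_records.csv, drift_summary.json
simulate-model     network protocol runs         → model_po.csv, model_run.json
model-analysis     deprivation stats, shuffles   → model_analysis.json
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .drift import convergence_summary, make_drift_records, shuffle_test
from .errors import ConfigValidationError, DependencyError, ParameterError
from .network import (
    DriftTrajectory,
    ModelConfig,
    Phase,
    PlasticityModel,
    ProtocolSpec,
    deprivation_analysis,
)
from .synthetic import SyntheticConfig, generate_experiment, load_experiment, save_experiment
from .tuning import analyze_sessions

__all__ = ["RunManifest", "validate_config", "run_pipeline", "STAGES"]

log = logging.getLogger("driftsteer")

STAGES = ("simulate-imaging", "analyze-tuning", "drift-stats",
          "simulate-model", "model-analysis")

_SECTIONS = {"imaging", "analysis", "model", "protocol"}


@dataclass
class RunManifest:
    """Provenance record written once per output directory."""

    command: str
    config_hash: str
    seed: int
    inputs: dict
    outputs: list
    package_version: str = __version__
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, out_dir: Path):
        with open(Path(out_dir) / "manifest.json", "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @staticmethod
    def read(out_dir: Path) -> "RunManifest":
        with open(Path(out_dir) / "manifest.json") as fh:
            return RunManifest(**json.load(fh))


def _check_section(raw: dict, name: str, cls, problems: list) -> dict:
    section = raw.get(name, {}) or {}
    if not isinstance(section, dict):
        problems.append(f"section '{name}' must be a mapping")
        return {}
    allowed = {f.name for f in dataclasses.fields(cls)}
    for key in section:
        if key not in allowed:
            problems.append(f"unknown key '{name}.{key}'")
    kwargs = {k: v for k, v in section.items() if k in allowed}
    if "session_days" in kwargs:
        kwargs["session_days"] = tuple(kwargs["session_days"])
    try:
        cls(**kwargs)
    except ParameterError as exc:
        problems.append(f"section '{name}': {exc}")
    except TypeError as exc:
        problems.append(f"section '{name}': {exc}")
    return kwargs


_ANALYSIS_KEYS = {"n_boot": 1000, "alpha": 0.05, "experienced": None,
                  "n_shuffle": 1000, "drop_fraction": 0.0}
_PROTOCOL_KEYS = {"kind": "baseline", "n_days": 20, "theta_hat": -30.0,
                  "period_days": 7, "exposure_fraction": 0.25,
                  "measure_every": 1, "ensemble_size": 1, "scale": 1}


def validate_config(config_path) -> dict:
    """Parse and validate a pipeline YAML file.

    Returns a dict with keys ``imaging`` (SyntheticConfig), ``analysis``
    (plain dict), ``model`` (ModelConfig) and ``protocol`` (plain dict).
    All violations are aggregated into one
    :class:`ConfigValidationError`; unknown keys are rejected.
    """
    path = Path(config_path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems = []
    if not isinstance(raw, dict):
        raise ConfigValidationError(["top level must be a mapping"])
    for key in raw:
        if key not in _SECTIONS:
            problems.append(f"unknown section '{key}'")

    imaging_kw = _check_section(raw, "imaging", SyntheticConfig, problems)
    model_kw = _check_section(raw, "model", ModelConfig, problems)

    analysis = dict(_ANALYSIS_KEYS)
    for key, val in (raw.get("analysis", {}) or {}).items():
        if key not in _ANALYSIS_KEYS:
            problems.append(f"unknown key 'analysis.{key}'")
        else:
            analysis[key] = val
    if not (isinstance(analysis["n_boot"], int) and analysis["n_boot"] >= 100):
        problems.append("analysis.n_boot must be an integer >= 100")
    if not 0.0 <= float(analysis["drop_fraction"]) < 1.0:
        problems.append("analysis.drop_fraction must lie in [0, 1)")

    protocol = dict(_PROTOCOL_KEYS)
    for key, val in (raw.get("protocol", {}) or {}).items():
        if key not in _PROTOCOL_KEYS:
            problems.append(f"unknown key 'protocol.{key}'")
        else:
            protocol[key] = val
    if protocol["kind"] not in ("baseline", "deprivation", "interrupted_deprivation", "recovery"):
        problems.append("protocol.kind must be baseline|deprivation|interrupted_deprivation|recovery")

    if problems:
        raise ConfigValidationError(problems)
    return {"imaging": SyntheticConfig(**imaging_kw), "analysis": analysis,
            "model": ModelConfig(**model_kw), "protocol": protocol,
            "_raw": raw}


def _build_protocol(p: dict) -> ProtocolSpec:
    kind, nd, th = p["kind"], int(p["n_days"]), p["theta_hat"]
    common = dict(measure_every=int(p["measure_every"]), ensemble_size=int(p["ensemble_size"]))
    if kind == "baseline":
        phases = (Phase("baseline", nd),)
    elif kind == "deprivation":
        phases = (Phase("deprivation", nd, theta_hat=th),)
    elif kind == "interrupted_deprivation":
        phases = (Phase("interrupted_deprivation", nd, theta_hat=th,
                        period_days=int(p["period_days"]),
                        exposure_fraction=float(p["exposure_fraction"])),)
    else:  # recovery: equal-length deprivation then baseline
        phases = (Phase("deprivation", nd, theta_hat=th), Phase("baseline", nd))
    return ProtocolSpec(phases=phases, **common)


def run_pipeline(config_path, stages, seed: int = 0, out_dir="driftsteer_out",
                 scale: int | None = None) -> RunManifest:
    """Run the requested stages in dependency order.

    Missing upstream outputs raise :class:`DependencyError`; any stage
    failure propagates (the CLI maps it to a non-zero exit status).
    Stage seeds are fixed offsets of ``seed`` so stage subsets compose
    reproducibly.
    """
    requested = set(stages)
    bad = requested - set(STAGES)
    if bad:
        raise ParameterError(f"unknown stage(s) {sorted(bad)}; choose from {STAGES}")
    stages = [s for s in STAGES if s in requested]
    if not stages:
        raise ParameterError(f"no valid stages requested (choose from {STAGES})")
    cfg = validate_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    h5_path = out / "experiment.h5"
    tuning_path = out / "tuning.csv"
    po_path = out / "model_po.csv"
    trajectories = None

    for stage in stages:
        t0 = time.time()
        if stage == "simulate-imaging":
            icfg = dataclasses.replace(cfg["imaging"], seed=seed)
            sessions, truth = generate_experiment(icfg)
            save_experiment(h5_path, sessions, truth, config=icfg)
            outputs += [h5_path.name, h5_path.name + ".truth.csv", h5_path.name + ".truth.json"]
            log.info("simulate-imaging: %d neurons, %d sessions (%.1fs)",
                     icfg.n_neurons, icfg.n_sessions, time.time() - t0)
        elif stage == "analyze-tuning":
            if not h5_path.exists():
                raise DependencyError("analyze-tuning needs experiment.h5 (run simulate-imaging)")
            sessions, _ = load_experiment(h5_path)
            table = analyze_sessions(sessions, n_boot=cfg["analysis"]["n_boot"],
                                     seed=seed + 1, alpha=cfg["analysis"]["alpha"])
            table.rename(columns={"po": "po_deg", "ci_low": "ci_low_deg",
                                  "ci_high": "ci_high_deg", "ci_width": "ci_width_deg"}
                         ).to_csv(tuning_path, index=False)
            outputs.append(tuning_path.name)
            log.info("analyze-tuning: %d rows, %.1f%% tuned (%.1fs)",
                     len(table), 100 * table["tuned"].mean(), time.time() - t0)
        elif stage == "drift-stats":
            if not tuning_path.exists():
                raise DependencyError("drift-stats needs tuning.csv (run analyze-tuning)")
            table = pd.read_csv(tuning_path)
            experienced = cfg["analysis"]["experienced"]
            records = make_drift_records(table, experienced=experienced)
            records.to_csv(out / "drift_records.csv", index=False)
            summary = {"n_records": int(len(records)),
                       "median_drift_magnitude": float(records["drift_magnitude"].median())
                       if len(records) else None,
                       "significant_fraction": float(records["significant"].mean())
                       if len(records) else None}
            if experienced is not None and len(records):
                rng = np.random.default_rng(seed + 2)
                med, ci = convergence_summary(records, rng=rng)
                summary["median_convergence"] = med
                summary["convergence_ci95"] = list(ci)
                for mode in ("magnitude", "direction"):
                    sh = shuffle_test(records, mode, n_shuffle=cfg["analysis"]["n_shuffle"], rng=rng)
                    summary[f"shuffle_{mode}_median"] = float(np.median(sh.medians))
                    summary[f"shuffle_{mode}_ci95"] = list(sh.ci())
            with open(out / "drift_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            outputs += ["drift_records.csv", "drift_summary.json"]
            log.info("drift-stats: %d records (%.1fs)", len(records), time.time() - t0)
        elif stage == "simulate-model":
            proto = _build_protocol(cfg["protocol"])
            eff_scale = int(scale if scale is not None else cfg["protocol"]["scale"])
            model = PlasticityModel(cfg["model"], scale=eff_scale)
            res = model.simulate(proto, seed=seed + 3)
            trajectories = res.trajectories
            frames = []
            for i, traj in enumerate(trajectories):
                df = traj.to_frame()
                df.insert(0, "iteration", i)
                frames.append(df)
            pd.concat(frames, ignore_index=True).to_csv(po_path, index=False)
            with open(out / "model_run.json", "w") as fh:
                json.dump({"config": model.config.to_dict(),
                           "protocol_kind": cfg["protocol"]["kind"],
                           "n_days": proto.n_days,
                           "ensemble": res.n_iter,
                           "max_norm_deviation": res.max_norm_deviation(),
                           "median_drift_rates": res.median_drift_rates().tolist()}, fh, indent=2)
            outputs += [po_path.name, "model_run.json"]
            log.info("simulate-model: %d days x %d iterations (%.1fs)",
                     proto.n_days, res.n_iter, time.time() - t0)
        elif stage == "model-analysis":
            if trajectories is None:
                if not po_path.exists():
                    raise DependencyError("model-analysis needs model_po.csv (run simulate-model)")
                trajectories = _load_trajectories(po_path)
            theta = float(cfg["protocol"]["theta_hat"])
            rng = np.random.default_rng(seed + 4)
            per_iter = []
            for traj in trajectories:
                summ = deprivation_analysis(traj, theta)
                med, ci = convergence_summary(summ.records, rng=rng)
                entry = {"spearman_r": summ.spearman_r, "spearman_p": summ.spearman_p,
                         "median_convergence": med, "convergence_ci95": list(ci)}
                for mode in ("magnitude", "direction"):
                    sh = shuffle_test(summ.records, mode,
                                      n_shuffle=cfg["analysis"]["n_shuffle"], rng=rng)
                    entry[f"shuffle_{mode}_median"] = float(np.median(sh.medians))
                    entry[f"shuffle_{mode}_ci95"] = list(sh.ci())
                per_iter.append(entry)
            agg = {"theta_hat": theta,
                   "spearman_mean": float(np.mean([e["spearman_r"] for e in per_iter])),
                   "median_convergence_mean": float(np.mean([e["median_convergence"]
                                                             for e in per_iter])),
                   "iterations": per_iter}
            with open(out / "model_analysis.json", "w") as fh:
                json.dump(agg, fh, indent=2)
            outputs.append("model_analysis.json")
            log.info("model-analysis: %d iterations (%.1fs)", len(per_iter), time.time() - t0)

    with open(config_path, "rb") as fh:
        config_hash = hashlib.sha256(fh.read()).hexdigest()
    manifest = RunManifest(command="run-pipeline:" + ",".join(stages),
                           config_hash=config_hash, seed=seed,
                           inputs={"config": str(config_path)}, outputs=outputs)
    manifest.write(out)
    return manifest


def _load_trajectories(po_csv) -> list:
    """Rebuild minimal trajectories from a saved model_po.csv."""
    df = pd.read_csv(po_csv)
    trajs = []
    for _, sub in df.groupby("iteration"):
        neuron_cols = [c for c in sub.columns if c.startswith("neuron_")]
        trajs.append(DriftTrajectory(
            days=sub["day"].to_numpy(), po=sub[neuron_cols].to_numpy(),
            condition_by_day=sub["condition"].tolist(), config=None, protocol=None,
            seed=-1, max_norm_deviation=np.nan,
            initial_widths=np.full(len(neuron_cols), np.nan)))
    return trajs
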