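"""End-to-end orchestration: segment -> panel -> filter -> fit -> report.

A pipeline run is driven by one config mapping (usually a YAML file),
writes every artifact as CSV/JSON under an output directory, and leaves
a manifest recording inputs, seeds, versions and convergence status.
The panel stage is resumable: if a panel CSV produced from identical
inputs (matched by content hash) already exists it is reused.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .events import read_events_csv, segment_events, streams_from_frame, write_events_csv
from .model import McmcSpec, ModelSpec, NonCollectionModel
from .panel import build_daily_panel, participant_missingness_summary
from .schedule import SensorSchedule
from .simulate import (
    ACCEL_TRUE_PARAMS,
    GPS_TRUE_PARAMS,
    SimConfig,
    TrueParams,
    generate_cohort,
    simulate_panel,
    simulate_streams,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries a machine-readable record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.record = {"stage": stage, "error": message}


def _schedule_from(config: dict) -> SensorSchedule:
    s = config.get("schedule", {"on_cycle_s": 60, "off_cycle_s": 540})
    return SensorSchedule(
        config.get("sensor", "gps"), int(s["on_cycle_s"]), int(s["off_cycle_s"])
    )


def _true_params_from(spec: Any) -> TrueParams:
    if spec in ("gps", None):
        return GPS_TRUE_PARAMS
    if spec == "accelerometer":
        return ACCEL_TRUE_PARAMS
    return TrueParams(
        alpha0=float(spec["alpha0"]),
        beta={k: float(v) for k, v in spec.get("beta", {}).items()},
        sigma_gamma=float(spec.get("sigma_gamma", 0.0)),
        sigma_delta=float(spec.get("sigma_delta", 0.0)),
        omega=float(spec.get("omega", 1.0)),
    )


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, output_dir: str | Path) -> Path:
    """Execute the pipeline described by ``config``; returns the manifest path.

    The config either carries a ``simulate`` block (synthetic run with
    ground truth) or an ``inputs`` block pointing at an events CSV and a
    covariates CSV.  Any stage failure aborts with the stage name, and
    the partial manifest (including the error record) is still written.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    schedule = _schedule_from(config)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "sensor": schedule.sensor_name,
        "schedule": {"on_cycle_s": schedule.on_cycle_s, "off_cycle_s": schedule.off_cycle_s},
        "stages": [],
        "outputs": {},
    }
    manifest_path = out / "manifest.json"

    def stage(name):
        def deco(fn):
            def run(*a, **kw):
                t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                try:
                    result = fn(*a, **kw)
                except PipelineError:
                    raise
                except Exception as e:  # noqa: BLE001 - convert to stage record
                    manifest["stages"].append({"name": name, "error": str(e)})
                    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
                    raise PipelineError(name, str(e)) from e
                manifest["stages"].append(
                    {"name": name, "seconds": round(time.perf_counter() - t0, 2)}
                )
                logger.info("stage %s: done", name)
                return result

            return run

        return deco

    @stage("simulate")
    def _simulate():
        sim_block = dict(config["simulate"])
        params = _true_params_from(sim_block.pop("params", "gps"))
        cfg = SimConfig(schedule=schedule, seed=seed, **sim_block)
        cohort = generate_cohort(cfg)
        panel, truth = simulate_panel(cohort, params, cfg)
        streams, enrollment = simulate_streams(panel, schedule, seed=seed)
        write_events_csv(streams, out / "events.csv")
        cohort.to_csv(out / "covariates.csv", index=False)
        (out / "ground_truth.json").write_text(truth.to_json())
        manifest["outputs"]["events"] = "events.csv"
        manifest["outputs"]["covariates"] = "covariates.csv"
        manifest["outputs"]["ground_truth"] = "ground_truth.json"
        manifest["clip_rate"] = truth.clip_rate
        return cohort, enrollment

    @stage("panel")
    def _panel(cohort, enrollment):
        events_path = out / "events.csv" if "simulate" in config else Path(
            config["inputs"]["events_csv"]
        )
        input_hash = _file_hash(events_path)
        panel_path = out / "panel.csv"
        hash_path = out / "panel.hash"
        if panel_path.exists() and hash_path.exists() and hash_path.read_text() == input_hash:
            logger.info("panel unchanged (hash %s); reusing", input_hash)
            manifest["outputs"]["panel"] = "panel.csv"
            manifest["panel_reused"] = True
            return pd.read_csv(panel_path, dtype={"participant_id": str, "study_id": str})
        events = read_events_csv(events_path)
        known = set(events["sensor"].unique())
        if schedule.sensor_name not in known:
            raise ValueError(
                f"sensor {schedule.sensor_name!r} not present in event log "
                f"(found {sorted(known)})"
            )
        events = events[events["sensor"] == schedule.sensor_name]
        groupings = {
            s.participant_id: segment_events(s, schedule)
            for s in streams_from_frame(events)
        }
        panel = build_daily_panel(
            groupings,
            schedule,
            cohort,
            timezone=config.get("timezone", "UTC"),
            enrollment=enrollment,
        )
        panel.to_csv(panel_path, index=False)
        hash_path.write_text(input_hash)
        manifest["outputs"]["panel"] = "panel.csv"
        manifest["panel_reused"] = False
        return panel

    @stage("fit")
    def _fit(panel):
        mspec = ModelSpec(**config.get("model", {}))
        mcmc = McmcSpec(seed=seed, **config.get("mcmc", {}))
        model = NonCollectionModel.from_dataframe(panel, mspec)
        model.exclusions.to_csv(out / "exclusions.csv", index=False)
        res = model.fit(mcmc)
        manifest["outputs"]["exclusions"] = "exclusions.csv"
        manifest["converged"] = res.converged
        manifest["divergences"] = res.n_divergent
        return res

    @stage("report")
    def _report(panel, res):
        override = bool(config.get("report", {}).get("override_convergence", False))
        res.diagnostics.to_csv(out / "diagnostics.csv")
        res.fixed_effects_report(override_convergence=True).to_csv(out / "fixed_effects.csv")
        res.random_effects_report("participant").to_csv(
            out / "random_effects_participant.csv", index=False
        )
        if "delta" in res.params:
            res.random_effects_report("study").to_csv(
                out / "random_effects_study.csv", index=False
            )
        participant_missingness_summary(panel).to_csv(
            out / "missingness_by_participant.csv", index=False
        )
        _write_draws(res, out / "draws.csv")
        metrics = {
            "waic": res.waic(),
            "loo": {k: v for k, v in res.loo().items() if k != "pareto_k"},
            "bayes_r2": res.bayes_r2(),
            "omega": _scalar_summary(res, "omega"),
            "sigma_gamma": _scalar_summary(res, "sigma_gamma"),
            "sigma_delta": _scalar_summary(res, "sigma_delta"),
            "converged": res.converged,
            "convergence_overridden": override and not res.converged,
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))
        manifest["outputs"].update(
            {
                "diagnostics": "diagnostics.csv",
                "fixed_effects": "fixed_effects.csv",
                "random_effects_participant": "random_effects_participant.csv",
                "missingness_by_participant": "missingness_by_participant.csv",
                "draws": "draws.csv",
                "metrics": "metrics.json",
            }
        )
        if not res.converged and not override:
            logger.warning(
                "fit did not pass the convergence gate; reports were written "
                "but metrics.json flags converged=false"
            )

    if "simulate" in config:
        cohort, enrollment = _simulate()
    elif "inputs" in config:
        cohort = pd.read_csv(
            config["inputs"]["covariates_csv"], dtype={"participant_id": str, "study_id": str}
        )
        enrollment = None
    else:
        raise PipelineError("config", "config needs a 'simulate' or 'inputs' block")

    panel = _panel(cohort, enrollment)
    res = _fit(panel)
    _report(panel, res)
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest_path


def _scalar_summary(res, name):
    if name not in res.params:
        return None
    d = res.params[name].reshape(-1)
    return {
        "median": float(np.median(d)),
        "ci_low": float(np.percentile(d, 2.5)),
        "ci_high": float(np.percentile(d, 97.5)),
    }


def _write_draws(res, path: Path) -> None:
    """Flat CSV of constrained draws: chain, draw, one column per parameter."""
    des = res.model.design
    n_chain, n_draw = res.theta.shape[:2]
    cols: dict[str, np.ndarray] = {
        "chain": np.repeat(np.arange(n_chain), n_draw),
        "draw": np.tile(np.arange(n_draw), n_chain),
    }
    for name, arr in res.params.items():
        if arr.ndim == 2:
            cols[name] = arr.reshape(-1)
        else:
            labels = {
                "beta": des.x_cols,
                "gamma": des.participant_ids,
                "delta": des.study_ids,
            }[name]
            for k, lab in enumerate(labels):
                cols[f"{name}[{lab}]"] = arr[:, :, k].reshape(-1)
    pd.DataFrame(cols).to_csv(path, index=False)
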