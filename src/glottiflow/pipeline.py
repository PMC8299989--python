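"""End-to-end training and FSI workflows as reproducible, logged runs.

Two pipelines are provided.  The *training* pipeline builds the synthetic
shape corpus, generates ground-truth section data, inverts it into
resistance targets, extracts features, cross-validates and trains the
regressor, and evaluates flow-rate/pressure errors of the learned-resistance
model against plain Bernoulli on held-out shapes.  The *FSI* pipeline runs a
Bernoulli-coupled oscillation, extracts one cycle's shapes, trains on them,
re-runs the coupled simulation with the learned resistance and writes a
paired waveform comparison.

Every run writes a manifest (config snapshot, package version, seeds, output
hashes, timings) so it can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dnn import (
    DNNConfig,
    evaluate_mae,
    kfold_cross_validate,
    save_model,
    split_data,
    train_final,
)
from .flow import (
    pressure_distribution,
    relative_errors,
    solve_flow_rate,
    solve_self_consistent,
    summarize_errors,
)
from .fsi import SolidWallModel, analyze_trace, extract_cycle_shapes, run_fsi
from .geometry import FluidProperties, FlowConditions, discretize_channel
from .oracle import build_training_set, make_ground_truth
from .shapes import default_shape_set

__all__ = ["RunConfig", "run_training_pipeline", "run_fsi_pipeline"]

log = logging.getLogger("glottiflow")

KPA_TO_DYNCM2 = 1.0e4


@dataclass(frozen=True)
class RunConfig:
    """Single configuration driving both pipelines.

    Pressures are accepted in kPa at this interface and converted to CGS
    (1 kPa = 1e4 dyn/cm^2) internally.  The ``fast`` profile shrinks the
    corpus (8 shapes), the discretization (n = 32) and the epoch count (500)
    for desk-scale runs; the defaults are the full study conditions.
    """

    seed: int = 0
    fast: bool = False
    out_dir: str = "runs/latest"
    # fluid and boundary conditions
    density_rho: float = 1.145e-3
    kinematic_viscosity_nu: float = 1.655e-1
    inlet_pressure_kPa: float = 1.0
    outlet_pressure_kPa: float = 0.0
    # shape corpus
    n_phases: int = 16
    mesh_resolution: float = 0.01
    n_sections: int = 128
    k_sep: float = 0.5
    # regressor
    epochs: int = 20000
    batch_size: int = 256
    l2_lambda: float = 1e-4
    learning_rate: float = 1e-3
    test_fraction: float = 0.2
    k_folds: int = 5
    run_cv: bool = True
    # FSI
    fsi_duration: float = 0.2
    fsi_dt: float = 1e-5
    fsi_n_sections: int = 32
    fsi_n_samples: int = 92
    fsi_solid_mesh: float = 0.03

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def effective(self) -> "RunConfig":
        """Apply the fast profile reductions if requested."""
        if not self.fast:
            return self
        return replace(
            self,
            n_phases=2,
            n_sections=32,
            epochs=500,
            mesh_resolution=max(self.mesh_resolution, 0.03),
        )

    def fluid(self) -> FluidProperties:
        return FluidProperties(self.density_rho, self.kinematic_viscosity_nu)

    def conditions(self) -> FlowConditions:
        return FlowConditions(
            self.inlet_pressure_kPa * KPA_TO_DYNCM2,
            self.outlet_pressure_kPa * KPA_TO_DYNCM2,
        )

    def dnn_config(self) -> DNNConfig:
        return DNNConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            l2_lambda=self.l2_lambda,
            learning_rate=self.learning_rate,
            seed=self.seed,
            k_folds=self.k_folds,
            test_fraction=self.test_fraction,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(payload, indent=2, sort_keys=True))
    os.replace(tmp, path)


def _finish_manifest(
    out: Path, config: RunConfig, stages: dict, outputs: list[Path]
) -> dict:
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "stage_seconds": stages,
        "output_hashes": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


class _StageTimer:
    def __init__(self):
        self.stages: dict[str, float] = {}

    def run(self, name: str, fn):
        log.info("stage %s: start", name)
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        self.stages[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.2fs", name, self.stages[name])
        return result


def _heldout_error_comparison(channels, test_ids, model, fluid, conditions, config):
    """E_Q / E_P of plain-Bernoulli and learned-resistance predictions
    against the surrogate ground truth on held-out shapes."""
    reports_bern, reports_dnn = [], []
    for sid in test_ids:
        dchan = discretize_channel(channels[sid], config.n_sections)
        gt = make_ground_truth(dchan, fluid, conditions, k_sep=config.k_sep)
        ref = pressure_distribution(
            dchan,
            np.zeros(dchan.n),
            fluid,
            conditions,
            gt.Q_ref,
        )
        ref.pressures_P = gt.mean_pressures
        ref.Q = gt.Q_ref
        q_b = solve_flow_rate(dchan, np.zeros(dchan.n), fluid, conditions)
        bern = pressure_distribution(dchan, np.zeros(dchan.n), fluid, conditions, q_b)
        dnn = solve_self_consistent(dchan, fluid, conditions, model)
        reports_bern.append(relative_errors(ref, bern, conditions))
        reports_dnn.append(relative_errors(ref, dnn, conditions))
    return {
        "bernoulli": summarize_errors(reports_bern),
        "dnn_bernoulli": summarize_errors(reports_dnn),
    }


def run_training_pipeline(config: RunConfig) -> dict:
    """Synthetic corpus -> targets -> features -> CV -> train -> evaluate."""
    cfg = config.effective()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fluid, conditions = cfg.fluid(), cfg.conditions()
    timer = _StageTimer()

    channels = timer.run(
        "shapes", lambda: default_shape_set(cfg.n_phases, cfg.mesh_resolution)
    )
    records = timer.run(
        "targets",
        lambda: build_training_set(
            channels, fluid, conditions, cfg.n_sections, cfg.k_sep
        ),
    )
    records_path = out / "training_records.csv"
    records.to_csv(records_path, index=False)

    train, test = split_data(records, cfg.test_fraction, cfg.seed)
    dnn_cfg = cfg.dnn_config()
    metrics: dict = {
        "n_shapes": len(channels),
        "n_records": int(len(records)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
    }
    if cfg.run_cv:
        cv = timer.run("cross_validation", lambda: kfold_cross_validate(train, dnn_cfg))
        metrics["cv_mean_final_val_mae"] = cv.mean_final_val_mae
    model = timer.run("train", lambda: train_final(train, dnn_cfg))
    model_path = out / "model.npz"
    save_model(model, model_path)

    test_mae, test_rel = evaluate_mae(model, test)
    train_mae, _ = evaluate_mae(model, train)
    metrics.update(
        {
            "train_mae": train_mae,
            "test_mae": test_mae,
            "test_relative_mae": test_rel,
        }
    )
    test_ids = sorted(test["shape_id"].unique().tolist())
    metrics["error_comparison"] = timer.run(
        "error_comparison",
        lambda: _heldout_error_comparison(
            channels, test_ids, model, fluid, conditions, cfg
        ),
    )
    metrics_path = out / "metrics.json"
    _write_json(metrics_path, metrics)
    manifest = _finish_manifest(
        out, config, timer.stages, [records_path, model_path, metrics_path]
    )
    return {"metrics": metrics, "manifest": manifest, "model": model}


def _default_solid(cfg: RunConfig) -> SolidWallModel:
    return SolidWallModel(
        geometry=replace(
            SolidWallModel().geometry, mesh_resolution=cfg.fsi_solid_mesh
        )
    )


def run_fsi_pipeline(config: RunConfig) -> dict:
    """Bernoulli FSI -> cycle shapes -> train -> learned-resistance FSI."""
    cfg = config.effective()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fluid, conditions = cfg.fluid(), cfg.conditions()
    solid = _default_solid(cfg)
    timer = _StageTimer()

    trace_b = timer.run(
        "fsi_bernoulli",
        lambda: run_fsi(
            solid,
            fluid,
            conditions,
            flow_mode="bernoulli",
            duration=cfg.fsi_duration,
            dt=cfg.fsi_dt,
            n_sections=cfg.fsi_n_sections,
        ),
    )
    shapes = timer.run(
        "extract_shapes", lambda: extract_cycle_shapes(trace_b, cfg.fsi_n_samples)
    )
    records = timer.run(
        "targets",
        lambda: build_training_set(
            shapes, fluid, conditions, cfg.fsi_n_sections, cfg.k_sep
        ),
    )
    train, test = split_data(records, cfg.test_fraction, cfg.seed)
    model = timer.run("train", lambda: train_final(train, cfg.dnn_config()))
    model_path = out / "fsi_model.npz"
    save_model(model, model_path)
    test_mae, test_rel = evaluate_mae(model, test) if len(test) else (float("nan"),) * 2

    trace_d = timer.run(
        "fsi_dnn",
        lambda: run_fsi(
            solid,
            fluid,
            conditions,
            flow_mode="dnn_bernoulli",
            model=model,
            duration=cfg.fsi_duration,
            dt=cfg.fsi_dt,
            n_sections=cfg.fsi_n_sections,
        ),
    )
    comparison = {
        "bernoulli": analyze_trace(trace_b),
        "dnn_bernoulli": analyze_trace(trace_d),
        "n_extracted_shapes": len(shapes),
        "test_mae": test_mae,
        "test_relative_mae": test_rel,
    }
    comparison_path = out / "fsi_comparison.json"
    _write_json(comparison_path, comparison)
    manifest = _finish_manifest(
        out, config, timer.stages, [model_path, comparison_path]
    )
    return {
        "comparison": comparison,
        "manifest": manifest,
        "traces": {"bernoulli": trace_b, "dnn_bernoulli": trace_d},
        "model": model,
    }
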