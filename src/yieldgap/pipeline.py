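"""End-to-end orchestration: simulate → features → frontier → fit → report.

A single :class:`RunConfig` drives the whole analysis.  The master seed
deterministically derives one seed per stage (hash of master seed and stage
name), so adding a stage never perturbs the randomness of earlier stages and
two runs with the same config are byte-identical in every data artifact.
The run directory receives every stage's outputs plus a manifest with input
and output hashes and wall times.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import climate_features, model_suite, synthetic_data, yield_frontier
from .data_model import Dataset, load_dataset
from .model_suite import RFParams, ScenarioRunConfig
from .synthetic_data import SimConfig

logger = logging.getLogger("yieldgap")


def configure_logging(level: int = logging.INFO) -> None:
    """INFO logging to stderr with per-stage timers (idempotent)."""
    root = logging.getLogger("yieldgap")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        root.addHandler(handler)
    root.setLevel(level)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class FrontierParams:
    width_pct: float = 5.0
    min_bin_count: int = 20
    cultivar_id: int | None = None


@dataclass
class RunConfig:
    """Everything a full run needs; round-trips through YAML unchanged."""

    master_seed: int = 0
    simulate: bool = True
    # input paths, used when simulate is false
    plots_csv: str | None = None
    monthly_csv: str | None = None
    daily_csv: str | None = None
    cells_csv: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    frontier: FrontierParams = field(default_factory=FrontierParams)
    model: ScenarioRunConfig = field(default_factory=ScenarioRunConfig)

    def __post_init__(self) -> None:
        if not self.simulate:
            missing = [
                name
                for name, p in {
                    "plots_csv": self.plots_csv,
                    "monthly_csv": self.monthly_csv,
                    "daily_csv": self.daily_csv,
                    "cells_csv": self.cells_csv,
                }.items()
                if p is None
            ]
            if missing:
                raise ValueError(
                    f"simulate=false requires input paths; missing: {missing}"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        if "frontier" in d and isinstance(d["frontier"], dict):
            d["frontier"] = FrontierParams(**d["frontier"])
        if "model" in d and isinstance(d["model"], dict):
            m = dict(d["model"])
            if "rf_params" in m and isinstance(m["rf_params"], dict):
                m["rf_params"] = RFParams(**m["rf_params"])
            if "scenario_ids" in m:
                m["scenario_ids"] = tuple(m["scenario_ids"])
            d["model"] = ScenarioRunConfig(**m)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_yamlable(self.to_dict()), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage in order, writing artifacts and a manifest.

    A failure in any stage halts the run; a FAILED marker naming the stage is
    left next to the partial outputs.
    """
    configure_logging()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": []}
    stage_name = "setup"
    try:
        # ------------------------------------------------------------- data
        stage_name = "simulate" if config.simulate else "load"
        t0 = time.perf_counter()
        if config.simulate:
            sim_cfg = dataclasses.replace(
                config.sim, seed=derive_seed(config.master_seed, "simulate")
            )
            result = synthetic_data.simulate_all(sim_cfg)
            data_dir = out / "data"
            paths = synthetic_data.write_simulated(result, data_dir)
            dataset = result.dataset
            monthly, daily, cells = result.monthly, result.daily, result.cells
            stage_outputs = list(paths.values())
            stage_inputs: list[Path] = []
        else:
            stage_inputs = [
                Path(config.plots_csv),
                Path(config.monthly_csv),
                Path(config.daily_csv),
                Path(config.cells_csv),
            ]
            dataset = load_dataset(config.plots_csv)
            monthly = pd.read_csv(config.monthly_csv)
            daily = pd.read_csv(config.daily_csv)
            cells = pd.read_csv(config.cells_csv)
            stage_outputs = []
        _record(manifest, stage_name, stage_inputs, stage_outputs, t0)

        # --------------------------------------------------------- features
        stage_name = "features"
        t0 = time.perf_counter()
        features, col_manifest = climate_features.build_feature_table(
            dataset, monthly, daily, cells
        )
        features_path = out / "features.csv"
        features.to_csv(features_path, index=False)
        (out / "features_manifest.json").write_text(
            json.dumps(col_manifest, indent=2, sort_keys=True)
        )
        _record(manifest, stage_name, stage_outputs, [features_path], t0)

        # --------------------------------------------------------- frontier
        stage_name = "frontier"
        t0 = time.perf_counter()
        fm = yield_frontier.estimate_frontier(
            dataset,
            width_pct=config.frontier.width_pct,
            min_bin_count=config.frontier.min_bin_count,
            cultivar_id=config.frontier.cultivar_id,
        )
        frontier_path = out / "frontier.json"
        yield_frontier.write_frontier(fm, frontier_path)
        gaps = yield_frontier.compute_gaps(dataset, fm)
        gaps_path = out / "gaps.csv"
        gaps.to_csv(gaps_path, index=False)
        _record(manifest, stage_name, [], [frontier_path, gaps_path], t0)

        # -------------------------------------------------------------- fit
        stage_name = "fit"
        t0 = time.perf_counter()
        model_cfg = dataclasses.replace(
            config.model, seed=derive_seed(config.master_seed, "fit")
        )
        model_suite.run_scenarios(features, gaps, model_cfg, out_dir=out)
        fit_outputs = sorted(out.glob("cv_report.json")) + sorted(
            out.glob("scenario_comparison.csv")
        )
        _record(manifest, stage_name, [features_path, gaps_path], fit_outputs, t0)
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage_name}\n")
        logger.exception("run failed in stage %s", stage_name)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(out / "run_config.yaml")
    logger.info("run complete: %s", out)
    return out


def _record(
    manifest: dict, stage: str, inputs: list[Path], outputs: list[Path], t0: float
) -> None:
    elapsed = time.perf_counter() - t0
    manifest["stages"].append(
        {
            "stage": stage,
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "wall_time_s": round(elapsed, 3),
        }
    )
    logger.info("stage %-9s done in %.2fs", stage, elapsed)
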