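"""Experiment configuration and end-to-end orchestration.

One YAML config describes a full run: synthetic cultivations, feature
settings, label augmentation, model architecture, training, simulation and
evaluation.  All randomness derives from a single global seed through named
substreams, so re-running a config reproduces every artifact.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import factors as F
from .env_features import FeatureSettings, feature_tensor
from .growth_records import (
    WindowDataset,
    augment_labels,
    interpolate_growth_daily,
    make_training_windows,
)
from .model import DeepCropConfig
from .simulation import SimulationRun, run_simulation
from .synthetic import (
    Cultivation,
    CultivationScenario,
    ReferenceParams,
    default_scenarios,
    derive_seed,
    generate_dataset,
    make_cultivation,
)
from .training import (
    TrainedModel,
    TrainingSettings,
    save_checkpoint,
    train,
)
from .evaluation import MetricsReport, evaluate_simulation

log = logging.getLogger("deepcrop")

#: factors scored by default in experiment evaluation
DEFAULT_EVAL_FACTORS = (
    "plant_height_m",
    "leaf_area_m2",
    "leaf_fw_g",
    "leaf_dw_g",
    "stem_fw_g",
    "stem_dw_g",
    "petiole_fw_g",
    "petiole_dw_g",
    "harvest_fw_g",
    "harvest_dw_g",
)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    seed: int = 0
    scenarios: list[CultivationScenario] | None = None   # default: 4 cultivations
    train_scenarios: tuple[str, ...] = ("2020-1", "2020-2")
    test_scenario: str = "2021-1"
    feature_settings: FeatureSettings = field(default_factory=FeatureSettings)
    reference_params: ReferenceParams = field(default_factory=ReferenceParams)
    n_obs_dates: int = 5
    obs_cv: float = 0.08
    n_augment_draws: int = 4
    model: DeepCropConfig = field(default_factory=DeepCropConfig)
    training: TrainingSettings = field(default_factory=TrainingSettings)
    train_split: float = 0.8
    eval_factors: tuple[str, ...] = DEFAULT_EVAL_FACTORS
    guidance: bool = True
    sanitize: bool = False
    out_dir: str = "experiment_out"

    def resolved_scenarios(self) -> list[CultivationScenario]:
        return self.scenarios or default_scenarios(self.seed)

    def copy(self) -> "ExperimentConfig":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        d = asdict(self)
        d["model"] = self.model.to_dict()
        if self.scenarios is not None:
            d["scenarios"] = [asdict(s) for s in self.scenarios]
        return plain(d)

    @staticmethod
    def from_dict(data: dict) -> "ExperimentConfig":
        known = set(ExperimentConfig.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for required in ("seed",):
            if required not in data:
                raise ValueError(f"missing config key: {required!r}")
        data = dict(data)
        if "scenarios" in data and data["scenarios"] is not None:
            data["scenarios"] = [CultivationScenario(**s) for s in data["scenarios"]]
        for key, cls in (
            ("feature_settings", FeatureSettings),
            ("reference_params", ReferenceParams),
            ("training", TrainingSettings),
        ):
            if key in data and isinstance(data[key], dict):
                data[key] = cls(**data[key])
        if "model" in data and isinstance(data["model"], dict):
            data["model"] = DeepCropConfig.from_dict(
                DeepCropConfig().to_dict() | data["model"]
            )
        for key in ("train_scenarios", "eval_factors"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return ExperimentConfig(**data)

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a mapping")
        return ExperimentConfig.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    trained: TrainedModel
    trace: pd.DataFrame
    run: SimulationRun
    metrics: MetricsReport
    n_train: int
    n_val: int
    n_loss_terms: int
    cultivations: dict[str, Cultivation]


def _labels_for(cult: Cultivation):
    """Daily interpolated labels for one cultivation, anchored at the first
    environment day (day-0 anchor = 50% of the first observation)."""
    return interpolate_growth_daily(cult.observations, start_date=cult.truth.index[0])


def build_training_data(
    config: ExperimentConfig, cultivations: dict[str, Cultivation]
) -> tuple[WindowDataset, WindowDataset]:
    """Interpolate, augment and window the training cultivations."""
    per_cultivation = {}
    for name in config.train_scenarios:
        cult = cultivations[name]
        features, dates, _ = feature_tensor(cult.env, config.feature_settings)
        if config.model.zero_features:
            idx = [i for i, f in enumerate(F.FEATURES) if f in config.model.zero_features]
            features = features.copy()
            features[:, :, idx] = 0.0
        daily = _labels_for(cult)
        label_sets = augment_labels(
            daily,
            config.n_augment_draws,
            seed=derive_seed(config.seed, f"augment:{name}"),
        )
        per_cultivation[name] = (features, label_sets)
    return make_training_windows(
        per_cultivation,
        config.model.memory_length,
        config.train_split,
        seed=derive_seed(config.seed, "split"),
    )


def run_experiment_in_memory(config: ExperimentConfig) -> ExperimentResult:
    """Execute synth -> features -> augment -> windows -> train -> simulate
    -> evaluate without touching disk."""
    t0 = time.time()
    scenarios = {s.name: s for s in config.resolved_scenarios()}
    for name in (*config.train_scenarios, config.test_scenario):
        if name not in scenarios:
            raise ValueError(f"scenario {name!r} not defined")

    log.info("generating %d synthetic cultivations", len(scenarios))
    cultivations = {
        name: make_cultivation(
            sc, config.reference_params, config.n_obs_dates, config.obs_cv
        )
        for name, sc in scenarios.items()
    }

    train_set, val_set = build_training_data(config, cultivations)
    log.info(
        "windows: %d train / %d validation (L=%d)",
        len(train_set), len(val_set), config.model.memory_length,
    )

    settings = copy.deepcopy(config.training)
    settings.seed = derive_seed(config.seed, "train")
    trained, trace = train(train_set, val_set, config.model, settings)
    log.info("training done in %.1f s (best epoch %d)",
             time.time() - t0, trace.attrs["best_epoch"])

    test = cultivations[config.test_scenario]
    run = run_simulation(
        initial=test.truth.iloc[0],
        env=test.env,
        trained=trained,
        guidance=config.guidance,
        sanitize=config.sanitize,
        feature_settings=config.feature_settings,
    )

    # the mean baseline is defined by the training-period labels
    train_label_frames = [
        _labels_for(cultivations[name]).frame() for name in config.train_scenarios
    ]
    metrics = evaluate_simulation(
        run,
        labels=test.truth,
        factor_subset=list(config.eval_factors),
        baseline_labels=pd.concat(train_label_frames),
    )
    log.info("aggregate EF %.3f / NRMSE %.3f", metrics.aggregate_ef,
             metrics.aggregate_nrmse)

    n_loss_terms = len(
        [c for c in trace.columns if c not in ("epoch", "total", "val_total")]
    )
    return ExperimentResult(
        config=config,
        trained=trained,
        trace=trace,
        run=run,
        metrics=metrics,
        n_train=len(train_set),
        n_val=len(val_set),
        n_loss_terms=n_loss_terms,
        cultivations=cultivations,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: ExperimentConfig) -> Path:
    """Run the full pipeline and write all artifacts to ``config.out_dir``.

    Artifacts: the synthetic dataset CSVs, the training trace, the model
    checkpoint, the simulated trajectory, the metrics table, and a manifest
    recording seeds and file hashes.  A failing stage raises with the stage
    name; artifacts written so far are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "synth"
        generate_dataset(
            config.resolved_scenarios(), out / "dataset",
            config.reference_params, config.n_obs_dates, config.obs_cv,
        )
        stage = "experiment"
        result = run_experiment_in_memory(config)
        stage = "artifacts"
        config.to_yaml(out / "config.yaml")
        result.trace.to_csv(out / "trace.csv", index=False, float_format="%.8g")
        save_checkpoint(result.trained, out / "checkpoint.npz")
        result.run.trajectory.to_csv(out / "trajectory.csv", float_format="%.8g")
        result.metrics.to_csv(out / "metrics.csv")
        files = [p for p in sorted(out.rglob("*")) if p.is_file()]
        manifest = {
            "seed": config.seed,
            "derived_seeds": {
                name: derive_seed(config.seed, name)
                for name in ["split", "train"]
                + [f"augment:{n}" for n in config.train_scenarios]
            },
            "n_train": result.n_train,
            "n_val": result.n_val,
            "aggregate_ef": result.metrics.aggregate_ef,
            "aggregate_nrmse": result.metrics.aggregate_nrmse,
            "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as err:
        raise RuntimeError(f"experiment failed in stage {stage!r}: {err}") from err
    return out
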