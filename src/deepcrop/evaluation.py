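"""Modeling-efficiency / NRMSE scoring, interpretation exports, ablations.

Modeling efficiency (Nash-Sutcliffe form) and range-normalized RMSE:

    EF    = 1 - sum((y - yhat)^2) / sum((y - mean(y))^2)
    NRMSE = RMSE / (max(y) - min(y))

EF = 1 is a perfect match; EF = 0 means the model performs exactly as well
as predicting the observation mean.  A constant mean-of-training baseline
accompanies every report.  The module also exports attention weights and
last-hidden-layer matrices for downstream interpretation (e.g. 2-D
embedding by external tooling) and drives the ablation harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import factors as F
from .growth_records import WindowDataset
from .model import AttentionMap
from .simulation import SimulationRun
from .training import TrainedModel


def modeling_efficiency(y_label, y_pred) -> float:
    """Nash-Sutcliffe modeling efficiency; 1 = perfect, 0 = mean predictor."""
    y = np.asarray(y_label, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("y_label and y_pred must be 1-D of equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    denom = float(((y - y.mean()) ** 2).sum())
    if denom == 0.0:
        raise ValueError("EF undefined: observations are constant")
    return 1.0 - float(((y - p) ** 2).sum()) / denom


def nrmse(y_label, y_pred) -> float:
    """RMSE normalized by the observed range (max - min)."""
    y = np.asarray(y_label, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("y_label and y_pred must be 1-D of equal length")
    span = float(y.max() - y.min())
    if span == 0.0:
        raise ValueError("NRMSE undefined: observed range is zero")
    return float(np.sqrt(((y - p) ** 2).mean())) / span


def mean_baseline(train_labels: pd.DataFrame, eval_index) -> pd.DataFrame:
    """Constant per-factor predictions equal to the training-period mean."""
    means = train_labels.mean(axis=0)
    return pd.DataFrame(
        np.tile(means.to_numpy(), (len(eval_index), 1)),
        index=eval_index,
        columns=train_labels.columns,
    )


@dataclass
class MetricsReport:
    """Per-factor EF/NRMSE with mean-baseline comparison."""

    per_factor: pd.DataFrame   # index factor; columns n, ef, nrmse, baseline_ef, baseline_nrmse
    aggregate_ef: float
    aggregate_nrmse: float

    def to_csv(self, path) -> None:
        self.per_factor.rename_axis("factor").to_csv(path, float_format="%.6g")


def evaluate_simulation(
    run: SimulationRun | pd.DataFrame,
    labels: pd.DataFrame,
    factor_subset: list[str] | None = None,
    baseline_labels: pd.DataFrame | None = None,
) -> MetricsReport:
    """Score a simulated trajectory against labels on their common days.

    ``labels`` carries one row per labelled day (observation days or a full
    truth table) and one column per factor.  ``baseline_labels`` (training
    labels) defines the constant mean baseline; defaults to ``labels``
    itself, for which baseline EF = 0 by construction.
    """
    trajectory = run.trajectory if isinstance(run, SimulationRun) else run
    subset = list(factor_subset) if factor_subset is not None else [
        f for f in labels.columns if f in trajectory.columns
    ]
    unknown = [f for f in subset if f not in trajectory.columns or f not in labels.columns]
    if unknown:
        raise ValueError(f"factors not present in both tables: {unknown}")
    common = trajectory.index.intersection(labels.index)
    if len(common) < 2:
        raise ValueError("fewer than 2 overlapping days between run and labels")
    base = mean_baseline(
        baseline_labels if baseline_labels is not None else labels.loc[common],
        common,
    )
    rows = []
    for factor in subset:
        y = labels.loc[common, factor].to_numpy()
        p = trajectory.loc[common, factor].to_numpy()
        b = base[factor].to_numpy()
        if np.ptp(y) == 0.0:
            # EF/NRMSE are undefined on constant observations (e.g. a
            # factor that never leaves zero on the labelled days)
            warnings.warn(f"skipping constant-label factor {factor!r}", stacklevel=2)
            continue
        rows.append(
            {
                "factor": factor,
                "n": len(common),
                "ef": modeling_efficiency(y, p),
                "nrmse": nrmse(y, p),
                "baseline_ef": modeling_efficiency(y, b),
                "baseline_nrmse": nrmse(y, b),
            }
        )
    if not rows:
        raise ValueError("no scoreable factors: all labels are constant")
    table = pd.DataFrame(rows).set_index("factor")
    return MetricsReport(
        per_factor=table,
        aggregate_ef=float(table["ef"].mean()),
        aggregate_nrmse=float(table["nrmse"].mean()),
    )


# -- interpretation exports ----------------------------------------------


def extract_attention(
    trained: TrainedModel,
    features: np.ndarray,
    prev_growth: np.ndarray,
    decoder_names: list[str] | None = None,
    day_tag: int | None = None,
) -> list[AttentionMap]:
    """Attention maps for one (already natural-units) window sample.

    Inputs are standardized internally.  Returns self- and cross-attention
    maps of the requested decoders (all by default), each tagged with the
    days-after-transplant label when given.
    """
    cfg = trained.cfg
    names = decoder_names or list(cfg.decoder_map)
    unknown = [n for n in names if n not in cfg.decoder_map]
    if unknown:
        raise ValueError(f"unknown decoders {unknown}")
    env = trained.feature_scaler.transform(np.asarray(features)[None, ...])
    prev = trained.factor_scaler.transform(np.asarray(prev_growth))[None, ...]
    _, extras = trained.model.forward(env, prev, train=False, collect_attention=True)
    maps = [m for m in extras["attention"] if m.decoder in names]
    if day_tag is not None:
        for m in maps:
            m.day_tag = day_tag
    return maps


def attention_to_frame(amap: AttentionMap) -> pd.DataFrame:
    """Long-format export: head, query position, key position, weight."""
    w = amap.weights[0]  # single sample
    heads, n_q, n_k = w.shape
    h, q, k = np.meshgrid(
        np.arange(heads), np.arange(n_q), np.arange(n_k), indexing="ij"
    )
    return pd.DataFrame(
        {
            "decoder": amap.decoder,
            "block": amap.block,
            "kind": amap.kind,
            "head": h.ravel(),
            "query_day": q.ravel(),
            "key_pos": k.ravel(),
            "weight": w.ravel(),
        }
    )


def export_hidden(
    trained: TrainedModel,
    dataset: WindowDataset,
    decoder: str = "leaf",
    batch_size: int = 64,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Last-hidden-layer vectors (one row per sample-day) with metadata.

    Rows come from the layer immediately before the selected decoder's
    linear head; metadata keys every row by cultivation, draw, window start
    and day offset, ready for external 2-D embedding.
    """
    cfg = trained.cfg
    if decoder not in cfg.decoder_map:
        raise ValueError(f"unknown decoder {decoder!r}")
    env = trained.feature_scaler.transform(dataset.env)
    prev = trained.factor_scaler.transform(dataset.prev)
    chunks = []
    for start in range(0, len(dataset), batch_size):
        sl = slice(start, min(start + batch_size, len(dataset)))
        _, extras = trained.model.forward(
            env[sl], prev[sl], train=False, collect_hidden=True
        )
        chunks.append(extras["hidden"][decoder])
    hidden = np.concatenate(chunks, axis=0)        # (N, L, d_model)
    n, L, d = hidden.shape
    meta = dataset.meta.loc[dataset.meta.index.repeat(L)].reset_index(drop=True)
    meta["day_offset"] = np.tile(np.arange(L), n)
    meta["decoder"] = decoder
    return hidden.reshape(n * L, d), meta


# -- ablation harness -----------------------------------------------------

ABLATION_AXES = ("input", "loss", "structure", "memory_length")


def ablation_run(base_config, axis: str, variants: list, run_fn=None) -> pd.DataFrame:
    """Train and score one experiment per variant on a shared seed schedule.

    ``base_config`` is an ExperimentConfig; ``variants`` are axis-specific
    specs: feature-name lists to drop (input), loss modes (loss),
    structure flags ("no_gate", "single_decoder") or memory lengths.  All
    variants are validated before any training starts, then run through
    ``run_fn`` (default: the workbench experiment runner) on the same
    synthetic dataset and held-out scenario.
    """
    from .workbench import run_experiment_in_memory

    if axis not in ABLATION_AXES:
        raise ValueError(f"unknown ablation axis {axis!r}; choose from {ABLATION_AXES}")
    configs = [(_variant_name(axis, v), _apply_variant(base_config, axis, v))
               for v in variants]
    run_fn = run_fn or run_experiment_in_memory
    rows = []
    for name, cfg in configs:
        result = run_fn(cfg)
        rows.append(
            {
                "variant": name,
                "axis": axis,
                "aggregate_ef": result.metrics.aggregate_ef,
                "aggregate_nrmse": result.metrics.aggregate_nrmse,
                "n_loss_terms": result.n_loss_terms,
            }
        )
    return pd.DataFrame(rows)


def _variant_name(axis: str, variant) -> str:
    if isinstance(variant, (list, tuple)):
        return f"drop_{'+'.join(variant)}" if variant else "full_input"
    return str(variant)


def _apply_variant(base_config, axis: str, variant):
    cfg = base_config.copy()
    if axis == "input":
        if not isinstance(variant, (list, tuple)):
            raise ValueError("input variants are lists of feature names to drop")
        unknown = set(variant) - set(F.FEATURES)
        if unknown:
            raise ValueError(f"unknown input features {sorted(unknown)}")
        cfg.drop_features = tuple(variant)
    elif axis == "loss":
        if variant not in ("multitask", "no_conservation", "single"):
            raise ValueError(f"unknown loss variant {variant!r}")
        cfg.training.loss_mode = variant
    elif axis == "structure":
        if variant == "no_gate":
            cfg.model.use_input_gate = False
        elif variant == "single_decoder":
            cfg.model.decoder_map = {"all": tuple(cfg.model.factors)}
        elif variant == "no_decoders":
            raise ValueError("at least one decoder is required")
        elif variant != "full":
            raise ValueError(f"unknown structure variant {variant!r}")
    elif axis == "memory_length":
        L = int(variant)
        if L < 1:
            raise ValueError("memory length must be >= 1")
        cfg.model.memory_length = L
    return cfg
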