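"""Loss assembly, standardization, the training loop and checkpoints.

The training objective is the unweighted mean of eight mean-squared-error
terms: one per decoder (over that decoder's factors and the L target days)
plus two vegetative-conservation terms comparing predicted and target sums
of leaf + stem + petiole fresh weight and dry weight.  The conservation
terms tie the three organ decoders together: they vanish whenever the organ
predictions sum correctly, even if individual organs are off in
compensating ways.

Losses are computed in standardized space (the factor set mixes grams,
meters and counts); the conservation sums are formed in natural units via
the scaler's affine inverse and re-normalized by the summed scales so the
term is comparable in magnitude to the per-decoder terms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import factors as F
from .growth_records import WindowDataset
from .model import DeepCropConfig, DeepCropModel
from .nn import Adam, Tensor

CHECKPOINT_VERSION = 1


@dataclass
class Scaler:
    """Per-column z-score statistics fitted on training data only."""

    mean: np.ndarray
    scale: np.ndarray

    @staticmethod
    def fit(values: np.ndarray) -> "Scaler":
        """Fit over all rows of ``values`` reshaped to (-1, n_columns)."""
        flat = values.reshape(-1, values.shape[-1])
        if flat.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit a scaler")
        mean = flat.mean(axis=0)
        scale = flat.std(axis=0)
        zero = scale == 0.0
        if zero.any():
            warnings.warn(
                f"zero-variance columns {np.flatnonzero(zero).tolist()}: scale set to 1",
                stacklevel=2,
            )
            scale = np.where(zero, 1.0, scale)
        return Scaler(mean, scale)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.scale

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values * self.scale + self.mean


@dataclass
class LossBreakdown:
    """The eight (or fewer, for ablations) loss terms and their mean."""

    terms: dict[str, float]
    total: float
    total_tensor: Tensor | None = None

    @property
    def n_terms(self) -> int:
        return len(self.terms)


def _mse(pred: Tensor, target: Tensor) -> Tensor:
    diff = pred - target
    return (diff * diff).mean()


def assemble_loss(
    predictions: dict[str, Tensor],
    target: Tensor | np.ndarray,
    cfg: DeepCropConfig,
    factor_scaler: Scaler,
    mode: str = "multitask",
) -> LossBreakdown:
    """Build the training loss from per-decoder predictions.

    ``target`` is the standardized (batch, L, n_factors) label window.
    Modes: "multitask" (6 decoder MSEs + 2 conservation terms),
    "no_conservation" (6 decoder MSEs), "single" (one MSE over all factors).
    """
    if not isinstance(target, Tensor):
        target = Tensor(target)
    for name in predictions:
        if name not in cfg.decoder_map:
            raise ValueError(f"prediction from unknown decoder {name!r}")
    terms: dict[str, Tensor] = {}
    if mode == "single":
        stacked = Tensor.concat(list(predictions.values()), axis=-1)
        cols = [c for name in predictions for c in cfg.factor_columns(name)]
        terms["all"] = _mse(stacked, target[:, :, cols])
    elif mode in ("multitask", "no_conservation"):
        for name, pred in predictions.items():
            cols = cfg.factor_columns(name)
            if pred.shape[-1] != len(cols):
                raise ValueError(
                    f"decoder {name!r} emits {pred.shape[-1]} factors, "
                    f"expected {len(cols)}"
                )
            terms[name] = _mse(pred, target[:, :, cols])
        if mode == "multitask":
            for label, group in (
                ("vegetative_fw", F.VEGETATIVE_FW),
                ("vegetative_dw", F.VEGETATIVE_DW),
            ):
                terms[label] = _conservation_term(
                    predictions, target, group, cfg, factor_scaler
                )
    else:
        raise ValueError(f"unknown loss mode {mode!r}")

    total = terms[next(iter(terms))] * 0.0
    for t in terms.values():
        total = total + t
    total = total * (1.0 / len(terms))
    return LossBreakdown(
        terms={k: v.item() for k, v in terms.items()},
        total=total.item(),
        total_tensor=total,
    )


def _conservation_term(
    predictions: dict[str, Tensor],
    target: Tensor,
    group: tuple[str, ...],
    cfg: DeepCropConfig,
    scaler: Scaler,
) -> Tensor:
    """MSE between predicted and target vegetative-organ weight sums.

    Sums are formed in natural units (the scaler's affine inverse; offsets
    cancel in the difference) and normalized by the summed scales.
    """
    idx = F.factor_index(cfg.factors)
    decoder_of = {f: d for d, fs in cfg.decoder_map.items() for f in fs}
    pred_sum = None
    tgt_sum = None
    sigma_total = 0.0
    for factor in group:
        col = idx[factor]
        dec = decoder_of[factor]
        pos = cfg.decoder_map[dec].index(factor)
        sigma = float(scaler.scale[col])
        sigma_total += sigma
        p = predictions[dec][:, :, pos] * sigma
        t = target[:, :, col] * sigma
        pred_sum = p if pred_sum is None else pred_sum + p
        tgt_sum = t if tgt_sum is None else tgt_sum + t
    return _mse(pred_sum * (1.0 / sigma_total), tgt_sum * (1.0 / sigma_total))


@dataclass
class TrainingSettings:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    loss_mode: str = "multitask"
    patience: int | None = None        # early stop on validation total
    seed: int = 0


@dataclass
class TrainedModel:
    """A trained model with the scalers simulation needs."""

    model: DeepCropModel
    cfg: DeepCropConfig
    feature_scaler: Scaler
    factor_scaler: Scaler


def _epoch_eval(
    model: DeepCropModel,
    env: np.ndarray,
    prev: np.ndarray,
    target: np.ndarray,
    cfg: DeepCropConfig,
    factor_scaler: Scaler,
    mode: str,
    batch_size: int = 64,
) -> float:
    total = 0.0
    n = env.shape[0]
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        preds, _ = model.forward(env[sl], prev[sl], train=False)
        breakdown = assemble_loss(preds, target[sl], cfg, factor_scaler, mode)
        total += breakdown.total * (sl.stop - sl.start)
    return total / n


def train(
    train_set: WindowDataset,
    val_set: WindowDataset,
    cfg: DeepCropConfig,
    settings: TrainingSettings | None = None,
) -> tuple[TrainedModel, pd.DataFrame]:
    """Seeded teacher-forced training.

    Standardizes with training-split statistics only, minimizes the
    averaged loss with Adam, and returns the parameter state with the
    lowest validation total together with the per-epoch trace.
    """
    settings = settings or TrainingSettings()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("empty train or validation set")

    feature_scaler = Scaler.fit(train_set.env)
    factor_scaler = Scaler.fit(
        np.concatenate([train_set.prev, train_set.target], axis=0)
    )
    env_tr = feature_scaler.transform(train_set.env)
    prev_tr = factor_scaler.transform(train_set.prev)
    tgt_tr = factor_scaler.transform(train_set.target)
    env_va = feature_scaler.transform(val_set.env)
    prev_va = factor_scaler.transform(val_set.prev)
    tgt_va = factor_scaler.transform(val_set.target)

    model = DeepCropModel(cfg)
    optimizer = Adam(model.parameters(), lr=settings.learning_rate)
    rng = np.random.default_rng(settings.seed)

    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    rows = []
    term_names: list[str] = []
    n = len(train_set)
    since_best = 0

    for epoch in range(settings.epochs):
        order = rng.permutation(n)
        epoch_terms: dict[str, float] = {}
        epoch_total = 0.0
        n_batches = 0
        for start in range(0, n, settings.batch_size):
            idx = order[start : start + settings.batch_size]
            preds, _ = model.forward(env_tr[idx], prev_tr[idx], train=True, rng=rng)
            breakdown = assemble_loss(
                preds, tgt_tr[idx], cfg, factor_scaler, settings.loss_mode
            )
            if not np.isfinite(breakdown.total):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: total={breakdown.total}"
                )
            optimizer.zero_grad()
            breakdown.total_tensor.backward()
            optimizer.step()
            for k, v in breakdown.terms.items():
                epoch_terms[k] = epoch_terms.get(k, 0.0) + v
            epoch_total += breakdown.total
            n_batches += 1
        term_names = list(epoch_terms)
        val_total = _epoch_eval(
            model, env_va, prev_va, tgt_va, cfg, factor_scaler, settings.loss_mode
        )
        rows.append(
            {"epoch": epoch}
            | {k: v / n_batches for k, v in epoch_terms.items()}
            | {"total": epoch_total / n_batches, "val_total": val_total}
        )
        if val_total < best_val:
            best_val = val_total
            best_state = model.state_dict()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if settings.patience is not None and since_best > settings.patience:
                break

    model.load_state_dict(best_state)
    trace = pd.DataFrame(rows)
    trace.attrs["best_epoch"] = best_epoch
    trace.attrs["best_val"] = best_val
    return TrainedModel(model, cfg, feature_scaler, factor_scaler), trace


def save_checkpoint(trained: TrainedModel, path) -> None:
    """Serialize model parameters, config and scalers to one .npz file."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": trained.cfg.to_dict(),
    }
    arrays = {f"state/{k}": v for k, v in trained.model.state_dict().items()}
    arrays["scaler/feature_mean"] = trained.feature_scaler.mean
    arrays["scaler/feature_scale"] = trained.feature_scaler.scale
    arrays["scaler/factor_mean"] = trained.factor_scaler.mean
    arrays["scaler/factor_scale"] = trained.factor_scaler.scale
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path, expect_decoder_map: dict | None = None) -> TrainedModel:
    try:
        archive = np.load(path)
    except (OSError, ValueError) as err:
        raise ValueError(f"cannot read checkpoint {path}: {err}") from err
    if "meta" not in archive:
        raise ValueError(f"{path} is not a model checkpoint (no meta entry)")
    meta = json.loads(archive["meta"].tobytes().decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
    cfg = DeepCropConfig.from_dict(meta["config"])
    if expect_decoder_map is not None:
        stored = {k: tuple(v) for k, v in cfg.decoder_map.items()}
        wanted = {k: tuple(v) for k, v in expect_decoder_map.items()}
        if stored != wanted:
            raise ValueError(
                "checkpoint decoder map does not match the expected one: "
                f"stored={sorted(stored)} expected={sorted(wanted)}"
            )
    model = DeepCropModel(cfg)
    state = {
        k[len("state/"):]: archive[k] for k in archive.files if k.startswith("state/")
    }
    model.load_state_dict(state)
    required = [
        "scaler/feature_mean", "scaler/feature_scale",
        "scaler/factor_mean", "scaler/factor_scale",
    ]
    missing = [k for k in required if k not in archive.files]
    if missing:
        raise ValueError(f"checkpoint missing scaler statistics: {missing}")
    return TrainedModel(
        model,
        cfg,
        Scaler(archive["scaler/feature_mean"], archive["scaler/feature_scale"]),
        Scaler(archive["scaler/factor_mean"], archive["scaler/factor_scale"]),
    )
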