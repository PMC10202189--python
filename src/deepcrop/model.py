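"""The attention-based crop model: shared encoder, input gate, six decoders.

The encoder consumes the hourly environment window (24*L rows of 7
features): multi-branch convolutional embedding, sinusoidal positional
encoding, then unmasked self-attention blocks.  An input gate blends the
encoded memory with a linear projection of the raw (embedded-width) input,
because the raw environment itself carries signal the encoding may dilute.
Each decoder consumes the previous L days of growth factors through its own
convolutional embedding, applies look-ahead-masked self-attention and
cross-attention over the gated memory, and maps its block-stack output to
its factor group through a linear head.  All six decoders share the memory
and have identical structure up to head width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import factors as F
from .nn import (
    ConvEmbed,
    Dropout,
    FeedForward,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    Tensor,
    look_ahead_mask,
    positional_encoding,
)


@dataclass
class DeepCropConfig:
    """Architecture hyperparameters.

    Defaults are a desk-scale configuration: 7-day memory, 32-wide model
    with 4 heads and 2 encoder / 2 decoder blocks, small enough to train in
    minutes on one CPU core while keeping the full architecture.
    """

    memory_length: int = 7
    d_model: int = 32
    n_heads: int = 4
    n_encoder_blocks: int = 2
    n_decoder_blocks: int = 2
    kernel_sizes: tuple[int, ...] = (1, 3, 5, 7)
    d_ff: int = 64
    dropout: float = 0.1
    decoder_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in F.DECODER_MAP.items()}
    )
    factors: tuple[str, ...] = F.FACTORS
    n_features: int = len(F.FEATURES)
    use_input_gate: bool = True
    #: input features zeroed out everywhere (input-ablation switch)
    zero_features: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.memory_length < 1:
            raise ValueError("memory_length must be >= 1")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.decoder_map = {k: tuple(v) for k, v in self.decoder_map.items()}
        self.factors = tuple(self.factors)
        F.validate_decoder_map(self.decoder_map, self.factors)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def input_steps(self) -> int:
        return 24 * self.memory_length

    def factor_columns(self, decoder: str) -> list[int]:
        idx = F.factor_index(self.factors)
        return [idx[f] for f in self.decoder_map[decoder]]

    def to_dict(self) -> dict:
        return {
            "memory_length": self.memory_length,
            "d_model": self.d_model,
            "n_heads": self.n_heads,
            "n_encoder_blocks": self.n_encoder_blocks,
            "n_decoder_blocks": self.n_decoder_blocks,
            "kernel_sizes": list(self.kernel_sizes),
            "d_ff": self.d_ff,
            "dropout": self.dropout,
            "decoder_map": {k: list(v) for k, v in self.decoder_map.items()},
            "factors": list(self.factors),
            "n_features": self.n_features,
            "use_input_gate": self.use_input_gate,
            "zero_features": list(self.zero_features),
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "DeepCropConfig":
        d = dict(d)
        d["kernel_sizes"] = tuple(d["kernel_sizes"])
        d["zero_features"] = tuple(d.get("zero_features", ()))
        d["factors"] = tuple(d["factors"])
        d["decoder_map"] = {k: tuple(v) for k, v in d["decoder_map"].items()}
        return DeepCropConfig(**d)


@dataclass
class AttentionMap:
    """Inspection record of one attention application."""

    decoder: str               # "" for encoder self-attention
    block: int
    kind: str                  # "self" | "cross"
    weights: np.ndarray        # (batch, heads, queries, keys)


class EncoderBlock(Module):
    def __init__(self, cfg: DeepCropConfig, rng):
        self.attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.norm1 = LayerNorm(cfg.d_model)
        self.ff = FeedForward(cfg.d_model, cfg.d_ff, rng)
        self.norm2 = LayerNorm(cfg.d_model)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x, train, rng):
        attended, weights = self.attn(x, x, x)
        x = self.norm1(x + self.drop(attended, train, rng))
        x = self.norm2(x + self.drop(self.ff(x), train, rng))
        return x, weights


class DecoderBlock(Module):
    def __init__(self, cfg: DeepCropConfig, rng):
        self.self_attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.norm1 = LayerNorm(cfg.d_model)
        self.cross_attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.norm2 = LayerNorm(cfg.d_model)
        self.ff = FeedForward(cfg.d_model, cfg.d_ff, rng)
        self.norm3 = LayerNorm(cfg.d_model)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x, memory, causal_mask, train, rng):
        attended, self_w = self.self_attn(x, x, x, keep_mask=causal_mask)
        x = self.norm1(x + self.drop(attended, train, rng))
        crossed, cross_w = self.cross_attn(x, memory, memory)
        x = self.norm2(x + self.drop(crossed, train, rng))
        x = self.norm3(x + self.drop(self.ff(x), train, rng))
        return x, self_w, cross_w


class Decoder(Module):
    def __init__(self, cfg: DeepCropConfig, n_out: int, rng):
        self.embed = ConvEmbed(cfg.n_factors, cfg.d_model, cfg.kernel_sizes, rng)
        self.blocks = [DecoderBlock(cfg, rng) for _ in range(cfg.n_decoder_blocks)]
        self.head = Linear(cfg.d_model, n_out, rng)
        self.pos = positional_encoding(cfg.memory_length, cfg.d_model)
        self.mask = look_ahead_mask(cfg.memory_length)

    def __call__(self, prev_growth, memory, train, rng, name=""):
        x = self.embed(prev_growth, train) + Tensor(self.pos)
        maps = []
        hidden = None
        for i, block in enumerate(self.blocks):
            x, self_w, cross_w = block(x, memory, self.mask, train, rng)
            maps.append(AttentionMap(name, i, "self", self_w))
            maps.append(AttentionMap(name, i, "cross", cross_w))
        hidden = x
        return self.head(x), hidden, maps


class InputGate(Module):
    """Sigmoid blend of encoded memory and projected raw input.

    g = sigmoid(affine([projected_raw, encoded])); out = g * encoded
    + (1 - g) * projected_raw.
    """

    def __init__(self, cfg: DeepCropConfig, rng):
        self.proj = Linear(cfg.n_features, cfg.d_model, rng)
        self.gate = Linear(2 * cfg.d_model, cfg.d_model, rng)

    def __call__(self, raw, encoded):
        projected = self.proj(raw)
        g = self.gate(Tensor.concat([projected, encoded], axis=-1)).sigmoid()
        return g * encoded + (1.0 - g) * projected


class DeepCropModel(Module):
    """Shared encoder + input gate + multitask decoders."""

    def __init__(self, cfg: DeepCropConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.embed = ConvEmbed(cfg.n_features, cfg.d_model, cfg.kernel_sizes, rng)
        self.enc_blocks = [EncoderBlock(cfg, rng) for _ in range(cfg.n_encoder_blocks)]
        self.gate = InputGate(cfg, rng) if cfg.use_input_gate else None
        self.decoders = {
            name: Decoder(cfg, len(group), rng)
            for name, group in cfg.decoder_map.items()
        }
        self.pos_enc = positional_encoding(cfg.input_steps, cfg.d_model)
        self.drop = Dropout(cfg.dropout)

    def _children(self):
        yield from super()._children()
        for name, dec in self.decoders.items():
            yield f"decoders.{name}", dec

    def encode(self, features: Tensor, train: bool, rng,
               collect: list | None = None) -> Tensor:
        if features.ndim != 3 or features.shape[1:] != (
            self.cfg.input_steps, self.cfg.n_features
        ):
            raise ValueError(
                f"expected features (batch, {self.cfg.input_steps}, "
                f"{self.cfg.n_features}), got {features.shape}"
            )
        x = self.embed(features, train) + Tensor(self.pos_enc)
        x = self.drop(x, train, rng)
        for i, block in enumerate(self.enc_blocks):
            x, weights = block(x, train, rng)
            if collect is not None:
                collect.append(AttentionMap("", i, "self", weights))
        return x

    def forward(
        self,
        features: np.ndarray | Tensor,
        prev_growth: np.ndarray | Tensor,
        train: bool = False,
        rng: np.random.Generator | None = None,
        collect_attention: bool = False,
        collect_hidden: bool = False,
    ):
        """Run the full model on standardized inputs.

        ``features``: (batch, 24*L, n_features); ``prev_growth``:
        (batch, L, n_factors).  Returns ``(predictions, extras)`` where
        predictions maps decoder name -> Tensor (batch, L, k_d) and extras
        holds attention maps / hidden states when requested.
        """
        rng = rng or np.random.default_rng(0)
        if not isinstance(features, Tensor):
            features = Tensor(features)
        if not isinstance(prev_growth, Tensor):
            prev_growth = Tensor(prev_growth)
        if prev_growth.shape[1:] != (self.cfg.memory_length, self.cfg.n_factors):
            raise ValueError(
                f"expected prev_growth (batch, {self.cfg.memory_length}, "
                f"{self.cfg.n_factors}), got {prev_growth.shape}"
            )
        maps: list[AttentionMap] = [] if collect_attention else None
        memory = self.encode(features, train, rng, collect=maps)
        if self.gate is not None:
            memory = self.gate(features, memory)
        predictions: dict[str, Tensor] = {}
        hidden: dict[str, np.ndarray] = {}
        for name, decoder in self.decoders.items():
            out, h, dec_maps = decoder(prev_growth, memory, train, rng, name=name)
            predictions[name] = out
            if collect_hidden:
                hidden[name] = h.data
            if collect_attention:
                maps.extend(dec_maps)
        extras = {"attention": maps or [], "hidden": hidden}
        return predictions, extras

    def predict(self, features: np.ndarray, prev_growth: np.ndarray) -> dict[str, np.ndarray]:
        """Inference-mode forward returning plain arrays."""
        preds, _ = self.forward(features, prev_growth, train=False)
        return {k: v.data for k, v in preds.items()}
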