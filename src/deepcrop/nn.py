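"""Minimal reverse-mode autodiff and neural layers on NumPy.

Implements exactly the primitives the crop model needs: broadcast-aware
elementwise arithmetic, batched matmul, slicing/concatenation/padding,
masked softmax (masked weights are exactly zero), layer and batch
normalization, dropout, and an Adam optimizer.  Gradients are validated
against finite differences in the test suite.

Tensors wrap float64 arrays; a backward pass walks the recorded graph in
reverse topological order.  Constants (inputs, masks) are Tensors with
``requires_grad=False``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Module", "Linear", "LayerNorm", "BatchNorm", "Dropout",
    "FeedForward", "MultiHeadAttention", "ConvEmbed", "Adam",
    "masked_softmax", "positional_encoding", "look_ahead_mask",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = (
        "data", "grad", "requires_grad", "_parents", "_backward", "_grad_aliased"
    )

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self._grad_aliased = False

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # First contribution aliases the incoming array (no copy); a second
        # contribution replaces it by a fresh sum, so aliased buffers are
        # never mutated in place.
        if self.grad is None:
            self.grad = grad
            self._grad_aliased = True
        elif self._grad_aliased:
            self.grad = self.grad + grad
            self._grad_aliased = False
        else:
            self.grad += grad

    def _owned_grad(self) -> np.ndarray:
        """Zero-initialized (or safely owned) gradient buffer for in-place
        scatter updates."""
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
            self._grad_aliased = False
        elif self._grad_aliased:
            self.grad = self.grad + 0.0
            self._grad_aliased = False
        return self.grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ other.data.swapaxes(-1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(self.data.swapaxes(-1, -2) @ g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, axes):
        inverse = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inverse))

        return Tensor._make(out_data, (self,), backward)

    @staticmethod
    def _is_basic_index(idx) -> bool:
        parts = idx if isinstance(idx, tuple) else (idx,)
        return all(isinstance(p, (int, slice, type(None), type(Ellipsis))) for p in parts)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                buf = self._owned_grad()
                if self._is_basic_index(idx):
                    buf[idx] += g  # basic indexing never repeats elements
                else:
                    np.add.at(buf, idx, g)

        return Tensor._make(out_data, (self,), backward)

    def pad_time(self, left: int):
        """Zero-pad ``left`` steps at the start of axis 1 (batch, time, ch)."""
        if left == 0:
            return self
        width = [(0, 0)] * self.ndim
        width[1] = (left, 0)
        out_data = np.pad(self.data, width)

        def backward(g):
            if self.requires_grad:
                self._accum(g[:, left:, ...])

        return Tensor._make(out_data, (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        return Tensor._make(out_data, tuple(tensors), backward)

    # -- nonlinearities and reductions ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0.0))

        return Tensor._make(out_data, (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            # read-only broadcast view: _accum never mutates aliased grads
            self._accum(np.broadcast_to(g, self.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def masked_softmax(logits: Tensor, keep: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; entries where ``keep`` is 0 get weight
    exactly 0 (renormalized over kept entries)."""
    if keep is None:
        shift = logits.data.max(axis=-1, keepdims=True)
        e = np.exp(logits.data - shift)
    else:
        # stabilizing max over kept entries only, so masked logits cannot
        # perturb the kept weights even at the bit level
        kept = np.where(keep > 0, logits.data, -np.inf)
        shift = kept.max(axis=-1, keepdims=True)
        e = np.exp(kept - shift, where=np.isfinite(kept), out=np.zeros_like(kept))
    w = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        if logits.requires_grad:
            dot = (g * w).sum(axis=-1, keepdims=True)
            logits._accum(w * (g - dot))

    return Tensor._make(w, (logits,), backward)


def positional_encoding(steps: int, d_model: int) -> np.ndarray:
    """Standard sinusoidal positional code, shape (steps, d_model)."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    pos = np.arange(steps)[:, None].astype(float)
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    code = np.empty((steps, d_model))
    code[:, 0::2] = np.sin(angle[:, 0::2])
    code[:, 1::2] = np.cos(angle[:, 1::2])
    return code


def look_ahead_mask(steps: int) -> np.ndarray:
    """Causal keep-mask: entry (i, j) is 1 iff key j <= query i."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    return np.tril(np.ones((steps, steps)))


# -- modules --------------------------------------------------------------


class Module:
    """Base class: parameter/buffer discovery by attribute walking."""

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in getattr(self, "_buffers", {}).items():
            yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}{name}.")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        expected = {f"param:{k}" for k in params} | {f"buffer:{k}" for k in buffers}
        if expected != set(state):
            missing = sorted(expected - set(state))
            extra = sorted(set(state) - expected)
            raise ValueError(f"state mismatch (missing={missing}, unexpected={extra})")
        for key, value in state.items():
            kind, name = key.split(":", 1)
            target = params[name].data if kind == "param" else buffers[name]
            if target.shape != value.shape:
                raise ValueError(f"shape mismatch for {key}")
            target[...] = value


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Tensor(_xavier(rng, d_in, d_out, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


class BatchNorm(Module):
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, d: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self._buffers = {
            "running_mean": np.zeros(d),
            "running_var": np.ones(d),
        }

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.mean(axis=(0, 1), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 1), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1.0 - m
            self._buffers["running_mean"] += m * mu.data.ravel()
            self._buffers["running_var"] *= 1.0 - m
            self._buffers["running_var"] += m * var.data.ravel()
            xn = xc * (var + self.eps) ** -0.5
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
            xn = (x - mu) * Tensor((var + self.eps) ** -0.5)
        return xn * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator) -> Tensor:
        if not train or self.rate == 0.0:
            return x
        keep = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(keep)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.lin1 = Linear(d_model, d_ff, rng)
        self.lin2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class MultiHeadAttention(Module):
    """Scaled dot-product attention with head split/merge.

    ``keep_mask`` (queries, keys) entries of 0 receive exactly zero weight.
    Returns the mixed values and the attention weights
    (batch, heads, queries, keys) as a plain array for inspection.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.d_head).transpose((0, 2, 1, 3))

    def __call__(
        self, query: Tensor, key: Tensor, value: Tensor,
        keep_mask: np.ndarray | None = None,
    ) -> tuple[Tensor, np.ndarray]:
        b, tq, d_model = query.shape
        q = self._split(self.wq(query))
        k = self._split(self.wk(key))
        v = self._split(self.wv(value))
        logits = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(self.d_head))
        weights = masked_softmax(logits, keep_mask)
        mixed = weights @ v
        merged = mixed.transpose((0, 2, 1, 3)).reshape(b, tq, d_model)
        return self.wo(merged), weights.data


class ConvEmbed(Module):
    """Multi-branch causal 1-D convolution embedding.

    One branch per kernel size; each branch maps the input channels to
    d_model / n_branches channels with left (causal) zero padding, so the
    embedding expands the channel dimension and position t never sees
    inputs after t.  Branch outputs are concatenated channel-wise and batch
    normalized.
    """

    def __init__(
        self, d_in: int, d_model: int, kernel_sizes: tuple[int, ...],
        rng: np.random.Generator,
    ):
        if d_model % len(kernel_sizes) != 0:
            raise ValueError(
                f"d_model={d_model} not divisible by {len(kernel_sizes)} conv branches"
            )
        self.kernel_sizes = tuple(kernel_sizes)
        d_branch = d_model // len(kernel_sizes)
        self.weights = [
            Tensor(_xavier(rng, k * d_in, d_branch, (k, d_in, d_branch)), requires_grad=True)
            for k in kernel_sizes
        ]
        self.biases = [Tensor(np.zeros(d_branch), requires_grad=True) for _ in kernel_sizes]
        self.norm = BatchNorm(d_model)

    def named_parameters(self, prefix: str = ""):
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            yield f"{prefix}weights.{i}", w
            yield f"{prefix}biases.{i}", b
        yield from self.norm.named_parameters(f"{prefix}norm.")

    def named_buffers(self, prefix: str = ""):
        yield from self.norm.named_buffers(f"{prefix}norm.")

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        t = x.shape[1]
        branches = []
        for k, w, b in zip(self.kernel_sizes, self.weights, self.biases):
            padded = x.pad_time(k - 1)
            taps = [padded[:, j : j + t, :] @ w[j] for j in range(k)]
            acc = taps[0]
            for tap in taps[1:]:
                acc = acc + tap
            branches.append(acc + b)
        out = Tensor.concat(branches, axis=-1)
        return self.norm(out, train)


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * p.grad**2
            m_hat = self.m[i] / (1.0 - self.b1**self.t)
            v_hat = self.v[i] / (1.0 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
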