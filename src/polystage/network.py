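"""Per-channel-group convolutional staging networks.

Five models score every record: four fed by a single channel (EEG C3/A2,
EEG C4/A1, EOG left, EOG right) and a fifth fed by all five channels.  Each
network is a stack of two block types over the 90-s spliced window:

* **conv block** — two convolutions, each followed by batch normalization
  and ReLU; a short connection concatenates the block input with the
  two-convolution output along the channel axis; an average-pooling layer
  then halves the temporal length;
* **trans block** — two convolutions with strides 2 and 1 (each BN+ReLU),
  halving the temporal length;

followed by a flatten layer and a dense layer producing the five stage
logits.  Temporal length after any halving block is ``ceil(L/2)``.

The implementation is plain numpy (im2col convolutions against BLAS, manual
reverse-mode gradients, Adam, class-weighted cross-entropy) and is
bit-deterministic under a fixed seed on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import ROLES, STAGES
from .preprocess import SpliceWindow


class ArchitectureError(ValueError):
    """The input is too short for the configured block stack."""


class DegenerateDataError(ValueError):
    """Training data does not contain at least two classes."""


# ---------------------------------------------------------------------------
# Channel groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelGroupSpec:
    group_id: int
    roles: tuple[str, ...]

    def indices(self) -> list[int]:
        return [ROLES.index(r) for r in self.roles]


def default_groups(paired_eog: bool = False) -> list[list[str]]:
    """The five staging groups: four single-signal groups + one all-channel.

    ``paired_eog=True`` merges the two EOG singletons into one 2-channel
    group (an alternative reading of the montage grouping).
    """
    if paired_eog:
        return [["EEG_C3A2"], ["EEG_C4A1"], ["EOG_L", "EOG_R"], list(ROLES)]
    return [["EEG_C3A2"], ["EEG_C4A1"], ["EOG_L"], ["EOG_R"], list(ROLES)]


def group_specs(paired_eog: bool = False) -> list[ChannelGroupSpec]:
    return [
        ChannelGroupSpec(i + 1, tuple(roles))
        for i, roles in enumerate(default_groups(paired_eog))
    ]


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _same_pad(L: int, k: int, stride: int) -> tuple[int, int, int]:
    out = -(-L // stride)                       # ceil
    pad = max((out - 1) * stride + k - L, 0)
    return out, pad // 2, pad - pad // 2


class _Conv1d:
    """Same-padded 1-D convolution; output length ceil(L / stride)."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * k))
        self.W = (rng.standard_normal((out_ch, in_ch, k)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.k, self.stride = k, stride

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        out_len, pl, pr = _same_pad(L, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        win = win[:, :, :: self.stride, :]       # (B, C, out_len, k)
        cols = win.transpose(0, 2, 1, 3).reshape(B, out_len, C * self.k)
        Wm = self.W.reshape(self.W.shape[0], -1).T       # (C*k, out_ch)
        y = cols @ Wm + self.b
        if train:
            self._cache = (cols, (B, C, L, out_len, pl))
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray):
        cols, (B, C, L, out_len, pl) = self._cache
        dyt = dy.transpose(0, 2, 1)              # (B, out_len, out_ch)
        self.dW = np.tensordot(cols, dyt, axes=([0, 1], [0, 1])).T \
            .reshape(self.W.shape).astype(np.float32)
        self.db = dyt.sum(axis=(0, 1)).astype(np.float32)
        Lp = L + pl + ( (out_len - 1) * self.stride + self.k - L - pl )
        dxp = np.zeros((B, C, max(Lp, pl + L)), dtype=np.float32)
        for kk in range(self.k):
            contrib = np.einsum("bol,oc->bcl", dy, self.W[:, :, kk])
            dxp[:, :, kk : kk + self.stride * out_len : self.stride] += contrib
        self._cache = None
        return dxp[:, :, pl : pl + L]

    def grads(self):
        return [("W", self.dW), ("b", self.db)]


class _BatchNorm1d:
    def __init__(self, C: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(C, dtype=np.float32)
        self.beta = np.zeros(C, dtype=np.float32)
        self.run_mean = np.zeros(C, dtype=np.float64)
        self.run_var = np.ones(C, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean = self.run_mean.astype(np.float32)
            var = self.run_var.astype(np.float32)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv[:, None]
        if train:
            self._cache = (xhat, inv.astype(np.float32))
        return (self.gamma[:, None] * xhat + self.beta[:, None]).astype(np.float32)

    def backward(self, dy: np.ndarray):
        xhat, inv = self._cache
        n = dy.shape[0] * dy.shape[2]
        self.dgamma = (dy * xhat).sum(axis=(0, 2)).astype(np.float32)
        self.dbeta = dy.sum(axis=(0, 2)).astype(np.float32)
        dxhat = dy * self.gamma[:, None]
        dx = (inv[:, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )
        self._cache = None
        return dx.astype(np.float32)

    def grads(self):
        return [("gamma", self.dgamma), ("beta", self.dbeta)]


class _ReLU:
    def params(self):
        return []

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx

    def grads(self):
        return []


class _AvgPoolHalve:
    """Average pooling, kernel 2 stride 2; odd tails pass through (ceil(L/2))."""

    def params(self):
        return []

    def forward(self, x, train):
        B, C, L = x.shape
        self._L = L
        even = L - (L % 2)
        y_even = 0.5 * (x[:, :, 0:even:2] + x[:, :, 1:even:2])
        if L % 2:
            return np.concatenate([y_even, x[:, :, -1:]], axis=2)
        return y_even

    def backward(self, dy):
        L = self._L
        B, C, _ = dy.shape
        dx = np.empty((B, C, L), dtype=dy.dtype)
        n_pairs = L // 2
        dx[:, :, 0 : 2 * n_pairs : 2] = 0.5 * dy[:, :, :n_pairs]
        dx[:, :, 1 : 2 * n_pairs : 2] = 0.5 * dy[:, :, :n_pairs]
        if L % 2:
            dx[:, :, -1] = dy[:, :, -1]
        return dx

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = (self._x.T @ dy).astype(np.float32)
        self.db = dy.sum(axis=0).astype(np.float32)
        dx = dy @ self.W.T
        self._x = None
        return dx

    def grads(self):
        return [("W", self.dW), ("b", self.db)]


# ---------------------------------------------------------------------------
# Blocks and network spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    kind: str                    # "conv_block" | "trans_block"
    n_filters: int
    kernel_size: int = 5
    kernel_size_2: int = 3       # second convolution of the block

    def __post_init__(self):
        if self.kind not in ("conv_block", "trans_block"):
            raise ValueError(f"unknown block kind {self.kind!r}")


@dataclass(frozen=True)
class NetworkSpec:
    """Block stack + implicit flatten/dense head emitting 5 stage logits."""

    blocks: tuple[BlockSpec, ...]
    n_classes: int = len(STAGES)


def default_network_spec() -> NetworkSpec:
    """Desk-scale reference stack: six halving blocks, 6000 → 47 samples."""
    return NetworkSpec(blocks=(
        BlockSpec("trans_block", 6, 7, 3),
        BlockSpec("trans_block", 8, 5, 3),
        BlockSpec("conv_block", 8, 5, 5),
        BlockSpec("trans_block", 12, 5, 3),
        BlockSpec("trans_block", 12, 5, 3),
        BlockSpec("conv_block", 12, 3, 3),
    ))


class _ConvBlock:
    """conv→BN→ReLU ×2, input∥output channel concat, then halving avg-pool."""

    def __init__(self, in_ch: int, spec: BlockSpec, rng):
        f = spec.n_filters
        self.c1 = _Conv1d(in_ch, f, spec.kernel_size, 1, rng)
        self.bn1 = _BatchNorm1d(f)
        self.r1 = _ReLU()
        self.c2 = _Conv1d(f, f, spec.kernel_size_2, 1, rng)
        self.bn2 = _BatchNorm1d(f)
        self.r2 = _ReLU()
        self.pool = _AvgPoolHalve()
        self.in_ch = in_ch
        self.out_ch = in_ch + f              # concatenation
        self._inner = [self.c1, self.bn1, self.r1, self.c2, self.bn2, self.r2]

    def layers(self):
        return self._inner + [self.pool]

    def out_len(self, L: int) -> int:
        return -(-L // 2)

    def forward(self, x, train):
        h = x
        for lay in self._inner:
            h = lay.forward(h, train)
        cat = np.concatenate([x, h], axis=1)
        return self.pool.forward(cat, train)

    def backward(self, dy):
        dcat = self.pool.backward(dy)
        dx_skip = dcat[:, : self.in_ch]
        dh = dcat[:, self.in_ch :]
        for lay in reversed(self._inner):
            dh = lay.backward(dh)
        return dx_skip + dh


class _TransBlock:
    """Two convolutions with strides 2 and 1 (BN+ReLU each); halves length."""

    def __init__(self, in_ch: int, spec: BlockSpec, rng):
        f = spec.n_filters
        self.out_ch = f
        self._inner = [
            _Conv1d(in_ch, f, spec.kernel_size, 2, rng), _BatchNorm1d(f), _ReLU(),
            _Conv1d(f, f, spec.kernel_size_2, 1, rng), _BatchNorm1d(f), _ReLU(),
        ]

    def layers(self):
        return self._inner

    def out_len(self, L: int) -> int:
        return -(-L // 2)

    def forward(self, x, train):
        for lay in self._inner:
            x = lay.forward(x, train)
        return x

    def backward(self, dy):
        for lay in reversed(self._inner):
            dy = lay.backward(dy)
        return dy


class StagingModel:
    """One group's staging network: (n_channels × input_len) → 5 probabilities."""

    def __init__(self, spec: NetworkSpec, n_input_channels: int, input_len: int,
                 seed: int = 0):
        rng = np.random.default_rng((seed, 17))
        self.spec = spec
        self.n_input_channels = n_input_channels
        self.input_len = input_len
        self.blocks = []
        ch, L = n_input_channels, input_len
        for bs in spec.blocks:
            blk = (_ConvBlock if bs.kind == "conv_block" else _TransBlock)(ch, bs, rng)
            L_next = blk.out_len(L)
            if L_next < 1 or L < bs.kernel_size:
                raise ArchitectureError(
                    f"input length {input_len} too short for the block stack "
                    f"(length {L} reached before a kernel-{bs.kernel_size} block)"
                )
            self.blocks.append(blk)
            ch, L = blk.out_ch, L_next
        self.feature_len = ch * L
        self.dense = _Dense(self.feature_len, spec.n_classes, rng)

    # -- plumbing ----------------------------------------------------------
    def _layers(self):
        out = []
        for b in self.blocks:
            out.extend(b.layers())
        out.append(self.dense)
        return out

    def parameters(self):
        """Flat list of (layer, name, array) for the optimizer."""
        out = []
        for lay in self._layers():
            for name, arr in lay.params():
                out.append((lay, name, arr))
        return out

    def weights_digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for _, _, arr in self.parameters():
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def get_state(self) -> list[np.ndarray]:
        state = [arr.copy() for _, _, arr in self.parameters()]
        for lay in self._layers():
            if isinstance(lay, _BatchNorm1d):
                state.extend([lay.run_mean.copy(), lay.run_var.copy()])
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for (lay, name, arr), new in zip(params, state[: len(params)]):
            arr[...] = new
        rest = iter(state[len(params) :])
        for lay in self._layers():
            if isinstance(lay, _BatchNorm1d):
                lay.run_mean = next(rest).copy()
                lay.run_var = next(rest).copy()

    # -- forward/backward --------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x.astype(np.float32)
        for blk in self.blocks:
            h = blk.forward(h, train)
        self._flat_shape = h.shape
        return self.dense.forward(h.reshape(h.shape[0], -1), train)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.dense.backward(dlogits).reshape(self._flat_shape)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)

    def predict_proba_array(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Probabilities for an (n, C, L) array; invariant to batch partition."""
        if X.ndim != 3 or X.shape[1] != self.n_input_channels or \
                X.shape[2] != self.input_len:
            raise ValueError(
                f"expected input of shape (n, {self.n_input_channels}, "
                f"{self.input_len}), got {X.shape}"
            )
        out = np.empty((len(X), self.spec.n_classes), dtype=np.float64)
        for i in range(0, len(X), batch_size):
            logits = self.forward_logits(X[i : i + batch_size], train=False)
            out[i : i + batch_size] = _softmax(logits)
        return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def scale_spec_for_channels(spec: NetworkSpec, n_channels: int) -> NetworkSpec:
    """Widen the first two blocks for multi-channel inputs.

    A single-channel group needs only a few band filters early on, but the
    all-channel group must represent every channel's bands in its first
    feature maps; doubling the early widths removes that bottleneck.
    """
    if n_channels <= 1:
        return spec
    blocks = list(spec.blocks)
    for i in range(min(2, len(blocks))):
        b = blocks[i]
        blocks[i] = replace(b, n_filters=min(2 * b.n_filters, 16))
    return replace(spec, blocks=tuple(blocks))


def build_network(
    spec: NetworkSpec | None = None,
    n_input_channels: int = 1,
    input_len: int = 6000,
    seed: int = 0,
) -> StagingModel:
    """Instantiate a staging network for one channel group.

    The block widths are adapted to the input channel count via
    :func:`scale_spec_for_channels`.
    """
    spec = scale_spec_for_channels(spec or default_network_spec(), n_input_channels)
    return StagingModel(spec, n_input_channels, input_len, seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    max_epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 3e-3
    class_weighting: str = "inverse"     # "inverse" | "none"
    seed: int = 0
    patience: int = 3                    # early stopping on validation accuracy
    min_epochs: int = 2

    def __post_init__(self):
        if self.class_weighting not in ("inverse", "none"):
            raise ValueError("class_weighting must be 'inverse' or 'none'")


class _Adam:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(a) for _, _, a in params]
        self.v = [np.zeros_like(a) for _, _, a in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for i, ((_, _, p), g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)


def class_weights(y: np.ndarray, mode: str, n_classes: int = 5) -> np.ndarray:
    """Inverse-frequency weights normalized to mean 1 over present classes."""
    w = np.ones(n_classes, dtype=np.float64)
    if mode == "inverse":
        counts = np.bincount(y, minlength=n_classes).astype(np.float64)
        present = counts > 0
        w[present] = counts[present].sum() / (present.sum() * counts[present])
    return w


def train_model(
    model: StagingModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> dict:
    """Mini-batch Adam on class-weighted cross-entropy.

    Returns a history dict (per-epoch mean loss, train accuracy, validation
    accuracy) and leaves the model at its best-validation snapshot (final
    snapshot when no validation set is given).  Deterministic for a fixed
    ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training labels contain fewer than two stages")
    rng = np.random.default_rng((cfg.seed, 23))
    w_class = class_weights(y, cfg.class_weighting, model.spec.n_classes)
    opt = _Adam(model.parameters(), cfg.learning_rate)

    history = {"loss": [], "train_acc": [], "val_acc": []}
    best_val, best_state, since_best = -np.inf, None, 0
    n = len(X)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.forward_logits(xb, train=True)
            p = _softmax(logits)
            wb = w_class[yb]
            eps = 1e-12
            losses.append(float(-(wb * np.log(p[np.arange(len(yb)), yb] + eps)).mean()))
            correct += int((p.argmax(axis=1) == yb).sum())
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits *= (wb / len(yb))[:, None]
            model.backward(dlogits.astype(np.float32))
            opt.step([g for lay in model._layers() for _, g in lay.grads()])
        history["loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / n)

        if X_val is not None and len(X_val):
            val_acc = float(
                (model.predict_proba_array(X_val).argmax(axis=1) == y_val).mean()
            )
            history["val_acc"].append(val_acc)
            if val_acc > best_val:
                best_val, best_state, since_best = val_acc, model.get_state(), 0
            else:
                since_best += 1
                if epoch + 1 >= cfg.min_epochs and since_best >= cfg.patience:
                    break
        else:
            history["val_acc"].append(float("nan"))
    if best_state is not None:
        model.set_state(best_state)
    return history


def predict_proba(
    model: StagingModel,
    windows: "Sequence[SpliceWindow] | np.ndarray",
    batch_size: int = 256,
) -> np.ndarray:
    """Per-window stage probabilities, one normalized 5-vector per window."""
    if isinstance(windows, np.ndarray):
        X = windows.astype(np.float32)
    else:
        X = np.stack([w.data for w in windows]).astype(np.float32)
    return model.predict_proba_array(X, batch_size=batch_size)


def select_group_channels(X: np.ndarray, roles: Sequence[str]) -> np.ndarray:
    """Slice an (n, 5, L) window array down to one group's channels."""
    idx = [ROLES.index(r) for r in roles]
    return np.ascontiguousarray(X[:, idx, :])
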