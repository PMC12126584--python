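"""Compact Inception-style time-series classifier and five-member ensemble.

Architecture (per network): a stack of Inception modules, global average
pooling over time, and a fully connected softmax layer.  Each Inception
module applies a 1x1 bottleneck convolution and then three parallel
convolution branches with filter lengths (filter_size, filter_size/2,
filter_size/4, minimum 2); a fourth branch max-pools the module input
(window 3, stride 1, same length) and bottlenecks it with a 1x1
convolution.  Branch outputs are concatenated along channels, batch
normalized and passed through ReLU, so the output length always equals
the input length.  A residual shortcut (1x1-projected, batch normalized)
joins every third module, and always the final one.

Varying filter lengths give the network a large receptive field, suited to
movement patterns that evolve over seconds; ensembling five networks that
differ only in random initialization damps the high run-to-run variability
typical of a single network.

Training minimizes categorical cross-entropy with Adam (step size 1e-3,
batch size 64).  Everything — forward, backward, optimizer — is NumPy;
execution is deterministic for a fixed seed under single-threaded BLAS.

The ``branch_mode`` flag selects how "number of filters" is interpreted:
``"per_branch"`` (default) keeps three branches with ``n_filters`` filters
each; ``"halving_count"`` builds ``n_filters`` branches with halving filter
lengths and one filter each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import PredictionSet
from .windows import WindowedDataset

_EINSUM_KW = {"optimize": True}


@dataclass
class InceptionConfig:
    depth: int = 6
    filter_size: int = 40
    n_filters: int = 32
    bottleneck_channels: int = 32
    residual: bool = True
    branch_mode: str = "per_branch"  # or "halving_count"
    batch_size: int = 64
    max_epochs: int = 600
    learning_rate: float = 1e-3
    n_classes: int = 2
    n_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.filter_size < 2 or self.n_filters < 1:
            raise ValueError("invalid InceptionConfig")
        if self.branch_mode not in ("per_branch", "halving_count"):
            raise ValueError(f"unknown branch_mode {self.branch_mode!r}")


# ---------------------------------------------------------------------------
# Layers (forward caches what backward needs; grads align with params)


class _Conv1dSame:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 bias: bool = False) -> None:
        limit = np.sqrt(6.0 / (c_in * k + c_out * k))
        self.w = rng.uniform(-limit, limit, size=(c_out, c_in, k))
        self.b = np.zeros(c_out) if bias else None
        self.k = k
        self.left = (k - 1) // 2

    @property
    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.left, self.k - 1 - self.left)))
        out = np.zeros((n, self.w.shape[0], L))
        for j in range(self.k):
            out += np.einsum("oc,ncl->nol", self.w[:, :, j], xp[:, :, j:j + L],
                             **_EINSUM_KW)
        if self.b is not None:
            out += self.b[None, :, None]
        self._xp, self._L = xp, L
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, L = self._xp, self._L
        dw = np.empty_like(self.w)
        dxp = np.zeros_like(xp)
        for j in range(self.k):
            dw[:, :, j] = np.einsum("nol,ncl->oc", dy, xp[:, :, j:j + L], **_EINSUM_KW)
            dxp[:, :, j:j + L] += np.einsum("oc,nol->ncl", self.w[:, :, j], dy,
                                            **_EINSUM_KW)
        self.grads = [dw] if self.b is None else [dw, dy.sum(axis=(0, 2))]
        return dxp[:, :, self.left:self.left + L]


class _BatchNorm:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        dgamma = (dy * xhat).sum(axis=(0, 2))
        dbeta = dy.sum(axis=(0, 2))
        self.grads = [dgamma, dbeta]
        g = self.gamma[None, :, None]
        if not train:
            return dy * g * inv[None, :, None]
        m = shape[0] * shape[2]
        dxhat = dy * g
        return (inv[None, :, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool3Same:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1)), constant_values=-np.inf)
        stacked = np.stack([xp[:, :, j:j + L] for j in range(3)])
        self._idx = stacked.argmax(axis=0)
        self._L = L
        return stacked.max(axis=0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, L = dy.shape
        dxp = np.zeros((n, c, L + 2))
        for j in range(3):
            mask = self._idx == j
            np.add.at(dxp[:, :, j:j + L], mask.nonzero(), dy[mask])
        return dxp[:, :, 1:1 + L]


class _Dense:
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (f_in + f_out))
        self.w = rng.uniform(-limit, limit, size=(f_in, f_out))
        self.b = np.zeros(f_out)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads = [self._x.T @ dy, dy.sum(axis=0)]
        return dy @ self.w.T


def _branch_lengths(config: InceptionConfig) -> list[int]:
    if config.branch_mode == "per_branch":
        return [max(2, config.filter_size // d) for d in (1, 2, 4)]
    return [max(2, config.filter_size // 2**i) for i in range(config.n_filters)]


class InceptionModule:
    """Bottleneck + parallel convolutions + max-pool branch + BN + ReLU."""

    def __init__(self, c_in: int, config: InceptionConfig, rng: np.random.Generator) -> None:
        if c_in <= 0:
            raise ValueError("input channel count must be positive")
        lengths = _branch_lengths(config)
        per_branch = config.n_filters if config.branch_mode == "per_branch" else 1
        self.bottleneck = _Conv1dSame(c_in, config.bottleneck_channels, 1, rng)
        self.branches = [
            _Conv1dSame(config.bottleneck_channels, per_branch, k, rng) for k in lengths
        ]
        self.pool = _MaxPool3Same()
        self.pool_bottleneck = _Conv1dSame(c_in, per_branch, 1, rng)
        self.out_channels = per_branch * (len(lengths) + 1)
        self.bn = _BatchNorm(self.out_channels)
        self.relu = _ReLU()

    @property
    def layers(self):
        return [self.bottleneck, *self.branches, self.pool_bottleneck, self.bn]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = self.bottleneck.forward(x, train)
        branch_outs = [b.forward(z, train) for b in self.branches]
        pooled = self.pool.forward(x, train)
        branch_outs.append(self.pool_bottleneck.forward(pooled, train))
        self._split = np.cumsum([b.shape[1] for b in branch_outs])[:-1]
        cat = np.concatenate(branch_outs, axis=1)
        return self.relu.forward(self.bn.forward(cat, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dcat = self.bn.backward(self.relu.backward(dy))
        parts = np.split(dcat, self._split, axis=1)
        dz = None
        for branch, dpart in zip(self.branches, parts[:-1]):
            g = branch.backward(dpart)
            dz = g if dz is None else dz + g
        dx = self.bottleneck.backward(dz)
        dpool = self.pool_bottleneck.backward(parts[-1])
        dx += self.pool.backward(dpool)
        return dx


class InceptionNetwork:
    """Stacked Inception modules + GAP + dense softmax classifier."""

    def __init__(self, config: InceptionConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.modules: list[InceptionModule] = []
        self.shortcuts: dict[int, tuple[_Conv1dSame, _BatchNorm, _ReLU]] = {}
        c = config.n_channels
        block_in_channels = c
        for i in range(config.depth):
            module = InceptionModule(c, config, rng)
            self.modules.append(module)
            c = module.out_channels
            if config.residual and ((i + 1) % 3 == 0 or i == config.depth - 1):
                self.shortcuts[i] = (
                    _Conv1dSame(block_in_channels, c, 1, rng, bias=True),
                    _BatchNorm(c),
                    _ReLU(),
                )
                block_in_channels = c
        self.dense = _Dense(c, config.n_classes, rng)
        self.out_channels = c
        self.loss_history: list[float] = []

    # -- plumbing ----------------------------------------------------------
    def _layers(self):
        layers = []
        for m in self.modules:
            layers.extend(m.layers)
        for conv, bn, _ in self.shortcuts.values():
            layers.extend([conv, bn])
        layers.append(self.dense)
        return layers

    def parameters(self):
        return [p for layer in self._layers() for p in layer.params]

    def gradients(self):
        return [g for layer in self._layers() for g in layer.grads]

    def count_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities for inputs of shape (N, C, L)."""
        h = x
        block_in = x
        for i, module in enumerate(self.modules):
            h = module.forward(h, train)
            if i in self.shortcuts:
                conv, bn, relu = self.shortcuts[i]
                s = bn.forward(conv.forward(block_in, train), train)
                h = relu.forward(h + s, train)
                block_in = h
        self._gap_len = h.shape[2]
        pooled = h.mean(axis=2)
        logits = self.dense.forward(pooled, train)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def backward(self, probs: np.ndarray, y_onehot: np.ndarray) -> None:
        n = probs.shape[0]
        dlogits = (probs - y_onehot) / n
        dpooled = self.dense.backward(dlogits)
        dy = np.repeat(dpooled[:, :, None], self._gap_len, axis=2) / self._gap_len
        # `pending` carries the shortcut gradient back to the tensor that
        # served as the (later) block's input, i.e. the previous shortcut
        # point's post-ReLU output (or the network input for the first block).
        pending = None
        for i in reversed(range(len(self.modules))):
            if i in self.shortcuts:
                conv, bn, relu = self.shortcuts[i]
                if pending is not None:
                    dy = dy + pending
                    pending = None
                dsum = relu.backward(dy)
                pending = conv.backward(bn.backward(dsum))
                dy = dsum
            dy = self.modules[i].backward(dy)
        if pending is not None:
            dy = dy + pending  # first block's shortcut taps the network input


# ---------------------------------------------------------------------------


def build_network(config: InceptionConfig) -> InceptionNetwork:
    return InceptionNetwork(config)


def _center(x: np.ndarray) -> np.ndarray:
    # per-window, per-channel mean removal strips the gravity offset while
    # preserving amplitude differences between windows (bradykinesia is an
    # amplitude effect, so per-window variance scaling would erase it)
    return x - x.mean(axis=2, keepdims=True)


class _Adam:
    def __init__(self, params, lr: float) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def train(model: InceptionNetwork, dataset: WindowedDataset,
          config: InceptionConfig | None = None) -> InceptionNetwork:
    """Minimize categorical cross-entropy with Adam on mini-batches."""
    config = config or model.config
    x = _center(dataset.acc.astype(float))
    y = dataset.labels
    if x.shape[1] != config.n_channels:
        raise ValueError("dataset channel count does not match config")
    n = len(y)
    onehot = np.eye(config.n_classes)[y]
    rng = np.random.default_rng(config.seed + 1)
    optimizer = _Adam(model.parameters(), config.learning_rate)
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            probs = model.forward(x[idx], train=True)
            loss = float(-np.log(np.clip(probs[np.arange(len(idx)), y[idx]],
                                         1e-12, None)).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at update {optimizer.t}: {loss}"
                )
            model.backward(probs, onehot[idx])
            optimizer.step(model.parameters(), model.gradients())
            epoch_loss += loss * len(idx)
        model.loss_history.append(epoch_loss / n)
    return model


def predict_proba(model: InceptionNetwork, dataset: WindowedDataset,
                  batch_size: int = 256) -> np.ndarray:
    x = _center(dataset.acc.astype(float))
    out = [model.forward(x[i:i + batch_size], train=False)
           for i in range(0, len(x), batch_size)]
    return np.concatenate(out) if out else np.empty((0, model.config.n_classes))


def ensemble_predict(models: list[InceptionNetwork],
                     dataset: WindowedDataset) -> PredictionSet:
    """Arithmetic mean of the member networks' probability vectors."""
    n_classes = {m.config.n_classes for m in models}
    if len(n_classes) != 1:
        raise ValueError("ensemble members disagree on class count")
    probs = np.mean([predict_proba(m, dataset) for m in models], axis=0)
    return PredictionSet(dataset.labels, probs, class_names=list(dataset.class_names))


class InceptionTimeClassifier:
    """Ensemble of five Inception networks differing only in initialization."""

    def __init__(self, config: InceptionConfig, n_members: int = 5) -> None:
        self.config = config
        self.n_members = n_members
        self.members: list[InceptionNetwork] = []

    def fit(self, dataset: WindowedDataset) -> "InceptionTimeClassifier":
        self.members = []
        for m in range(self.n_members):
            cfg = InceptionConfig(**{**self.config.__dict__,
                                     "seed": self.config.seed + 1000 * m})
            self.members.append(train(build_network(cfg), dataset, cfg))
        return self

    def predict_proba(self, dataset: WindowedDataset) -> np.ndarray:
        return ensemble_predict(self.members, dataset).scores

    def predict_set(self, dataset: WindowedDataset) -> PredictionSet:
        return ensemble_predict(self.members, dataset)
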