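"""A compact 1-D convolutional classifier for multi-channel SpO2 spectra.

Architecture: two blocks of (conv - conv - maxpool), a flatten, a stack of
fully connected ReLU layers with dropout, and a softmax over the ten SpO2
class labels.  Convolutions are stride-1 with length-preserving padding;
pooling is max with window 2.  Each 1-D convolution output is the sliding
inner product of a kernel h with the sequence u,

    Y(k) = sum_i h_{k-i} * u_i ,

learned end-to-end against categorical cross-entropy with the Adam update.

The softmax output is not used as a hard class decision alone: the scalar
SpO2 estimate is the expectation of the class labels under the predicted
distribution, SpO2 = sum_i L_i * W_i, which recovers sub-class resolution
from a 2 %-spaced label grid.

The network is implemented directly on numpy (im2col convolutions, explicit
backpropagation); sizes here are tiny — a dozen input samples, tens of
filters — so this is fast, dependency-free and bit-reproducible under seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field, replace

import numpy as np

from .preprocess import DEFAULT_LABELS, LabeledDataset

__all__ = [
    "CNNConfig",
    "ClassWeights",
    "TrainedModel",
    "TABLE_BOUNDS",
    "best_reported_config",
    "build_model",
    "train",
    "predict_weights",
    "decode_spo2",
]

#: Admissible hyperparameter ranges of the search study (continuous form).
TABLE_BOUNDS = {
    "filters_block1": (2, 64),
    "filters_block2": (2, 64),
    "n_dense_layers": (1, 10),
    "kernel_size": (2, 32),
    "dropout_ratio": (0.01, 1.0),
    "dense_nodes": (1, 100),
    "learning_rate": (1e-4, 0.1),
    "batch_size": (10, 300),
    "epochs": (10, 500),
}


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters of the classifier, bounded by the search-space ranges."""

    filters_block1: int = 10
    filters_block2: int = 16
    n_dense_layers: int = 3
    kernel_size: int = 6
    dropout_ratio: float = 0.37
    dense_nodes: int = 40
    learning_rate: float = 9e-4
    batch_size: int = 85
    epochs: int = 100
    seed: int = 0
    n_blocks: int = 2

    def __post_init__(self):
        for name, (lo, hi) in TABLE_BOUNDS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside admissible range [{lo}, {hi}]")
        if self.n_blocks not in (1, 2):
            raise ValueError("n_blocks must be 1 or 2")

    def with_(self, **kwargs) -> "CNNConfig":
        return replace(self, **kwargs)


def best_reported_config(**overrides) -> CNNConfig:
    """The best-found architecture of the optimization study.

    Filters 10/16, three dense layers of 40 nodes, kernel 6, dropout 0.37,
    batch 85; the learning rate is the study's best-found 9e-4.
    """
    return CNNConfig().with_(**overrides)


@dataclass
class ClassWeights:
    """Softmax class distribution over the ascending SpO2 label vector."""

    w: np.ndarray
    label_vector: tuple[int, ...] = DEFAULT_LABELS

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.label_vector),):
            raise ValueError("weight vector length must match label vector")
        if np.any(self.w < 0) or abs(self.w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must be a probability vector")


def decode_spo2(cw: ClassWeights) -> float:
    """Expectation decoding: SpO2 = sum_i L_i * W_i (always within label range)."""
    return float(np.dot(cw.w, np.asarray(cw.label_vector, dtype=float)))


# ---------------------------------------------------------------- layers ---


class _Conv1D:
    """Stride-1, length-preserving ('same') 1-D convolution."""

    def __init__(self, k, c_in, c_out, rng):
        limit = np.sqrt(6.0 / (k * c_in + k * c_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(k * c_in, c_out))
        self.b = np.zeros(c_out)
        self.k, self.c_in = k, c_in

    def _indices(self, L):
        pad_l = (self.k - 1) // 2
        idx = np.arange(L)[:, None] + np.arange(self.k)[None, :]  # into padded axis
        return pad_l, self.k - 1 - pad_l, idx

    def forward(self, x, train):
        N, L, _ = x.shape
        pad_l, pad_r, idx = self._indices(L)
        xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        cols = xp[:, idx, :].reshape(N, L, self.k * self.c_in)
        self._cols, self._L = cols, L
        return cols @ self.W + self.b

    def backward(self, dy):
        N, L, _ = dy.shape
        self.dW = np.einsum("nlc,nlf->cf", self._cols, dy) / N
        self.db = dy.mean(axis=(0, 1)) * L
        dcols = (dy @ self.W.T).reshape(N, L, self.k, self.c_in)
        pad_l, pad_r, idx = self._indices(L)
        dxp = np.zeros((N, L + pad_l + pad_r, self.c_in))
        np.add.at(dxp, (slice(None), idx), dcols)
        return dxp[:, pad_l : pad_l + L, :]

    params = property(lambda self: [("W", self.W), ("b", self.b)])


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    params = property(lambda self: [])


class _MaxPool2:
    """Max pooling, window 2, stride 2, trailing odd sample dropped."""

    def forward(self, x, train):
        N, L, C = x.shape
        self._L = L
        Lp = L // 2
        xx = x[:, : 2 * Lp, :].reshape(N, Lp, 2, C)
        self._arg = xx.argmax(axis=2)
        return xx.max(axis=2)

    def backward(self, dy):
        N, Lp, C = dy.shape
        dx = np.zeros((N, Lp, 2, C))
        n, l, c = np.ogrid[:N, :Lp, :C]
        dx[n, l, self._arg, c] = dy
        dx = dx.reshape(N, 2 * Lp, C)
        if self._L > 2 * Lp:
            dx = np.pad(dx, ((0, 0), (0, self._L - 2 * Lp), (0, 0)))
        return dx

    params = property(lambda self: [])


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    params = property(lambda self: [])


class _Dense:
    def __init__(self, n_in, n_out, rng):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy / dy.shape[0]
        self.db = dy.mean(axis=0)
        return dy @ self.W.T

    params = property(lambda self: [("W", self.W), ("b", self.b)])


class _Dropout:
    """Inverted dropout; identity at inference time."""

    def __init__(self, p, rng):
        self.p, self._rng = min(p, 0.99), rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    params = property(lambda self: [])


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------- model ---


class CNN1D:
    """The layer stack plus its Adam state.  Input shape (batch, steps, 1)."""

    def __init__(self, cfg: CNNConfig, input_length: int, n_classes: int):
        if cfg.n_blocks == 2 and input_length < 4:
            raise ValueError(
                f"input length {input_length} collapses to zero under two pooling "
                "layers; build with n_blocks=1 for 3-channel sub-regions"
            )
        k = cfg.kernel_size
        if k > input_length:
            warnings.warn(
                f"kernel size {k} exceeds input length {input_length}; clamped",
                stacklevel=3,
            )
            k = input_length
        self.cfg, self.input_length, self.n_classes = cfg, input_length, n_classes
        rng = np.random.default_rng(cfg.seed)
        drop_rng = np.random.default_rng(cfg.seed + 1)
        layers: list = []
        L, C = input_length, 1
        for b in range(cfg.n_blocks):
            f = cfg.filters_block1 if b == 0 else cfg.filters_block2
            layers += [_Conv1D(k, C, f, rng), _ReLU(), _Conv1D(k, f, f, rng), _ReLU(), _MaxPool2()]
            C, L = f, L // 2
        layers.append(_Flatten())
        n_in = L * C
        for _ in range(cfg.n_dense_layers):
            layers += [_Dense(n_in, cfg.dense_nodes, rng), _ReLU(), _Dropout(cfg.dropout_ratio, drop_rng)]
            n_in = cfg.dense_nodes
        layers.append(_Dense(n_in, n_classes, rng))
        self.layers = layers
        self._adam_m, self._adam_v, self._adam_t = None, None, 0

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.asarray(X, dtype=float).reshape(len(X), self.input_length, 1)
        for layer in self.layers:
            h = layer.forward(h, train)
        return _softmax(h)

    def train_step(self, X, Y_onehot):
        """One Adam step on a batch; returns (cross-entropy loss, accuracy)."""
        P = self.forward(X, train=True)
        eps = 1e-12
        loss = -np.mean(np.sum(Y_onehot * np.log(P + eps), axis=1))
        acc = np.mean(P.argmax(axis=1) == Y_onehot.argmax(axis=1))
        dy = P - Y_onehot  # combined softmax + cross-entropy gradient
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        self._adam_update()
        return loss, acc

    def _adam_update(self, beta1=0.9, beta2=0.999, eps=1e-8):
        grads, params = [], []
        for layer in self.layers:
            for name, p in layer.params:
                params.append(p)
                grads.append(getattr(layer, "d" + name))
        if self._adam_m is None:
            self._adam_m = [np.zeros_like(g) for g in grads]
            self._adam_v = [np.zeros_like(g) for g in grads]
        self._adam_t += 1
        t, lr = self._adam_t, self.cfg.learning_rate
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m[:] = beta1 * m + (1 - beta1) * g
            v[:] = beta2 * v + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- parameter (de)serialization -------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params:
                out[f"layer{i}_{name}"] = p
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, p in layer.params:
                p[:] = arrays[f"layer{i}_{name}"]


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reuse or audit it."""

    net: CNN1D
    label_vector: tuple[int, ...]
    config: CNNConfig
    history: dict = field(default_factory=dict)
    dataset_fingerprint: str = ""

    @property
    def input_length(self) -> int:
        return self.net.input_length

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.net.state_arrays())
        meta = {
            "label_vector": list(self.label_vector),
            "config": asdict(self.config),
            "input_length": self.net.input_length,
            "n_classes": self.net.n_classes,
            "history": {k: list(map(float, v)) for k, v in self.history.items()},
            "dataset_fingerprint": self.dataset_fingerprint,
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        cfg = CNNConfig(**meta["config"])
        net = CNN1D(cfg, meta["input_length"], meta["n_classes"])
        with np.load(d / "weights.npz") as arrays:
            net.load_state_arrays(dict(arrays))
        return cls(
            net=net,
            label_vector=tuple(meta["label_vector"]),
            config=cfg,
            history=meta["history"],
            dataset_fingerprint=meta["dataset_fingerprint"],
        )


def build_model(cfg: CNNConfig, input_length: int, n_classes: int = 10) -> CNN1D:
    """Assemble the (untrained) network for the given input width."""
    return CNN1D(cfg, input_length, n_classes)


def train(net: CNN1D, dataset: LabeledDataset, cfg: CNNConfig | None = None) -> TrainedModel:
    """Fit the network on a labeled dataset with mini-batch Adam.

    Deterministic under ``cfg.seed`` (pure-numpy arithmetic).  Raises on NaN
    loss, which usually means the learning rate is too high for this net.
    """
    cfg = cfg or net.cfg
    labels = np.asarray(dataset.label_vector, dtype=float)
    if net.input_length != dataset.X.shape[1]:
        raise ValueError("dataset region width does not match model input length")
    class_idx = np.searchsorted(labels, dataset.y)
    if not np.allclose(labels[class_idx], dataset.y):
        raise ValueError("dataset labels not one-hot encodable against label vector")
    Y = np.eye(net.n_classes)[class_idx]
    X = dataset.X
    rng = np.random.default_rng(cfg.seed + 2)
    history = {"loss": [], "accuracy": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(len(X))
        losses, accs, sizes = [], [], []
        for start in range(0, len(X), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            loss, acc = net.train_step(X[sel], Y[sel])
            losses.append(loss), accs.append(acc), sizes.append(len(sel))
        w = np.asarray(sizes, dtype=float)
        epoch_loss = float(np.average(losses, weights=w))
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                "training loss is not finite; the learning rate is likely too "
                "high for this configuration"
            )
        history["loss"].append(epoch_loss)
        history["accuracy"].append(float(np.average(accs, weights=w)))
    fingerprint = f"{dataset.region.name}/noise={dataset.noise_ratio}/n={len(X)}/seed={dataset.seed}"
    return TrainedModel(
        net=net,
        label_vector=dataset.label_vector,
        config=cfg,
        history=history,
        dataset_fingerprint=fingerprint,
    )


def predict_weights(model: TrainedModel, x: np.ndarray) -> ClassWeights:
    """Softmax class distribution for one normalized spectrum row."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.input_length,):
        raise ValueError(f"expected row of length {model.input_length}, got {x.shape}")
    p = model.net.forward(x[None, :])[0]
    return ClassWeights(w=p, label_vector=model.label_vector)


def predict_batch(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Softmax matrix (rows x classes) for a matrix of spectrum rows."""
    return model.net.forward(np.asarray(X, dtype=float))


def decode_batch(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Expectation-decoded scalar SpO2 for each row."""
    P = predict_batch(model, X)
    return P @ np.asarray(model.label_vector, dtype=float)
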