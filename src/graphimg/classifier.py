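"""LeNet-style CNN for graph-image classification.

Architecture (valid, i.e. unpadded, convolutions):

    input (r x r x C)
    -> conv 3x3, 32 maps, ReLU   (dropout 0.25 in training)
    -> conv 3x3, 128 maps, ReLU  (dropout 0.25 in training)
    -> max pool 2x2
    -> flatten
    -> FC 32, ReLU               (dropout 0.25 in training)
    -> FC 16, ReLU
    -> FC n_classes, softmax

For a 10x10 input the spatial chain is 10 -> 8 -> 6 -> 3, so the
flattened vector entering the first fully-connected layer has
3*3*128 = 1,152 units.  Training minimises categorical cross-entropy
with Adam plus an L2 penalty on all weight matrices, and early-stops on
validation loss, restoring the best weights seen.

The network is implemented directly on numpy (forward and backward
passes, Adam state) — at this scale (tens of 10x10x2 images) that is
fast, exactly reproducible under a seed, and dependency-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import derive_rng

__all__ = [
    "CNNConfig",
    "CNNModel",
    "LabeledImageSet",
    "TrainHistory",
    "CVResult",
    "ParameterCount",
    "build_model",
    "count_parameters",
    "train",
    "predict",
    "cross_validate",
    "save_model",
    "load_model",
]

CLASS_ORDER = ("control", "case")  # label 0 = control, label 1 = case


@dataclass
class CNNConfig:
    input_shape: tuple[int, int, int] = (10, 10, 2)
    conv1_maps: int = 32
    conv2_maps: int = 128
    kernel: int = 3
    pool: int = 2
    fc1_units: int = 32
    fc2_units: int = 16
    n_classes: int = 2
    dropout_rate: float = 0.25
    learning_rate: float = 0.001
    weight_decay: float = 5e-4
    max_epochs: int = 1000
    early_stop_patience: int = 50
    early_stop_min_delta: float = 0.0
    batch_size: int = 8
    normalize_counts: bool = False  # optionally divide each channel by its pixel sum
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.conv1_maps, self.conv2_maps, self.kernel, self.pool,
                  self.fc1_units, self.fc2_units, self.n_classes,
                  self.max_epochs, self.early_stop_patience, self.batch_size)
        if any(c < 1 for c in counts):
            raise ValueError("all architecture/training counts must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("invalid optimiser settings")
        h, w, c = self.input_shape
        if c < 1:
            raise ValueError("input needs at least one channel")
        h2, w2 = h - 2 * (self.kernel - 1), w - 2 * (self.kernel - 1)
        if h2 < self.pool or w2 < self.pool:
            raise ValueError(
                f"input {h}x{w} too small for two valid {self.kernel}x{self.kernel} "
                f"convolutions followed by {self.pool}x{self.pool} pooling"
            )

    @property
    def conv_out_shape(self) -> tuple[int, int]:
        h, w, _ = self.input_shape
        return h - 2 * (self.kernel - 1), w - 2 * (self.kernel - 1)

    @property
    def flatten_units(self) -> int:
        h2, w2 = self.conv_out_shape
        return (h2 // self.pool) * (w2 // self.pool) * self.conv2_maps


@dataclass
class LabeledImageSet:
    """N images (N x r x r x C) with binary labels (0=control, 1=case)."""

    images: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim != 4:
            raise ValueError("images must be N x r x r x channels")
        n = self.images.shape[0]
        if self.labels.shape != (n,) or len(self.subject_ids) != n:
            raise ValueError("labels and subject_ids must match the number of images")
        if n < 2:
            raise ValueError("need at least 2 images")
        if np.any(self.images < 0):
            raise ValueError("images must be non-negative counts")

    def __len__(self) -> int:
        return self.images.shape[0]

    def subset(self, idx: np.ndarray) -> "LabeledImageSet":
        return LabeledImageSet(self.images[idx], self.labels[idx],
                               [self.subject_ids[i] for i in idx])


@dataclass
class TrainHistory:
    train_loss: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    stopped_epoch: int
    best_epoch: int


@dataclass
class CVResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    histories: list[TrainHistory] = field(default_factory=list)


@dataclass
class ParameterCount:
    weights_only: int
    bias_terms: int

    @property
    def with_biases(self) -> int:
        return self.weights_only + self.bias_terms


class CNNModel:
    """Parameter container + forward/backward passes."""

    WEIGHT_KEYS = ("W1", "W2", "W5", "W6", "W7")
    BIAS_KEYS = ("b1", "b2", "b5", "b6", "b7")

    def __init__(self, cfg: CNNConfig):
        self.cfg = cfg
        k, cin = cfg.kernel, cfg.input_shape[2]
        rng = derive_rng(cfg.seed, "cnn-init")
        def glorot(shape, fan_in, fan_out):
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)
        self.params: dict[str, np.ndarray] = {
            "W1": glorot((k, k, cin, cfg.conv1_maps), k * k * cin, k * k * cfg.conv1_maps),
            "b1": np.zeros(cfg.conv1_maps),
            "W2": glorot((k, k, cfg.conv1_maps, cfg.conv2_maps),
                         k * k * cfg.conv1_maps, k * k * cfg.conv2_maps),
            "b2": np.zeros(cfg.conv2_maps),
            "W5": glorot((cfg.flatten_units, cfg.fc1_units), cfg.flatten_units, cfg.fc1_units),
            "b5": np.zeros(cfg.fc1_units),
            "W6": glorot((cfg.fc1_units, cfg.fc2_units), cfg.fc1_units, cfg.fc2_units),
            "b6": np.zeros(cfg.fc2_units),
            "W7": glorot((cfg.fc2_units, cfg.n_classes), cfg.fc2_units, cfg.n_classes),
            "b7": np.zeros(cfg.n_classes),
        }

    @property
    def flatten_units(self) -> int:
        return self.cfg.flatten_units

    @property
    def conv2_kernel_slices(self) -> int:
        """Number of distinct kxk kernel slices in the second convolution."""
        return self.cfg.conv1_maps * self.cfg.conv2_maps

    # ---- forward -----------------------------------------------------

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.cfg.input_shape:
            raise ValueError(
                f"image shape {x.shape[1:]} does not match model input {self.cfg.input_shape}"
            )
        if self.cfg.normalize_counts:
            sums = x.sum(axis=(1, 2), keepdims=True)
            x = x / np.where(sums > 0, sums, 1.0)
        return x

    def forward(self, images: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Class probabilities (N x n_classes); with a cache when training."""
        cfg, p = self.cfg, self.params
        x = self._prepare(images)
        drop = cfg.dropout_rate if train else 0.0
        if drop > 0 and rng is None:
            raise ValueError("training forward pass needs an rng for dropout")
        cache: dict[str, np.ndarray] = {"x": x}

        def dropout(a, key):
            if drop == 0:
                return a
            mask = (rng.random(a.shape) >= drop) / (1.0 - drop)
            cache[key] = mask
            return a * mask

        p1, z1 = _conv_forward(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        d1 = dropout(a1, "m1")
        p2, z2 = _conv_forward(d1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        d2 = dropout(a2, "m2")
        pooled, pool_idx = _maxpool_forward(d2, cfg.pool)
        flat = pooled.reshape(pooled.shape[0], -1)
        z5 = flat @ p["W5"] + p["b5"]
        a5 = np.maximum(z5, 0.0)
        d5 = dropout(a5, "m5")
        z6 = d5 @ p["W6"] + p["b6"]
        a6 = np.maximum(z6, 0.0)
        z7 = a6 @ p["W7"] + p["b7"]
        probs = _softmax(z7)
        if not train:
            return probs
        cache.update(patches1=p1, z1=z1, d1=d1, patches2=p2, z2=z2,
                     pool_idx=pool_idx, pooled_shape=np.array(pooled.shape),
                     flat=flat, z5=z5, d5=d5, z6=z6, a6=a6, probs=probs)
        return probs, cache

    # ---- backward ----------------------------------------------------

    def backward(self, cache: dict, labels: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean cross-entropy (+ L2 on weights) w.r.t. parameters."""
        cfg, p = self.cfg, self.params
        n = labels.size
        probs = cache["probs"]
        dz7 = probs.copy()
        dz7[np.arange(n), labels] -= 1.0
        dz7 /= n
        g = {}
        g["W7"] = cache["a6"].T @ dz7
        g["b7"] = dz7.sum(axis=0)
        da6 = dz7 @ p["W7"].T
        dz6 = da6 * (cache["z6"] > 0)
        g["W6"] = cache["d5"].T @ dz6
        g["b6"] = dz6.sum(axis=0)
        dd5 = dz6 @ p["W6"].T
        if "m5" in cache:
            dd5 = dd5 * cache["m5"]
        dz5 = dd5 * (cache["z5"] > 0)
        g["W5"] = cache["flat"].T @ dz5
        g["b5"] = dz5.sum(axis=0)
        dflat = dz5 @ p["W5"].T
        dpooled = dflat.reshape(tuple(cache["pooled_shape"]))
        dd2 = _maxpool_backward(dpooled, cache["pool_idx"], cache["z2"].shape, cfg.pool)
        if "m2" in cache:
            dd2 = dd2 * cache["m2"]
        dz2 = dd2 * (cache["z2"] > 0)
        g["W2"], g["b2"], dd1 = _conv_backward(dz2, cache["patches2"], p["W2"], cache["d1"].shape)
        if "m1" in cache:
            dd1 = dd1 * cache["m1"]
        dz1 = dd1 * (cache["z1"] > 0)
        g["W1"], g["b1"], _ = _conv_backward(dz1, cache["patches1"], p["W1"], cache["x"].shape)
        if cfg.weight_decay:
            for key in self.WEIGHT_KEYS:
                g[key] = g[key] + 2.0 * cfg.weight_decay * p[key]
        return g

    def loss(self, probs: np.ndarray, labels: np.ndarray) -> float:
        """Mean categorical cross-entropy plus the L2 weight penalty."""
        n = labels.size
        ce = -float(np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
        l2 = self.cfg.weight_decay * sum(
            float(np.sum(self.params[k] ** 2)) for k in self.WEIGHT_KEYS
        )
        return ce + l2

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid convolution; returns (patches, pre-activation)."""
    k = w.shape[0]
    patches = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # patches: (N, Ho, Wo, Cin, k, k)
    z = np.einsum("nhwcij,ijcf->nhwf", patches, w, optimize=True) + b
    return patches, z


def _conv_backward(dz: np.ndarray, patches: np.ndarray, w: np.ndarray, x_shape):
    k = w.shape[0]
    dw = np.einsum("nhwcij,nhwf->ijcf", patches, dz, optimize=True)
    db = dz.sum(axis=(0, 1, 2))
    dx = np.zeros(x_shape)
    ho, wo = dz.shape[1], dz.shape[2]
    for i in range(k):
        for j in range(k):
            dx[:, i : i + ho, j : j + wo, :] += dz @ w[i, j].T
    return dw, db, dx


def _maxpool_forward(x: np.ndarray, pool: int):
    n, h, w, c = x.shape
    hp, wp = h // pool, w // pool
    xr = (x[:, : hp * pool, : wp * pool, :]
          .reshape(n, hp, pool, wp, pool, c)
          .transpose(0, 1, 3, 5, 2, 4)
          .reshape(n, hp, wp, c, pool * pool))
    idx = np.argmax(xr, axis=-1)  # deterministic first-max tie-break
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(dout: np.ndarray, idx: np.ndarray, x_shape, pool: int):
    n, h, w, c = x_shape
    hp, wp = h // pool, w // pool
    grid = np.zeros((n, hp, wp, c, pool * pool))
    np.put_along_axis(grid, idx[..., None], dout[..., None], axis=-1)
    dx = np.zeros(x_shape)
    dx[:, : hp * pool, : wp * pool, :] = (
        grid.reshape(n, hp, wp, c, pool, pool)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, hp * pool, wp * pool, c)
    )
    return dx


def build_model(cfg: CNNConfig) -> CNNModel:
    """Instantiate the network; raises if the input is too small for the stack."""
    return CNNModel(cfg)


def count_parameters(model: CNNModel) -> ParameterCount:
    """Trainable scalar counts, with and without bias terms.

    For the default 10x10x2 configuration the weights-only count is
    74,848 and the count including biases is 75,058.
    """
    weights = sum(model.params[k].size for k in model.WEIGHT_KEYS)
    biases = sum(model.params[k].size for k in model.BIAS_KEYS)
    return ParameterCount(weights, biases)


def save_model(path, model: CNNModel) -> None:
    """Checkpoint: parameters plus the config needed to rebuild the model."""
    import json

    from dataclasses import asdict

    cfg = asdict(model.cfg)
    cfg["input_shape"] = list(cfg["input_shape"])
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **model.params)


def load_model(path) -> CNNModel:
    import json

    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
        model = CNNModel(CNNConfig(**cfg_dict))
        model.params = {k: data[k] for k in data.files if k != "__config__"}
    return model


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(model: CNNModel, train_set: LabeledImageSet, val_set: LabeledImageSet,
          cfg: CNNConfig | None = None) -> tuple[CNNModel, TrainHistory]:
    """Adam training with dropout, L2 penalty and early stopping.

    Stops when validation loss has not improved for
    ``early_stop_patience`` epochs (or at ``max_epochs``) and restores
    the best weights seen.
    """
    cfg = cfg or model.cfg
    if len(np.unique(train_set.labels)) < 2:
        raise ValueError("training set must contain both classes")
    rng = derive_rng(cfg.seed, "cnn-train")
    opt = _Adam(model.params, cfg.learning_rate)
    n = len(train_set)
    history = TrainHistory([], [], [], stopped_epoch=0, best_epoch=0)
    best_loss = np.inf
    best_params = model.copy_params()
    since_best = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        batch_losses = []
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            probs, cache = model.forward(train_set.images[sel], train=True, rng=rng)
            batch_losses.append(model.loss(probs, train_set.labels[sel]))
            grads = model.backward(cache, train_set.labels[sel])
            opt.step(model.params, grads)
        val_probs = model.forward(val_set.images)
        val_loss = model.loss(val_probs, val_set.labels)
        val_acc = float(np.mean(val_probs.argmax(axis=1) == val_set.labels))
        history.train_loss.append(float(np.mean(batch_losses)))
        history.val_loss.append(float(val_loss))
        history.val_accuracy.append(val_acc)
        if val_loss < best_loss - cfg.early_stop_min_delta:
            best_loss = val_loss
            best_params = model.copy_params()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        history.stopped_epoch = epoch
        if since_best >= cfg.early_stop_patience:
            break
    model.params = best_params
    return model, history


def predict(model: CNNModel, images: np.ndarray) -> np.ndarray:
    """Per-image class probabilities (deterministic: no dropout)."""
    return model.forward(images)


def partition_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into k near-equal disjoint folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects ({n})")
    return np.array_split(rng.permutation(n), k)


def cross_validate(data: LabeledImageSet, k: int, iterations: int,
                   cfg: CNNConfig, seed: int = 0) -> CVResult:
    """Repeated k-fold cross-validation with a fresh model per fold.

    Each iteration draws a fresh random partition into k near-equal
    folds; every fold serves once as the held-out test group (also used
    for early stopping) while the remaining folds train the model.
    """
    n = len(data)
    rng = derive_rng(seed, "cv-partition")
    fold_accs: list[float] = []
    histories: list[TrainHistory] = []
    for _ in range(iterations):
        folds = partition_folds(n, k, rng)
        for fold in folds:
            test = data.subset(fold)
            train_idx = np.setdiff1d(np.arange(n), fold)
            train_data = data.subset(train_idx)
            fold_cfg = replace(cfg, seed=int(rng.integers(2**31)))
            model = build_model(fold_cfg)
            model, hist = train(model, train_data, test, fold_cfg)
            probs = predict(model, test.images)
            fold_accs.append(float(np.mean(probs.argmax(axis=1) == test.labels)))
            histories.append(hist)
    return CVResult(fold_accs, float(np.mean(fold_accs)), histories)
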