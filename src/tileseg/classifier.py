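"""Compact CNN patch classifier: architecture, training loop, prediction.

The classifier maps a 128 x 128 RGB tile to a tumor confidence in [0, 1]
(0 = healthy, 1 = tumor). The network is deliberately small — four
convolutional blocks with 8/16/16/32 filters and 3x3 / 3x3 / 5x5 / 3x3
kernels — because the two tissue classes differ in local texture statistics
(nuclear density, size, chromatin color) that saturate quickly with depth.
Each block is conv -> batch norm -> SELU -> 2x2 max pool; a global average
pooling feeds a 2-unit softmax head. Training uses plain SGD with momentum
0.75, an L2 weight penalty, and a mean-squared-error loss on the softmax
tumor probability against the 0/1 label, with early stopping on a held-out
fraction of the training patches and restoration of the best-epoch weights.

The implementation is pure numpy (im2col convolutions): it is deterministic
given a seed and a device, needs no accelerator, and is fast enough for
desk-scale slides. Intensities are scaled to [0, 1] on entry; no stain
normalization is applied.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DataError, FormatError, ParameterError
from .patching import PatchDataset

SELU_ALPHA = 1.6732632423543772
SELU_LAMBDA = 1.0507009873554805
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class ClassifierConfig:
    """Hyperparameters of the compact CNN.

    Defaults follow the reference training recipe: SGD(momentum=0.75,
    lr=1e-4), L2 penalty, MSE-on-softmax loss, batches of 64, early stopping
    with the best validation-loss weights restored. ``tile_size`` must be
    divisible by 16 (four 2x2 pooling stages).
    """

    conv_filters: tuple[int, ...] = (8, 16, 16, 32)
    conv_kernels: tuple[int, ...] = (3, 3, 5, 3)
    tile_size: int = 128
    learning_rate: float = 1e-4
    momentum: float = 0.75
    l2: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 2

    def __post_init__(self) -> None:
        self.conv_filters = tuple(int(f) for f in self.conv_filters)
        self.conv_kernels = tuple(int(k) for k in self.conv_kernels)
        if len(self.conv_filters) != 4 or len(self.conv_kernels) != 4:
            raise ParameterError("conv_filters and conv_kernels must have length 4")
        if any(f < 1 for f in self.conv_filters):
            raise ParameterError("conv filter counts must be positive")
        if any(k < 1 or k % 2 == 0 for k in self.conv_kernels):
            raise ParameterError("conv kernels must be positive odd integers")
        if self.tile_size % 16 != 0 or self.tile_size < 16:
            raise ParameterError("tile_size must be a positive multiple of 16")
        for name in ("learning_rate", "momentum", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.l2 < 0:
            raise ParameterError("l2 must be nonnegative")


@dataclass
class TrainingHistory:
    """Per-epoch losses; ``best_epoch`` is the argmin of the validation loss."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.val_loss))

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)


# ---------------------------------------------------------------------------
# numerical primitives
# ---------------------------------------------------------------------------

def _selu(x):
    return SELU_LAMBDA * np.where(x > 0, x, SELU_ALPHA * np.expm1(x))


def _selu_grad(x):
    return SELU_LAMBDA * np.where(x > 0, 1.0, SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, k*k*C) column matrix for a same-padded conv."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = sliding_window_view(xp, (k, k), axis=(1, 2))   # N, H, W, C, k, k
    cols = cols.transpose(0, 1, 2, 4, 5, 3)               # N, H, W, k, k, C
    n, h, w = x.shape[:3]
    return np.ascontiguousarray(cols).reshape(n * h * w, k * k * x.shape[3])


def _conv_forward(x, weight, bias):
    """Stride-1 same-padded convolution; weight is (k, k, Cin, F)."""
    k = weight.shape[0]
    n, h, w, _ = x.shape
    cols = _im2col(x, k)
    out = cols @ weight.reshape(-1, weight.shape[3]) + bias
    return out.reshape(n, h, w, weight.shape[3]), cols


def _conv_backward_input(dout, weight):
    # gradient wrt the conv input = same-padded conv of dout with the
    # spatially flipped kernel, input/output channels swapped
    wflip = weight[::-1, ::-1].transpose(0, 1, 3, 2)
    dx, _ = _conv_forward(dout, np.ascontiguousarray(wflip),
                          np.zeros(wflip.shape[3], dtype=weight.dtype))
    return dx


def _maxpool(x):
    n, h, w, c = x.shape
    r = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = r.max(axis=(2, 4))
    mask = r == out[:, :, None, :, None, :]
    # split the gradient among ties so it is conserved
    ties = mask.sum(axis=(2, 4), keepdims=True)
    return out, (mask / ties)


def _maxpool_backward(dout, pool_cache, shape):
    n, h, w, c = shape
    d = pool_cache * dout[:, :, None, :, None, :]
    return d.reshape(n, h, w, c)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class CompactCNN:
    """Four-block convolutional tumor/normal tile classifier.

    Built untrained by :func:`build_classifier`; trained in place by
    :func:`train_classifier`. ``predict`` returns tumor confidences in
    [0, 1] and is deterministic for fixed weights (batch-norm statistics are
    frozen at inference).
    """

    def __init__(self, config: ClassifierConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        self.is_trained = False
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        cin = 3
        for i, (f, k) in enumerate(zip(config.conv_filters, config.conv_kernels)):
            fan_in = k * k * cin
            # LeCun normal initialization, the standard pairing with SELU
            self.params[f"w{i}"] = rng.normal(
                0.0, np.sqrt(1.0 / fan_in), size=(k, k, cin, f)
            ).astype(np.float32)
            self.params[f"b{i}"] = np.zeros(f, dtype=np.float32)
            self.params[f"gamma{i}"] = np.ones(f, dtype=np.float32)
            self.params[f"beta{i}"] = np.zeros(f, dtype=np.float32)
            cin = f
        self.params["w_head"] = rng.normal(
            0.0, np.sqrt(1.0 / cin), size=(cin, 2)
        ).astype(np.float32)
        self.params["b_head"] = np.zeros(2, dtype=np.float32)
        self.running_mean = [np.zeros(f, dtype=np.float32) for f in config.conv_filters]
        self.running_var = [np.ones(f, dtype=np.float32) for f in config.conv_filters]

    # -- forward -----------------------------------------------------------

    def _prepare(self, tiles: np.ndarray) -> np.ndarray:
        tiles = np.asarray(tiles)
        squeeze = tiles.ndim == 3
        if squeeze:
            tiles = tiles[None]
        s = self.config.tile_size
        if tiles.ndim != 4 or tiles.shape[1:] != (s, s, 3):
            raise FormatError(
                f"expected tiles of shape (N, {s}, {s}, 3), got {tiles.shape}"
            )
        if tiles.dtype == np.uint8:
            x = tiles.astype(np.float32) / 255.0
        else:
            x = tiles.astype(np.float32)
        return x

    def _forward(self, x: np.ndarray, training: bool):
        """Returns softmax probabilities (N, 2) and, in training mode, caches."""
        caches = []
        for i in range(4):
            w, b = self.params[f"w{i}"], self.params[f"b{i}"]
            gamma, beta = self.params[f"gamma{i}"], self.params[f"beta{i}"]
            z, cols = _conv_forward(x, w, b)
            if training:
                axes = (0, 1, 2)
                mu = z.mean(axis=axes)
                var = z.var(axis=axes)
                self.running_mean[i] = (_BN_MOMENTUM * self.running_mean[i]
                                        + (1 - _BN_MOMENTUM) * mu).astype(np.float32)
                self.running_var[i] = (_BN_MOMENTUM * self.running_var[i]
                                       + (1 - _BN_MOMENTUM) * var).astype(np.float32)
            else:
                mu, var = self.running_mean[i], self.running_var[i]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (z - mu) * inv_std
            bn_out = gamma * xhat + beta
            act = _selu(bn_out)
            pooled, pool_cache = _maxpool(act)
            if training:
                caches.append({
                    "x_shape": x.shape, "cols": cols, "xhat": xhat,
                    "inv_std": inv_std, "bn_out": bn_out,
                    "pool_cache": pool_cache, "act_shape": act.shape,
                })
            x = pooled
        feats = x.mean(axis=(1, 2))                       # global average pooling
        logits = feats @ self.params["w_head"] + self.params["b_head"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        if training:
            return probs, {"feats": feats, "pre_gap_shape": x.shape, "convs": caches}
        return probs, None

    # -- backward ----------------------------------------------------------

    def _backward(self, probs, labels, cache):
        """Gradient of mean((p_tumor - y)^2) wrt every parameter."""
        n = probs.shape[0]
        grads = {}
        p1 = probs[:, 1]
        dp1 = 2.0 * (p1 - labels) / n
        # softmax jacobian row for the tumor output
        dz = dp1[:, None] * p1[:, None] * (np.array([0.0, 1.0]) - probs)
        dz = dz.astype(np.float32)
        grads["w_head"] = cache["feats"].T @ dz
        grads["b_head"] = dz.sum(axis=0)
        dfeats = dz @ self.params["w_head"].T
        nb, hb, wb, cb = cache["pre_gap_shape"]
        dx = np.broadcast_to(
            dfeats[:, None, None, :] / (hb * wb), cache["pre_gap_shape"]
        ).astype(np.float32)
        for i in range(3, -1, -1):
            c = cache["convs"][i]
            dact = _maxpool_backward(dx, c["pool_cache"], c["act_shape"])
            dbn = dact * _selu_grad(c["bn_out"])
            gamma = self.params[f"gamma{i}"]
            xhat, inv_std = c["xhat"], c["inv_std"]
            m = dbn.shape[0] * dbn.shape[1] * dbn.shape[2]
            grads[f"gamma{i}"] = (dbn * xhat).sum(axis=(0, 1, 2))
            grads[f"beta{i}"] = dbn.sum(axis=(0, 1, 2))
            dzc = (gamma * inv_std / m) * (
                m * dbn
                - grads[f"beta{i}"]
                - xhat * grads[f"gamma{i}"]
            )
            dzc = dzc.astype(np.float32)
            w = self.params[f"w{i}"]
            dflat = dzc.reshape(-1, w.shape[3])
            grads[f"w{i}"] = (c["cols"].T @ dflat).reshape(w.shape)
            grads[f"b{i}"] = dflat.sum(axis=0)
            if i > 0:
                dx = _conv_backward_input(dzc, w)
        return grads

    # -- public API --------------------------------------------------------

    def predict(self, tiles) -> np.ndarray:
        """Tumor confidence for a tile (S, S, 3) or batch (N, S, S, 3)."""
        tiles = np.asarray(tiles)
        single = tiles.ndim == 3
        if tiles.shape[0] == 0:
            return np.zeros(0, dtype=np.float32)
        x = self._prepare(tiles)
        out = []
        bs = self.config.batch_size
        for start in range(0, x.shape[0], bs):
            probs, _ = self._forward(x[start:start + bs], training=False)
            out.append(probs[:, 1])
        conf = np.concatenate(out)
        return float(conf[0]) if single else conf

    def loss_on(self, tiles, labels) -> float:
        conf = self.predict(tiles)
        return float(np.mean((np.atleast_1d(conf) - np.asarray(labels)) ** 2))

    def snapshot(self):
        return (copy.deepcopy(self.params),
                [m.copy() for m in self.running_mean],
                [v.copy() for v in self.running_var])

    def restore(self, snap) -> None:
        self.params, self.running_mean, self.running_var = (
            copy.deepcopy(snap[0]), [m.copy() for m in snap[1]],
            [v.copy() for v in snap[2]])

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def build_classifier(config: ClassifierConfig | None = None, seed: int = 0) -> CompactCNN:
    """Construct an untrained classifier with seed-deterministic initialization."""
    return CompactCNN(config or ClassifierConfig(), seed=seed)


def train_classifier(model: CompactCNN, train_set: PatchDataset,
                     config: ClassifierConfig | None = None,
                     holdout_fraction: float = 0.10,
                     seed: int = 0) -> tuple[CompactCNN, TrainingHistory]:
    """Train with SGD + momentum and early stopping; restore best weights.

    ``holdout_fraction`` of the training patches is set aside (stratified) to
    monitor the validation loss; training stops once that loss has not
    improved for ``config.patience`` consecutive epochs, and the weights from
    the best epoch are restored.
    """
    cfg = config or model.config
    labels = train_set.labels
    if len(train_set) == 0 or len(np.unique(labels)) < 2:
        raise DataError("training requires patches from both classes")
    if not 0 < holdout_fraction < 1:
        raise ParameterError("holdout_fraction must be in (0, 1)")

    rng = np.random.default_rng(seed)
    tiles = train_set.tiles
    # stratified holdout so both classes appear in the monitoring set
    val_idx = []
    for code in (0, 1):
        idx = np.flatnonzero(labels == code)
        n_hold = max(1, int(round(holdout_fraction * len(idx))))
        val_idx.append(rng.choice(idx, size=n_hold, replace=False))
    val_idx = np.sort(np.concatenate(val_idx))
    train_idx = np.setdiff1d(np.arange(len(labels)), val_idx)
    if len(train_idx) == 0:
        raise DataError("holdout left no training patches")

    x_train = model._prepare(tiles[train_idx])
    y_train = labels[train_idx].astype(np.float32)
    x_val = tiles[val_idx]
    y_val = labels[val_idx].astype(np.float32)

    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    history = TrainingHistory()
    best = None
    best_loss = np.inf
    since_best = 0

    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_idx))
        batch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            probs, cache = model._forward(xb, training=True)
            batch_losses.append(float(np.mean((probs[:, 1] - yb) ** 2)))
            grads = model._backward(probs, yb, cache)
            for name, g in grads.items():
                if cfg.l2 > 0 and name.startswith("w"):
                    g = g + cfg.l2 * model.params[name]
                velocity[name] = cfg.momentum * velocity[name] - cfg.learning_rate * g
                model.params[name] += velocity[name]
        history.train_loss.append(float(np.mean(batch_losses)))
        val_loss = model.loss_on(x_val, y_val)
        history.val_loss.append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best = model.snapshot()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    if best is not None:
        model.restore(best)
    model.is_trained = True
    return model, history


def predict_patches(model: CompactCNN, patches) -> np.ndarray:
    """Batched, order-preserving tumor confidences for patches or raw tiles."""
    if isinstance(patches, PatchDataset):
        tiles = patches.tiles
    else:
        tiles = np.asarray(patches)
    if tiles.shape[0] == 0:
        return np.zeros(0, dtype=np.float32)
    return np.atleast_1d(model.predict(tiles))


# ---------------------------------------------------------------------------
# persistence: npz weights + JSON sidecar
# ---------------------------------------------------------------------------

def save_model(model: CompactCNN, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = dict(model.params)
    for i in range(4):
        arrays[f"running_mean{i}"] = model.running_mean[i]
        arrays[f"running_var{i}"] = model.running_var[i]
    np.savez(directory / "weights.npz", **arrays)
    sidecar = {"config": asdict(model.config), "seed": model.seed,
               "is_trained": model.is_trained}
    with open(directory / "model.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(directory) -> CompactCNN:
    directory = Path(directory)
    with open(directory / "model.json") as fh:
        sidecar = json.load(fh)
    cfg_dict = dict(sidecar["config"])
    cfg = ClassifierConfig(**cfg_dict)
    model = CompactCNN(cfg, seed=sidecar["seed"])
    with np.load(directory / "weights.npz") as data:
        for key in model.params:
            model.params[key] = data[key]
        model.running_mean = [data[f"running_mean{i}"] for i in range(4)]
        model.running_var = [data[f"running_var{i}"] for i in range(4)]
    model.is_trained = bool(sidecar["is_trained"])
    return model
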