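"""A compact NumPy CNN for 16x16 t-score patch classification.

The network is the 17-layer architecture used throughout this package: an
input layer, three convolution -> batch-normalization -> ReLU -> max-pooling
blocks, a fully connected layer to 2 classes, dropout, softmax, and a
classification (cross-entropy) output layer.  Spatial size shrinks
16 -> 8 -> 4 -> 2 across the three 2x2 pooling stages, so the head sees
2 * 2 * conv_filters[-1] features.

Training uses stochastic gradient descent with momentum on the
cross-entropy loss summed over the mini-batch, with an L2 weight penalty and
a per-epoch geometric learning-rate decay from ``lr_initial`` to
``lr_final``.  Summing (rather than averaging) the per-sample losses makes
the small printed learning rates effective at the default batch size of 500;
see docs/methods.md.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .patches import PatchDataset
from .preprocess import ContractError


# ---------------------------------------------------------------------------
# layers


def _conv2d(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padding stride-1 2-D convolution (cross-correlation).

    x: (N, C, H, W); w: (O, C, k, k) with odd k.  Returns (out, cols) where
    cols are the im2col patches kept for the backward pass.
    """
    n, c, h, wd = x.shape
    o, _, k, _ = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * wd, c * k * k)
    out = cols @ w.reshape(o, -1).T            # (N, H*W, O)
    return out.transpose(0, 2, 1).reshape(n, o, h, wd), cols


class Conv:
    """3x3 convolution, stride 1, symmetric (same) padding, He init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (in_ch * kernel * kernel))
        self.w = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = ("w", "b")
        self.decayed = ("w",)  # L2 penalty applies to weights, not biases

    def forward(self, x, train):
        out, self._cols = _conv2d(x, self.w)
        self._xshape = x.shape
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        n, o, h, wd = dout.shape
        d2 = np.ascontiguousarray(dout.reshape(n, o, h * wd).transpose(1, 0, 2))
        self.dw = (d2.reshape(o, -1)
                   @ self._cols.reshape(-1, self._cols.shape[2])).reshape(self.w.shape)
        self.db = dout.sum(axis=(0, 2, 3))
        # dx = full correlation of dout with the flipped, channel-swapped kernel
        w_t = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx, _ = _conv2d(dout, w_t)
        return dx


class BatchNorm:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.params = ("gamma", "beta")
        self.decayed = ()

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        axes = (0, 2, 3)
        self.dgamma = (dout * self._xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        g = self.gamma[None, :, None, None]
        if not self._train:
            return dout * g / self._std[None, :, None, None]
        m = self._m
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True))
        return dx / self._std[None, :, None, None]


class ReLU:
    params: tuple = ()
    decayed: tuple = ()

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool:
    """2x2 max pooling, stride 2 (input sizes must be even)."""

    params: tuple = ()
    decayed: tuple = ()

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        argmask = xr == out[:, :, :, None, :, None]
        # break ties: keep only the first max in each 2x2 window
        flat = argmask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._argmask = ((flat & first)
                         .reshape(n, c, h // 2, w // 2, 2, 2)
                         .transpose(0, 1, 2, 4, 3, 5))
        self._xshape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._xshape
        dx = self._argmask * dout[:, :, :, None, :, None]
        return dx.reshape(n, c, h, w)


class Flatten:
    params: tuple = ()
    decayed: tuple = ()

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = ("w", "b")
        self.decayed = ("w",)

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T


class Dropout:
    """Inverted dropout; active only during training."""

    params: tuple = ()
    decayed: tuple = ()

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# network


@dataclass
class CNNConfig:
    """Architecture of the 17-layer patch classifier."""

    input_size: int = 16
    conv_filters: tuple[int, int, int] = (8, 16, 32)
    conv_kernel: int = 3
    dropout_rate: float = 0.5
    n_classes: int = 2
    seed: int = 0


@dataclass
class TrainConfig:
    """SGDM hyperparameters (defaults: momentum 0.9, lr 1e-5 -> 1e-7,
    1000 epochs / 8000 iterations caps, batch 500, weight decay 0.005)."""

    lr_initial: float = 1e-5
    lr_final: float = 1e-7
    max_epochs: int = 1000
    max_iterations: int = 8000
    batch_size: int = 500
    momentum: float = 0.9
    weight_decay: float = 0.005
    lr_schedule: str = "geometric"  # or "constant"
    eval_every: int = 10  # epochs between (costly) full-train-set accuracy evals
    seed: int = 0

    def __post_init__(self):
        if self.lr_final > self.lr_initial:
            raise ContractError("lr_final must not exceed lr_initial")
        if min(self.lr_initial, self.lr_final, self.momentum + 1e-12,
               self.batch_size) <= 0:
            raise ContractError("rates and batch size must be positive")


class PatchCNN:
    """The 17-layer patch classifier: 3 conv blocks + FC head.

    ``enumerate_layers`` lists the architecture layer by layer (input, three
    convolution/batch-norm/ReLU/max-pool blocks, fully connected, dropout,
    softmax, classification output) — 17 in total.
    """

    def __init__(self, cfg: CNNConfig | None = None):
        cfg = cfg or CNNConfig()
        if cfg.input_size % 8 != 0:
            raise ContractError("input size must survive three 2x2 poolings")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f1, f2, f3 = cfg.conv_filters
        k = cfg.conv_kernel
        side = cfg.input_size // 8
        self.dropout = Dropout(cfg.dropout_rate, rng)
        self.layers = [
            Conv(1, f1, k, rng), BatchNorm(f1), ReLU(), MaxPool(),
            Conv(f1, f2, k, rng), BatchNorm(f2), ReLU(), MaxPool(),
            Conv(f2, f3, k, rng), BatchNorm(f3), ReLU(), MaxPool(),
            Flatten(), Dense(side * side * f3, cfg.n_classes, rng),
            self.dropout,
        ]
        self.trained = False

    def enumerate_layers(self) -> list[str]:
        names = ["input"]
        for i in range(1, 4):
            names += [f"conv{i}", f"batchnorm{i}", f"relu{i}", f"maxpool{i}"]
        names += ["fully_connected", "dropout", "softmax", "classification_output"]
        return names

    # forward/backward ------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        s = self.cfg.input_size
        if x.ndim != 3 or x.shape[1:] != (s, s):
            raise ContractError(f"expected (n, {s}, {s}) patches, got {x.shape}")
        return x[:, None, :, :]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities (n, 2); dropout is active only when training."""
        h = self._check_input(x)
        for layer in self.layers:
            h = layer.forward(h, train)
        return softmax(h)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> float:
        """Summed cross-entropy over the batch; leaves gradients on layers."""
        probs = self.forward(x, train=True)
        n = probs.shape[0]
        eps = 1e-12
        loss = float(-np.log(probs[np.arange(n), y] + eps).sum())
        d = probs.copy()
        d[np.arange(n), y] -= 1.0
        self._backward(d)
        return loss

    # persistence -----------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for p in layer.params:
                state[f"{i}.{p}"] = getattr(layer, p)
            if isinstance(layer, BatchNorm):
                state[f"{i}.running_mean"] = layer.running_mean
                state[f"{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            idx, name = key.split(".", 1)
            setattr(self.layers[int(idx)], name, np.asarray(value))
        self.trained = True

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cfg = {"input_size": self.cfg.input_size,
               "conv_filters": list(self.cfg.conv_filters),
               "conv_kernel": self.cfg.conv_kernel,
               "dropout_rate": self.cfg.dropout_rate,
               "n_classes": self.cfg.n_classes, "seed": self.cfg.seed,
               "trained": self.trained}
        np.savez(path, __config__=json.dumps(cfg), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "PatchCNN":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["__config__"]))
            trained = cfg.pop("trained")
            cfg["conv_filters"] = tuple(cfg["conv_filters"])
            model = cls(CNNConfig(**cfg))
            model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        model.trained = trained
        return model


def build_cnn(cfg: CNNConfig | None = None) -> PatchCNN:
    """Construct the default 17-layer patch classifier."""
    return PatchCNN(cfg)


# ---------------------------------------------------------------------------
# training


class _SGDM:
    def __init__(self, layers, momentum, weight_decay):
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = {}
        self.layers = layers

    def step(self, lr: float) -> None:
        for i, layer in enumerate(self.layers):
            for p in layer.params:
                grad = getattr(layer, "d" + p)
                if p in layer.decayed:
                    grad = grad + self.weight_decay * getattr(layer, p)
                key = (i, p)
                v = self.momentum * self.velocity.get(key, 0.0) - lr * grad
                self.velocity[key] = v
                setattr(layer, p, getattr(layer, p) + v)


def _epoch_lrs(tc: TrainConfig, planned_epochs: int) -> np.ndarray:
    if tc.lr_schedule == "constant" or planned_epochs <= 1:
        return np.full(max(planned_epochs, 1), tc.lr_initial)
    ratio = tc.lr_final / tc.lr_initial
    return tc.lr_initial * ratio ** (np.arange(planned_epochs) / (planned_epochs - 1))


def train_cnn(model: PatchCNN, ds: PatchDataset,
              tc: TrainConfig | None = None) -> pd.DataFrame:
    """Train in place with SGDM; returns a per-epoch log.

    Training stops at whichever of ``max_epochs`` / ``max_iterations`` binds
    first; the learning rate decays geometrically per epoch from
    ``lr_initial`` to ``lr_final`` over the planned run.  Partial final
    mini-batches are used.  The log has columns epoch, lr, train_loss (mean
    per sample), train_accuracy, val_accuracy.
    """
    tc = tc or TrainConfig()
    if ds.split_assignment is None:
        raise ContractError("train_cnn requires a dataset with a train/validation split")
    x_train, y_train = ds.arrays("train")
    x_val, y_val = ds.arrays("validation")
    if len(np.unique(y_train)) < 2:
        raise ContractError("training set must contain both classes")

    n = len(y_train)
    iters_per_epoch = math.ceil(n / tc.batch_size)
    planned_epochs = min(tc.max_epochs, math.ceil(tc.max_iterations / iters_per_epoch))
    lrs = _epoch_lrs(tc, planned_epochs)

    rng = np.random.default_rng(tc.seed)
    opt = _SGDM(model.layers, tc.momentum, tc.weight_decay)
    log = []
    iteration = 0
    for epoch in range(planned_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        seen = 0
        for start in range(0, n, tc.batch_size):
            if iteration >= tc.max_iterations:
                break
            idx = order[start:start + tc.batch_size]
            epoch_loss += model.loss_and_grad(x_train[idx], y_train[idx])
            seen += len(idx)
            opt.step(float(lrs[epoch]))
            iteration += 1
        last = iteration >= tc.max_iterations or epoch == planned_epochs - 1
        train_acc = (float((predict_classes(model, x_train) == y_train).mean())
                     if (epoch % tc.eval_every == 0 or last) else float("nan"))
        val_acc = (float((predict_classes(model, x_val) == y_val).mean())
                   if len(y_val) else float("nan"))
        log.append({"epoch": epoch + 1, "lr": float(lrs[epoch]),
                    "train_loss": epoch_loss / max(seen, 1),
                    "train_accuracy": train_acc, "val_accuracy": val_acc})
        if iteration >= tc.max_iterations:
            break
    model.trained = True
    return pd.DataFrame(log)


def predict_classes(model: PatchCNN, x: np.ndarray) -> np.ndarray:
    return model.forward(x, train=False).argmax(axis=1)


def predict_patches(model: PatchCNN, patches) -> list[tuple[str, float]]:
    """Per-patch (label, infarct probability); deterministic in eval mode."""
    if not model.trained:
        raise ContractError("predict_patches requires a trained model")
    x = np.stack([p.values for p in patches]).astype(np.float32)
    probs = model.forward(x, train=False)
    out = []
    for prob in probs:
        label = "infarcted" if prob[1] >= prob[0] else "non_infarcted"
        out.append((label, float(prob[1])))
    return out
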