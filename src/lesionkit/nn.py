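"""A small, seeded convolutional-network engine in pure NumPy.

This backs the "tiny" backbone used across the package: a 4-block
convolutional pyramid (3x3 conv + ReLU + 2x2 max-pool per block), truncated
after the 4th block, followed by global average pooling and a fully
connected head — sigmoid for binary malignancy scoring, softmax for the
(C+1)-way proposal classifier of the detector.  Training is plain SGD with
momentum and weight decay under either a half-period cosine learning-rate
schedule or step decay.

The engine is deliberately minimal: float32, CPU, deterministic given a
seed.  It exists so that every learnable stage of the pipeline is trainable
and testable at desk scale without a deep-learning framework.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "cosine_lr",
    "step_lr",
    "TinyConvNet",
    "SGDTrainer",
    "parameter_hash",
]


def cosine_lr(t: float, t_max: float, lr_init: float) -> float:
    """Half-period cosine learning-rate decay.

    ``eta(t) = lr_init * [0.5 + 0.5 * cos(t * pi / t_max)]``: starts at
    ``lr_init``, reaches ``lr_init / 2`` at mid-schedule and 0 at ``t_max``.
    Monotonically non-increasing on ``[0, t_max]``.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if t < 0 or t > t_max:
        raise ValueError(f"step t={t} outside [0, {t_max}]")
    return lr_init * (0.5 + 0.5 * math.cos(t * math.pi / t_max))


# Reference horizon for the detector's step schedule: with the full-scale
# training run the decay milestones sit at steps 60k and 80k of a 90k-step
# schedule; at smaller total step counts the milestones keep the same
# fractional positions (2/3 and 8/9).
_STEP_MILESTONE_FRACTIONS = (60000 / 90000, 80000 / 90000)


def step_lr(
    t: float,
    t_max: float,
    lr_init: float,
    milestone_fractions: Sequence[float] = _STEP_MILESTONE_FRACTIONS,
    gamma: float = 0.1,
) -> float:
    """Step decay: multiply by ``gamma`` at each milestone fraction of t_max."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if t < 0 or t > t_max:
        raise ValueError(f"step t={t} outside [0, {t_max}]")
    k = sum(t >= f * t_max for f in milestone_fractions)
    return lr_init * gamma**k


def _conv3x3_forward(x_pad: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution on NHWC input (already padded by 1)."""
    n, hp, wp, _ = x_pad.shape
    h, wd = hp - 2, wp - 2
    out = np.tile(b, (n, h, wd, 1)).astype(np.float32)
    for dy in range(3):
        for dx in range(3):
            out += x_pad[:, dy : dy + h, dx : dx + wd, :] @ w[dy, dx]
    return out


def _conv3x3_backward(x_pad: np.ndarray, w: np.ndarray, d_out: np.ndarray):
    n, hp, wp, cin = x_pad.shape
    h, wd = hp - 2, wp - 2
    cout = w.shape[-1]
    dw = np.zeros_like(w)
    dx_pad = np.zeros_like(x_pad)
    d_flat = d_out.reshape(-1, cout)
    for dy in range(3):
        for dx in range(3):
            view = x_pad[:, dy : dy + h, dx : dx + wd, :]
            dw[dy, dx] = view.reshape(-1, cin).T @ d_flat
            dx_pad[:, dy : dy + h, dx : dx + wd, :] += d_out @ w[dy, dx].T
    db = d_flat.sum(axis=0)
    return dw, db, dx_pad


def _pool2_forward(x: np.ndarray):
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    x = x[:, : 2 * h2, : 2 * w2, :]  # drop odd edge rows/cols
    windows = (
        x.reshape(n, h2, 2, w2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h2, w2, c, 4)
    )
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool2_backward(d_out: np.ndarray, cache, in_shape):
    idx, x_shape = cache
    n, h, w, c = x_shape
    h2, w2 = h // 2, w // 2
    d_windows = np.zeros((n, h2, w2, c, 4), dtype=np.float32)
    np.put_along_axis(d_windows, idx[..., None], d_out[..., None], axis=-1)
    dx = (
        d_windows.reshape(n, h2, w2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h, w, c)
    )
    if (h, w) != in_shape[1:3]:
        full = np.zeros(in_shape, dtype=np.float32)
        full[:, :h, :w, :] = dx
        return full
    return dx


class TinyConvNet:
    """4-block conv pyramid + global average pool + fully connected head.

    ``n_out == 1`` gives a sigmoid (binary) head; ``n_out > 1`` a softmax
    head.  ``features(X)`` exposes the pooled last-block feature maps, which
    is the representation the image–covariate fusion model consumes while
    keeping every convolutional layer frozen.
    """

    def __init__(
        self,
        n_out: int,
        in_channels: int = 3,
        channels: Sequence[int] = (8, 16, 32, 32),
        seed: int = 0,
    ):
        if len(channels) != 4:
            raise ValueError("the tiny backbone is truncated at 4 blocks")
        self.n_out = int(n_out)
        self.channels = tuple(int(c) for c in channels)
        self.in_channels = int(in_channels)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        cin = in_channels
        for i, cout in enumerate(self.channels):
            fan_in = 9 * cin
            self.params[f"conv{i}_w"] = (
                rng.normal(0.0, math.sqrt(2.0 / fan_in), (3, 3, cin, cout))
            ).astype(np.float32)
            self.params[f"conv{i}_b"] = np.zeros(cout, dtype=np.float32)
            cin = cout
        self.params["fc_w"] = (
            rng.normal(0.0, math.sqrt(2.0 / cin), (cin, self.n_out))
        ).astype(np.float32)
        self.params["fc_b"] = np.zeros(self.n_out, dtype=np.float32)

    # -- forward ---------------------------------------------------------

    @staticmethod
    def preprocess(images: np.ndarray) -> np.ndarray:
        """uint8 NHWC images -> centered float32 in [-1, 1]."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        return x / 127.5 - 1.0

    def _forward(self, x: np.ndarray, record: bool):
        caches = []
        for i in range(4):
            x_pad = np.pad(
                x, ((0, 0), (1, 1), (1, 1), (0, 0)), mode="constant"
            ).astype(np.float32)
            z = _conv3x3_forward(
                x_pad, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"]
            )
            relu_mask = z > 0
            a = z * relu_mask
            pooled, pcache = _pool2_forward(a)
            if record:
                caches.append((x_pad, relu_mask, pcache, a.shape))
            x = pooled
        feats = x.mean(axis=(1, 2))  # global average pool
        logits = feats @ self.params["fc_w"] + self.params["fc_b"]
        return logits, feats, x.shape, caches

    def features(self, images: np.ndarray) -> np.ndarray:
        """Global-average-pooled features of the truncated backbone."""
        _, feats, _, _ = self._forward(self.preprocess(images), record=False)
        return feats

    def logits(self, images: np.ndarray) -> np.ndarray:
        out, _, _, _ = self._forward(self.preprocess(images), record=False)
        return out

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Probabilities: shape (N,) for binary, (N, n_out) for softmax."""
        z = self.logits(images)
        if self.n_out == 1:
            return _sigmoid(z[:, 0])
        return _softmax(z)

    # -- loss / gradients ------------------------------------------------

    def loss_and_grads(self, images: np.ndarray, y: np.ndarray):
        """Mean cross-entropy loss and parameter gradients for a batch."""
        x = self.preprocess(images)
        y = np.asarray(y)
        logits, feats, pooled_shape, caches = self._forward(x, record=True)
        n = x.shape[0]
        if self.n_out == 1:
            z = logits[:, 0]
            p = _sigmoid(z)
            loss = float(
                np.mean(
                    np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
                )
            )
            d_logits = ((p - y) / n).astype(np.float32)[:, None]
        else:
            p = _softmax(logits)
            loss = float(
                -np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12)))
            )
            d_logits = p.copy()
            d_logits[np.arange(n), y] -= 1.0
            d_logits = (d_logits / n).astype(np.float32)

        grads: dict[str, np.ndarray] = {}
        grads["fc_w"] = feats.T @ d_logits
        grads["fc_b"] = d_logits.sum(axis=0)
        d_feats = d_logits @ self.params["fc_w"].T
        _, ph, pw, _ = pooled_shape
        d_pool = np.broadcast_to(
            d_feats[:, None, None, :] / (ph * pw), pooled_shape
        ).astype(np.float32)

        d_x = d_pool
        for i in reversed(range(4)):
            x_pad, relu_mask, pcache, a_shape = caches[i]
            d_a = _pool2_backward(d_x, pcache, a_shape)
            d_z = d_a * relu_mask
            dw, db, dx_pad = _conv3x3_backward(
                x_pad, self.params[f"conv{i}_w"], d_z
            )
            grads[f"conv{i}_w"] = dw
            grads[f"conv{i}_b"] = db
            d_x = dx_pad[:, 1:-1, 1:-1, :]
        return loss, grads

    def conv_parameter_names(self) -> list[str]:
        return [k for k in self.params if k.startswith("conv")]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def parameter_hash(net: TinyConvNet, names: Sequence[str] | None = None) -> str:
    """Stable hash of (a subset of) the network parameters."""
    h = hashlib.sha256()
    for name in sorted(names if names is not None else net.params):
        h.update(name.encode())
        h.update(np.ascontiguousarray(net.params[name]).tobytes())
    return h.hexdigest()


@dataclass
class SGDTrainer:
    """Minibatch SGD with momentum, weight decay and an LR schedule.

    ``schedule`` is ``"cosine"`` (half-period cosine to zero) or ``"step"``
    (10x decay at the 2/3 and 8/9 fractional milestones).  ``frozen``
    parameter names receive no updates.
    """

    epochs: int = 10
    batch_size: int = 64
    lr_init: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    schedule: str = "cosine"
    seed: int = 0
    frozen: tuple[str, ...] = ()

    def lr_at(self, t: int, t_max: int) -> float:
        if self.schedule == "cosine":
            return cosine_lr(t, t_max, self.lr_init)
        if self.schedule == "step":
            return step_lr(t, t_max, self.lr_init)
        raise ValueError(f"unknown schedule {self.schedule!r}")

    def train(
        self,
        net: TinyConvNet,
        images: np.ndarray,
        y: np.ndarray,
        augment_fn: Callable[[np.ndarray, np.random.Generator], np.ndarray]
        | None = None,
    ) -> list[float]:
        """Train in place; returns the per-epoch mean loss history."""
        images = np.asarray(images)
        y = np.asarray(y)
        n = images.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.seed)
        velocity = {k: np.zeros_like(v) for k, v in net.params.items()}
        steps_per_epoch = max(1, math.ceil(n / self.batch_size))
        t_max = self.epochs * steps_per_epoch
        history: list[float] = []
        t = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for s in range(steps_per_epoch):
                idx = order[s * self.batch_size : (s + 1) * self.batch_size]
                if idx.size == 0:
                    continue
                batch = images[idx]
                if augment_fn is not None:
                    batch = augment_fn(batch, rng)
                loss, grads = net.loss_and_grads(batch, y[idx])
                lr = self.lr_at(t, t_max)
                for k, g in grads.items():
                    if k in self.frozen:
                        continue
                    g = g + self.weight_decay * net.params[k]
                    velocity[k] = self.momentum * velocity[k] - lr * g
                    net.params[k] += velocity[k]
                epoch_losses.append(loss)
                t += 1
            history.append(float(np.mean(epoch_losses)))
        return history
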