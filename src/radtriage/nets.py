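"""Feed-forward sigmoid heads trained with Adam and binary cross-entropy.

Both the abnormality-probability head (one output) and the multi-label
tagging head (one sigmoid output per tag) are instances of the same small
fully connected network.  Training is full-batch Adam with a
reduce-on-plateau learning-rate schedule: when the validation loss has not
improved for `patience` consecutive epochs the rate is halved, down to
`min_lr`.  Everything is seeded and purely numpy, so two runs with the same
data and seed produce bit-identical weights.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings for the sigmoid heads.

    lr: initial Adam learning rate.
    epochs: full-batch epochs.
    hidden: sizes of optional ReLU hidden layers ('()' = a single dense
        layer with sigmoid, the default head).
    lr_reduce_factor / patience / min_lr: reduce-on-plateau schedule.
    """

    lr: float = 1e-3
    epochs: int = 300
    batch_size: int = 32
    hidden: tuple[int, ...] = ()
    seed: int = 0
    lr_reduce_factor: float = 0.5
    patience: int = 2
    min_lr: float = 1e-5
    l2: float = 0.0
    standardize: bool = True  # z-score inputs with training-split statistics


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy over all samples and output nodes."""
    eps = 1e-12
    p = np.clip(probs, eps, 1.0 - eps)
    return float(-np.mean(targets * np.log(p) + (1.0 - targets) * np.log(1.0 - p)))


class SigmoidNet:
    """Dense network with ReLU hidden layers and sigmoid outputs."""

    def __init__(self, in_dim: int, out_dim: int, hidden: Sequence[int] = (), seed: int = 0):
        self.in_dim = int(in_dim)
        self.out_dim = int(out_dim)
        self.hidden = tuple(int(h) for h in hidden)
        # optional input standardization fitted on the training split
        self.input_mean: np.ndarray | None = None
        self.input_scale: np.ndarray | None = None
        rng = np.random.default_rng(seed)
        sizes = [self.in_dim, *self.hidden, self.out_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for nin, nout in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (nin + nout))  # Glorot uniform
            self.weights.append(rng.uniform(-bound, bound, size=(nin, nout)))
            self.biases.append(np.zeros(nout))

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [x]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ w + b
            a = _sigmoid(z) if i == len(self.weights) - 1 else np.maximum(z, 0.0)
            acts.append(a)
        return acts[-1], acts

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.in_dim:
            raise ValueError(f"expected input dimension {self.in_dim}, got {x.shape[1]}")
        if self.input_mean is not None:
            x = (x - self.input_mean) / self.input_scale
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self._forward(self.transform(x))[0]

    def _gradients(self, x: np.ndarray, y: np.ndarray, l2: float):
        probs, acts = self._forward(x)
        n = x.shape[0]
        delta = (probs - y) / (n * self.out_dim)  # d(mean BCE)/d(logits)
        grads_w, grads_b = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            gw = acts[i].T @ delta + l2 * self.weights[i]
            gb = delta.sum(axis=0)
            grads_w.append(gw)
            grads_b.append(gb)
            if i > 0:
                delta = (delta @ self.weights[i].T) * (acts[i] > 0)
        return probs, grads_w[::-1], grads_b[::-1]

    def parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]


def train_sigmoid_net(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    out_dim: int,
    config: TrainConfig,
) -> tuple[SigmoidNet, dict]:
    """Fit a sigmoid head; returns the net and a per-epoch history dict.

    Raises RuntimeError on non-finite loss (diverged optimization).
    """
    x_train = np.asarray(x_train, dtype=np.float64)
    y_train = np.atleast_2d(np.asarray(y_train, dtype=np.float64))
    if y_train.shape[0] == 1 and x_train.shape[0] != 1:
        y_train = y_train.T
    x_val = np.asarray(x_val, dtype=np.float64)
    y_val = np.atleast_2d(np.asarray(y_val, dtype=np.float64))
    if y_val.shape[0] == 1 and x_val.shape[0] != 1:
        y_val = y_val.T

    net = SigmoidNet(x_train.shape[1], out_dim, config.hidden, seed=config.seed)
    if config.standardize:
        net.input_mean = x_train.mean(axis=0)
        scale = x_train.std(axis=0)
        scale[scale < 1e-8] = 1.0
        net.input_scale = scale
    x_fit = net.transform(x_train)
    n = x_fit.shape[0]
    batch = min(config.batch_size, n)
    params = net.parameters()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.lr
    best_val = np.inf
    stale = 0
    step = 0
    batch_rng = np.random.default_rng(config.seed + 1)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}

    for epoch in range(1, config.epochs + 1):
        perm = batch_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch):
            idx = perm[start:start + batch]
            probs, grads_w, grads_b = net._gradients(x_fit[idx], y_train[idx], config.l2)
            batch_loss = bce_loss(probs, y_train[idx])
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            epoch_losses.append(batch_loss)
            step += 1
            grads = [*grads_w, *grads_b]
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                mhat = mi / (1 - beta1 ** step)
                vhat = vi / (1 - beta2 ** step)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
        train_loss = float(np.mean(epoch_losses))

        val_loss = bce_loss(net.predict_proba(x_val), y_val)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(lr)
        # reduce-on-plateau: halve after `patience` epochs without improvement
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            stale = 0
        else:
            stale += 1
            if stale >= config.patience and lr > config.min_lr:
                lr = max(lr * config.lr_reduce_factor, config.min_lr)
                stale = 0
    return net, history
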