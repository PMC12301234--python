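"""Convolutional sequence classifier for binder triage.

A small 1-D convolutional network over one-hot encoded amino-acid sequences:
two convolutional layers (ReLU), global max pooling, one hidden dense layer
and a sigmoid output. Implemented directly in numpy (forward + backprop +
Adam); at triage scale (a few thousand sequences of ~120 residues) this
trains in seconds to minutes on one CPU and is exactly reproducible given a
seed. Model selection follows the screening workflow: the per-epoch
checkpoint with the best validation F1 is returned, and the predicted
probability is thresholded to call binders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .knn import fbeta_from_predictions

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class ConvArchitecture:
    """Architecture description: (kernel, filters) per conv layer + hidden width."""

    conv_layers: tuple[tuple[int, int], ...] = ((5, 32), (3, 64))
    hidden: int = 64


def one_hot_encode(sequences: Sequence[str], max_len: int) -> np.ndarray:
    """Encode to (N, max_len, 20) float32, right-padded with zeros."""
    X = np.zeros((len(sequences), max_len, len(AA_ALPHABET)), dtype=np.float32)
    for i, seq in enumerate(sequences):
        if len(seq) > max_len:
            raise ValueError(f"sequence longer than model max_len={max_len}")
        for j, res in enumerate(seq):
            try:
                X[i, j, _AA_INDEX[res]] = 1.0
            except KeyError:
                raise ValueError(f"non-standard residue {res!r}") from None
    return X


def _patches(x: np.ndarray, k: int) -> np.ndarray:
    # (N, L, C) -> (N, L-k+1, k*C)
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
    # win: (N, T, C, k) -> (N, T, k, C)
    win = win.transpose(0, 1, 3, 2)
    n, t = win.shape[:2]
    return np.ascontiguousarray(win).reshape(n, t, -1)


class _Net:
    """Parameter container with forward/backward passes."""

    def __init__(self, arch: ConvArchitecture, in_channels: int,
                 rng: np.random.Generator):
        self.arch = arch
        self.params: dict[str, np.ndarray] = {}
        c_in = in_channels
        for li, (k, c_out) in enumerate(arch.conv_layers):
            fan_in = k * c_in
            self.params[f"Wc{li}"] = (rng.standard_normal((fan_in, c_out))
                                      * np.sqrt(2.0 / fan_in)).astype(np.float32)
            self.params[f"bc{li}"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        self.params["Wh"] = (rng.standard_normal((c_in, arch.hidden))
                             * np.sqrt(2.0 / c_in)).astype(np.float32)
        self.params["bh"] = np.zeros(arch.hidden, dtype=np.float32)
        self.params["Wo"] = (rng.standard_normal((arch.hidden, 1))
                             * np.sqrt(2.0 / arch.hidden)).astype(np.float32)
        self.params["bo"] = np.zeros(1, dtype=np.float32)

    def forward(self, X: np.ndarray, cache: dict | None = None) -> np.ndarray:
        h = X
        for li, (k, _) in enumerate(self.arch.conv_layers):
            p = _patches(h, k)
            z = p @ self.params[f"Wc{li}"] + self.params[f"bc{li}"]
            a = np.maximum(z, 0.0)
            if cache is not None:
                cache[f"p{li}"], cache[f"z{li}"] = p, z
                cache[f"shape{li}"] = h.shape
            h = a
        pooled = h.max(axis=1)
        if cache is not None:
            cache["argmax"] = h.argmax(axis=1)
            cache["conv_out_shape"] = h.shape
        zh = pooled @ self.params["Wh"] + self.params["bh"]
        ah = np.maximum(zh, 0.0)
        logit = (ah @ self.params["Wo"] + self.params["bo"]).ravel()
        if cache is not None:
            cache["pooled"], cache["zh"], cache["ah"] = pooled, zh, ah
        prob = 1.0 / (1.0 + np.exp(-logit))
        return prob

    def backward(self, X: np.ndarray, y: np.ndarray, cache: dict,
                 prob: np.ndarray) -> dict[str, np.ndarray]:
        n = len(y)
        grads: dict[str, np.ndarray] = {}
        dlogit = ((prob - y) / n).astype(np.float32)  # BCE + sigmoid
        grads["Wo"] = cache["ah"].T @ dlogit[:, None]
        grads["bo"] = np.array([dlogit.sum()], dtype=np.float32)
        dah = dlogit[:, None] @ self.params["Wo"].T
        dzh = dah * (cache["zh"] > 0)
        grads["Wh"] = cache["pooled"].T @ dzh
        grads["bh"] = dzh.sum(axis=0)
        dpooled = dzh @ self.params["Wh"].T
        # route pooled gradient back to argmax time steps
        n_, t_, c_ = cache["conv_out_shape"]
        dconv = np.zeros((n_, t_, c_), dtype=np.float32)
        ii = np.repeat(np.arange(n_), c_)
        cc = np.tile(np.arange(c_), n_)
        dconv[ii, cache["argmax"].ravel(), cc] = dpooled.ravel()
        for li in reversed(range(len(self.arch.conv_layers))):
            k, _ = self.arch.conv_layers[li]
            dz = dconv * (cache[f"z{li}"] > 0)
            p = cache[f"p{li}"]
            grads[f"Wc{li}"] = np.tensordot(p, dz, axes=([0, 1], [0, 1]))
            grads[f"bc{li}"] = dz.sum(axis=(0, 1))
            if li > 0:
                dp = dz @ self.params[f"Wc{li}"].T  # (N, T, k*C)
                n_in, l_in, c_in = cache[f"shape{li}"]
                dp = dp.reshape(dp.shape[0], dp.shape[1], k, c_in)
                dh = np.zeros((n_in, l_in, c_in), dtype=np.float32)
                t_len = dp.shape[1]
                for j in range(k):
                    dh[:, j : j + t_len, :] += dp[:, :, j, :]
                dconv = dh
        return grads


class _Adam:
    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            params[key] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32)


@dataclass
class ConvTriageModel:
    architecture: ConvArchitecture
    max_len: int
    params: dict[str, np.ndarray] = field(repr=False, default=None)
    threshold: float = 0.5
    best_epoch: int = -1
    best_val_f1: float = float("nan")
    history: pd.DataFrame = field(repr=False, default=None)

    def predict_proba(self, sequences: Sequence[str]) -> np.ndarray:
        net = _Net(self.architecture, len(AA_ALPHABET),
                   np.random.default_rng(0))
        net.params = self.params
        X = one_hot_encode(sequences, self.max_len)
        return net.forward(X)


def _stratified_split(y: np.ndarray, fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    val_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(fraction * len(idx))))
        val_idx.append(idx[:n_val])
    val = np.sort(np.concatenate(val_idx))
    train = np.setdiff1d(np.arange(len(y)), val)
    return train, val


def train_conv_classifier(
    training,
    validation_fraction: float = 0.2,
    architecture: ConvArchitecture | None = None,
    epochs: int = 15,
    seed: int = 0,
    batch_size: int = 32,
    lr: float = 3e-3,
    threshold: float = 0.5,
) -> ConvTriageModel:
    """Train the convolutional classifier with best-validation-F1 selection.

    ``training`` is a :class:`panscreen.knn.TrainingSet`. A stratified
    validation split is scored after every epoch; the parameter snapshot
    with the highest validation F1 (ties: earliest epoch) is returned.
    Fully deterministic given ``seed``.
    """
    if architecture is None:
        architecture = ConvArchitecture()
    if not (0 < validation_fraction < 1):
        raise ValueError("validation_fraction must be in (0, 1)")
    y = np.asarray(training.labels, dtype=np.float32)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = _stratified_split(y.astype(int), validation_fraction, rng)
    if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[val_idx])) < 2:
        raise ValueError("degenerate single-class split")
    max_len = max(len(s) for s in training.sequences)
    X = one_hot_encode(training.sequences, max_len)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]
    net = _Net(architecture, len(AA_ALPHABET), rng)
    opt = _Adam(net.params, lr=lr)
    best = (-1.0, -1, None)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(len(ytr))
        for start in range(0, len(order), batch_size):
            batch = order[start : start + batch_size]
            cache: dict = {}
            prob = net.forward(Xtr[batch], cache)
            grads = net.backward(Xtr[batch], ytr[batch], cache, prob)
            opt.step(net.params, grads)
        val_prob = net.forward(Xval)
        val_pred = (val_prob >= threshold).astype(int)
        val_f1 = fbeta_from_predictions(yval.astype(int), val_pred, beta=1.0)
        eps = 1e-7
        val_loss = float(-np.mean(yval * np.log(val_prob + eps)
                                  + (1 - yval) * np.log(1 - val_prob + eps)))
        history.append({"epoch": epoch, "val_f1": val_f1, "val_loss": val_loss})
        if val_f1 > best[0]:
            best = (val_f1, epoch, {k: v.copy() for k, v in net.params.items()})
    return ConvTriageModel(architecture=architecture, max_len=max_len,
                           params=best[2], threshold=threshold,
                           best_epoch=best[1], best_val_f1=best[0],
                           history=pd.DataFrame(history))


def predict_binders(
    model: ConvTriageModel,
    sequences: Sequence[str],
    threshold: float | None = None,
) -> list[tuple[str, float]]:
    """Score sequences and keep those with probability >= threshold."""
    if threshold is None:
        threshold = model.threshold
    probs = model.predict_proba(sequences)
    return [(s, float(p)) for s, p in zip(sequences, probs) if p >= threshold]
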