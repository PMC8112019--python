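"""A compact, deterministic CNN for scrambled-rectangle connectome input.

Architecture (fixed up to widths): one convolution layer whose filters span a
full rectangle row across all input channels (shape 1 x n_cols x n_channels),
ReLU, flatten, then three dense layers of 64 units each with batch
normalisation, ReLU and 0.5 dropout, and a final softmax over the two
classes.  Trained with Adam on cross-entropy; a parameter snapshot is taken
every epoch and the snapshot with the highest validation accuracy is the
returned model (ties broken by the earliest epoch).

The network is written directly on NumPy with explicit backward passes.
That keeps training deterministic for a given seed and, importantly, exposes
the intermediate gradients that Grad-CAM and guided backpropagation need
(see :mod:`wassconn.saliency`).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelSpec", "TrainedModel", "train_member", "DegenerateLabelsError"]

_BN_EPS = 1e-5


class DegenerateLabelsError(ValueError):
    """Training set contains a single class."""


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one ensemble member."""

    n_filters: int = 256
    dense_units: int = 64
    n_dense: int = 3
    dropout: float = 0.5
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if min(self.n_filters, self.dense_units, self.n_dense, self.epochs) < 1:
            raise ValueError("widths, depth and epochs must be positive")


def _init_params(spec: ModelSpec, rect_shape: tuple[int, int], n_channels: int, rng):
    """He-initialised parameter dictionary."""
    rows, cols = rect_shape
    ck = cols * n_channels
    p: dict[str, np.ndarray] = {}
    p["Wc"] = rng.standard_normal((spec.n_filters, ck)) * np.sqrt(2.0 / ck)
    p["bc"] = np.zeros(spec.n_filters)
    fan_in = rows * spec.n_filters
    for i in range(spec.n_dense):
        p[f"W{i}"] = rng.standard_normal((fan_in, spec.dense_units)) * np.sqrt(2.0 / fan_in)
        p[f"b{i}"] = np.zeros(spec.dense_units)
        p[f"gamma{i}"] = np.ones(spec.dense_units)
        p[f"beta{i}"] = np.zeros(spec.dense_units)
        fan_in = spec.dense_units
    p["Wo"] = rng.standard_normal((fan_in, 2)) * np.sqrt(2.0 / fan_in)
    p["bo"] = np.zeros(2)
    return p


def _init_bn_stats(spec: ModelSpec):
    return {
        f"{k}{i}": np.zeros(spec.dense_units) if k == "mean" else np.ones(spec.dense_units)
        for i in range(spec.n_dense)
        for k in ("mean", "var")
    }


@dataclass
class TrainedModel:
    """Parameters of the best-validation epoch plus provenance."""

    spec: ModelSpec
    rect_shape: tuple[int, int]
    n_channels: int
    params: dict[str, np.ndarray]
    bn_stats: dict[str, np.ndarray]
    best_epoch: int = 0
    val_accuracy_trace: list[float] = field(default_factory=list)

    # ------------------------------------------------------------------ forward
    def _forward(self, x: np.ndarray, train: bool = False, drop_rng=None,
                 bn_batch: bool = False):
        """Forward pass returning (logits, cache).

        ``x`` has shape (batch, rows, cols, channels).  With ``train`` the
        dropout masks are sampled from ``drop_rng`` and batch-norm uses batch
        statistics; in eval mode dropout is identity and batch-norm uses the
        running statistics.
        """
        p = self.params
        spec = self.spec
        b, rows, cols, k = x.shape
        x2 = x.reshape(b, rows, cols * k)
        z1 = x2 @ p["Wc"].T + p["bc"]  # (b, rows, filters)
        a1 = np.maximum(z1, 0.0)
        h = a1.reshape(b, rows * spec.n_filters)
        cache = {"x": x, "x2": x2, "z1": z1, "a1": a1, "flat": h, "dense": []}
        for i in range(spec.n_dense):
            z = h @ p[f"W{i}"] + p[f"b{i}"]
            if train or bn_batch:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
            else:
                mu = self.bn_stats[f"mean{i}"]
                var = self.bn_stats[f"var{i}"]
            zhat = (z - mu) / np.sqrt(var + _BN_EPS)
            zb = p[f"gamma{i}"] * zhat + p[f"beta{i}"]
            a = np.maximum(zb, 0.0)
            if train and spec.dropout > 0:
                keep = 1.0 - spec.dropout
                mask = (drop_rng.random(a.shape) < keep) / keep
            else:
                mask = np.ones_like(a)
            out = a * mask
            cache["dense"].append(
                {"h_in": h, "z": z, "mu": mu, "var": var, "zhat": zhat,
                 "zb": zb, "a": a, "mask": mask}
            )
            h = out
        logits = h @ p["Wo"] + p["bo"]
        cache["h_last"] = h
        return logits, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Case-class probability for a batch of encoded rectangles."""
        logits, _ = self._forward(np.asarray(x, dtype=float), train=False)
        return _softmax(logits)[:, 1]

    def predict_label(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x) >= 0.5).astype(int)

    # ----------------------------------------------------------------- backward
    def backward_from_logit(self, cache, target_class: int, guided: bool = False,
                            contrastive: bool = False):
        """Gradient of a class score w.r.t. the conv activation and the input.

        Used by saliency analysis in eval mode (batch statistics frozen).
        The score is the target-class logit, or with ``contrastive`` the
        target logit minus the other logit (the log-odds) — which removes
        the common-mode direction that cancels in the softmax.  With
        ``guided`` each ReLU passes gradient only where both its activation
        and the incoming gradient are positive (guided backpropagation);
        otherwise the exact gradient flows.

        Returns (d_score/d_a1, d_score/d_x).
        """
        p = self.params
        spec = self.spec
        b = cache["x"].shape[0]
        dh = np.zeros((b, 2))
        dh[:, target_class] = 1.0
        if contrastive:
            dh[:, 1 - target_class] = -1.0
        dh = dh @ p["Wo"].T  # grad wrt output of last dense block
        for i in reversed(range(spec.n_dense)):
            c = cache["dense"][i]
            da = dh * c["mask"]
            relu_gate = (c["zb"] > 0).astype(float)
            if guided:
                relu_gate = relu_gate * (da > 0)
            dzb = da * relu_gate
            dzhat = dzb * p[f"gamma{i}"]
            dz = dzhat / np.sqrt(c["var"] + _BN_EPS)  # eval mode: stats constant
            dh = dz @ p[f"W{i}"].T
        da1 = dh.reshape(cache["a1"].shape)
        gate = (cache["z1"] > 0).astype(float)
        if guided:
            gate = gate * (da1 > 0)
        dz1 = da1 * gate
        dx2 = dz1 @ p["Wc"]
        dx = dx2.reshape(cache["x"].shape)
        return da1, dx


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _train_backward(model: TrainedModel, cache, probs, y):
    """Cross-entropy gradients for all parameters (batch-stat batch norm)."""
    p = model.params
    spec = model.spec
    b = y.size
    grads: dict[str, np.ndarray] = {}
    dlogits = probs.copy()
    dlogits[np.arange(b), y] -= 1.0
    dlogits /= b
    grads["Wo"] = cache["h_last"].T @ dlogits
    grads["bo"] = dlogits.sum(axis=0)
    dh = dlogits @ p["Wo"].T
    for i in reversed(range(spec.n_dense)):
        c = cache["dense"][i]
        da = dh * c["mask"]
        dzb = da * (c["zb"] > 0)
        grads[f"gamma{i}"] = (dzb * c["zhat"]).sum(axis=0)
        grads[f"beta{i}"] = dzb.sum(axis=0)
        dzhat = dzb * p[f"gamma{i}"]
        inv_std = 1.0 / np.sqrt(c["var"] + _BN_EPS)
        # batch-norm backward through batch statistics
        dz = (
            dzhat
            - dzhat.mean(axis=0)
            - c["zhat"] * (dzhat * c["zhat"]).mean(axis=0)
        ) * inv_std
        grads[f"W{i}"] = c["h_in"].T @ dz
        grads[f"b{i}"] = dz.sum(axis=0)
        dh = dz @ p[f"W{i}"].T
    da1 = dh.reshape(cache["a1"].shape)
    dz1 = da1 * (cache["z1"] > 0)
    grads["Wc"] = np.einsum("brf,brc->fc", dz1, cache["x2"])
    grads["bc"] = dz1.sum(axis=(0, 1))
    return grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train_member(
    spec: ModelSpec,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
) -> TrainedModel:
    """Train one ensemble member and return its best-validation checkpoint.

    Labels are 0 = control, 1 = case.  Validation accuracy is evaluated after
    every epoch; the parameter snapshot with the highest accuracy wins, ties
    going to the earliest epoch.  Fully deterministic given ``spec.seed`` and
    the data.
    """
    train_x = np.asarray(train_x, dtype=float)
    val_x = np.asarray(val_x, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    val_y = np.asarray(val_y, dtype=int)
    if train_x.ndim == 3:
        train_x = train_x[..., None]
    if val_x.ndim == 3:
        val_x = val_x[..., None]
    if train_x.size == 0 or val_x.size == 0:
        raise ValueError("empty training or validation set")
    if len(np.unique(train_y)) < 2:
        raise DegenerateLabelsError("training set contains a single class")

    _, rows, cols, k = train_x.shape
    rng = np.random.default_rng(spec.seed)
    params = _init_params(spec, (rows, cols), k, rng)
    model = TrainedModel(
        spec=spec, rect_shape=(rows, cols), n_channels=k,
        params=params, bn_stats=_init_bn_stats(spec),
    )
    opt = _Adam(params, spec.learning_rate)
    n = train_x.shape[0]
    best_acc = -1.0
    best_params = None
    best_stats = None
    best_epoch = -1
    momentum = 0.9  # running batch-norm statistics
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            if idx.size < 2:
                continue  # batch statistics undefined on singleton batches
            xb, yb = train_x[idx], train_y[idx]
            logits, cache = model._forward(xb, train=True, drop_rng=rng)
            probs = _softmax(logits)
            grads = _train_backward(model, cache, probs, yb)
            opt.step(params, grads)
            for i in range(spec.n_dense):
                c = cache["dense"][i]
                model.bn_stats[f"mean{i}"] = (
                    momentum * model.bn_stats[f"mean{i}"] + (1 - momentum) * c["mu"]
                )
                model.bn_stats[f"var{i}"] = (
                    momentum * model.bn_stats[f"var{i}"] + (1 - momentum) * c["var"]
                )
        val_acc = float(np.mean(model.predict_label(val_x) == val_y))
        model.val_accuracy_trace.append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_params = copy.deepcopy(params)
            best_stats = copy.deepcopy(model.bn_stats)
            best_epoch = epoch
    model.params = best_params
    model.bn_stats = best_stats
    model.best_epoch = best_epoch
    return model
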