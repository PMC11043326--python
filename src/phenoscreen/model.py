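"""Masked multi-task activity models.

A single network predicts activity in every assay of the panel at once
(multi-label binary prediction, one sigmoid output per assay).  Because the
label matrix is incomplete, the loss is *masked*: unknown compound-assay
cells contribute exactly zero to the objective and to its gradient, so the
network trains on whatever labels exist without imputation.

The objective is binary cross-entropy modulated by the focal factor
``(1 - p_t)^gamma`` (gamma = 0 recovers plain BCE), which down-weights easy
examples — important at the ~3% hit rates typical of single-concentration
HTS labels.  A ``bce+focal`` variant sums the two terms 1:1.

Networks are small numpy modules with hand-written backward passes: an MLP
for feature-vector and fingerprint inputs, and a compact convolutional
network for tiny multichannel images.  Training uses minibatch SGD or Adam
with early stopping on mean per-assay validation ROC-AUC and learning-rate
reduction on plateau.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import aggregate_replicates

__all__ = [
    "CNN",
    "MLP",
    "ModelConfig",
    "PredictionMatrix",
    "build_model",
    "expand_input_channels",
    "features_model_config",
    "image_model_config",
    "masked_focal_bce",
    "predict",
    "structure_model_config",
    "train",
]

_P_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one modality's network and its training run."""

    modality: str = "features"  # features | structure | image
    hidden_layers: int = 3
    hidden_width: int = 1024
    conv_channels: tuple[int, ...] = (8, 16, 32, 64)  # image modality only
    gamma: float = 2.0
    loss: str = "focal"  # bce | focal | bce+focal
    learning_rate: float = 1.0
    weight_decay: float = 0.0
    optimizer: str = "sgd"  # sgd | adam
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in {"features", "structure", "image"}:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.loss not in {"bce", "focal", "bce+focal"}:
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in {"sgd", "adam"}:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.gamma < 0 or self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("gamma/weight_decay must be >= 0 and learning_rate > 0")
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 0:
            raise ValueError("batch_size and patience must be >= 1, max_epochs >= 0")

    def with_(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


def features_model_config(**overrides) -> ModelConfig:
    """Morphological-feature MLP defaults: 3 hidden layers of width 1024, SGD lr 5.0."""
    cfg = ModelConfig(modality="features", hidden_layers=3, hidden_width=1024,
                      learning_rate=5.0, weight_decay=0.0, optimizer="sgd", max_epochs=150)
    return cfg.with_(**overrides)


def structure_model_config(**overrides) -> ModelConfig:
    """Fingerprint MLP defaults: 3 hidden layers of width 512, SGD lr 2.0."""
    cfg = ModelConfig(modality="structure", hidden_layers=3, hidden_width=512,
                      learning_rate=2.0, weight_decay=0.0, optimizer="sgd", max_epochs=150)
    return cfg.with_(**overrides)


def image_model_config(batch_size: int = 64, **overrides) -> ModelConfig:
    """Image CNN defaults: SGD, weight decay 1e-4, per-sample rate 0.2/256 scaled by batch."""
    cfg = ModelConfig(modality="image", learning_rate=0.2 * batch_size / 256.0,
                      weight_decay=1e-4, optimizer="sgd", batch_size=batch_size)
    return cfg.with_(**overrides)


# ---------------------------------------------------------------------------
# loss


def masked_focal_bce(scores: np.ndarray, labels: np.ndarray, gamma: float = 2.0,
                     loss: str = "focal") -> float:
    """Mean focal-modulated binary cross-entropy over the observed labels.

    ``scores`` are probabilities in [0, 1]; ``labels`` is a matching ternary
    array with 1 active, 0 inactive and NaN unknown.  Unknown cells contribute
    exactly zero.  With no observed cells the loss is 0 (with a warning).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError(f"shape mismatch: scores {scores.shape} vs labels {labels.shape}")
    mask = ~np.isnan(labels)
    n_obs = int(mask.sum())
    if n_obs == 0:
        warnings.warn("no observed labels; masked loss is 0", stacklevel=2)
        return 0.0
    p = np.clip(scores[mask], _P_EPS, 1.0 - _P_EPS)
    y = labels[mask]
    p_t = np.where(y == 1.0, p, 1.0 - p)
    log_pt = np.log(p_t)
    focal = -((1.0 - p_t) ** gamma) * log_pt
    if loss == "focal":
        per_cell = focal
    elif loss == "bce":
        per_cell = -log_pt
    elif loss == "bce+focal":
        per_cell = -log_pt + focal
    else:
        raise ValueError(f"unknown loss {loss!r}")
    return float(per_cell.mean())


def _loss_grad_logits(logits: np.ndarray, labels: np.ndarray, gamma: float,
                      loss: str) -> tuple[float, np.ndarray]:
    """Loss value and d(loss)/d(logits) with masking; used by the trainer."""
    mask = ~np.isnan(labels)
    n_obs = int(mask.sum())
    grad = np.zeros_like(logits)
    if n_obs == 0:
        return 0.0, grad
    z = logits[mask]
    y = labels[mask]
    p = 1.0 / (1.0 + np.exp(-z))
    p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    p_t = np.where(y == 1.0, p, 1.0 - p)
    log_pt = np.log(p_t)
    sign = 2.0 * y - 1.0
    one_m = 1.0 - p_t

    def focal_terms():
        val = -(one_m**gamma) * log_pt
        # d/dz of -(1-p_t)^g log p_t with dp_t/dz = sign * p_t (1 - p_t)
        g = sign * (gamma * p_t * (one_m**gamma) * log_pt - one_m ** (gamma + 1.0))
        return val, g

    def bce_terms():
        return -log_pt, sign * (p_t - 1.0)

    if loss == "focal":
        val, g = focal_terms()
    elif loss == "bce":
        val, g = bce_terms()
    else:  # bce+focal
        v1, g1 = bce_terms()
        v2, g2 = focal_terms()
        val, g = v1 + v2, g1 + g2
    grad[mask] = g / n_obs
    return float(val.mean()), grad


# ---------------------------------------------------------------------------
# networks


class MLP:
    """Fully connected ReLU network with sigmoid multi-assay outputs."""

    def __init__(self, in_dim: int, n_outputs: int, hidden_layers: int, hidden_width: int,
                 rng: np.random.Generator):
        dims = [in_dim] + [hidden_width] * hidden_layers + [n_outputs]
        self.weights = []
        self.biases = []
        for i, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
            scale = np.sqrt(2.0 / d_in) if i < len(dims) - 2 else np.sqrt(1.0 / d_in)
            self.weights.append(rng.normal(0.0, scale, size=(d_in, d_out)))
            self.biases.append(np.zeros(d_out))
        self.n_outputs = n_outputs

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_output_bias(self, bias: np.ndarray) -> None:
        self.biases[-1] = np.asarray(bias, dtype=float).copy()

    def state_dict(self) -> dict:
        return {"weights": [w.copy() for w in self.weights],
                "biases": [b.copy() for b in self.biases]}

    def load_state_dict(self, state: dict) -> None:
        self.weights = [w.copy() for w in state["weights"]]
        self.biases = [b.copy() for b in state["biases"]]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        a = np.asarray(x, dtype=float)
        cache = []
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            cache.append((a, z))
            a = np.maximum(z, 0.0) if i < len(self.weights) - 1 else z
        return a, cache  # final `a` is the logit matrix

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits(x)))

    def backward(self, cache: list, dlogits: np.ndarray) -> list[np.ndarray]:
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = dlogits
        for i in reversed(range(len(self.weights))):
            a_in, z = cache[i]
            if i < len(self.weights) - 1:
                delta = delta * (z > 0)
            grads_w[i] = a_in.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
        return grads_w + grads_b


def _conv2d(x: np.ndarray, w: np.ndarray, pad: int = 1) -> np.ndarray:
    """Same-size 3x3 cross-correlation: x (B,C,H,W), w (O,C,kh,kw) -> (B,O,H,W)."""
    kh, kw = w.shape[2], w.shape[3]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return np.einsum("bchwij,ocij->bohw", windows, w, optimize=True)


class CNN:
    """Small convolutional network for tiny multichannel images.

    Repeated [3x3 conv -> ReLU -> 2x2 mean-pool] blocks, global average
    pooling and a linear sigmoid head.  Input height/width must be divisible
    by 2**n_blocks.
    """

    def __init__(self, in_channels: int, image_size: int, n_outputs: int,
                 conv_channels: tuple[int, ...], rng: np.random.Generator):
        if image_size % (2 ** len(conv_channels)) != 0:
            raise ValueError(
                f"image size {image_size} not divisible by 2^{len(conv_channels)} blocks")
        self.kernels = []
        self.kbiases = []
        c_in = in_channels
        for c_out in conv_channels:
            scale = np.sqrt(2.0 / (c_in * 9))
            self.kernels.append(rng.normal(0.0, scale, size=(c_out, c_in, 3, 3)))
            self.kbiases.append(np.zeros(c_out))
            c_in = c_out
        self.head_w = rng.normal(0.0, np.sqrt(1.0 / c_in), size=(c_in, n_outputs))
        self.head_b = np.zeros(n_outputs)
        self.n_outputs = n_outputs
        self.in_channels = in_channels

    def parameters(self) -> list[np.ndarray]:
        return self.kernels + self.kbiases + [self.head_w, self.head_b]

    def set_output_bias(self, bias: np.ndarray) -> None:
        self.head_b = np.asarray(bias, dtype=float).copy()

    def state_dict(self) -> dict:
        return {"kernels": [k.copy() for k in self.kernels],
                "kbiases": [b.copy() for b in self.kbiases],
                "head_w": self.head_w.copy(), "head_b": self.head_b.copy()}

    def load_state_dict(self, state: dict) -> None:
        self.kernels = [k.copy() for k in state["kernels"]]
        self.kbiases = [b.copy() for b in state["kbiases"]]
        self.head_w = state["head_w"].copy()
        self.head_b = state["head_b"].copy()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        a = np.asarray(x, dtype=float)
        cache = []
        for k, b in zip(self.kernels, self.kbiases):
            z = _conv2d(a, k) + b[None, :, None, None]
            r = np.maximum(z, 0.0)
            B, C, H, W = r.shape
            pooled = r.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
            cache.append((a, z, r.shape))
            a = pooled
        gap = a.mean(axis=(2, 3))
        logits = gap @ self.head_w + self.head_b
        cache.append((a.shape, gap))
        return logits, cache

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.logits(x)))

    def backward(self, cache: list, dlogits: np.ndarray) -> list[np.ndarray]:
        pooled_shape, gap = cache[-1]
        d_head_w = gap.T @ dlogits
        d_head_b = dlogits.sum(axis=0)
        dgap = dlogits @ self.head_w.T
        B, C, H, W = pooled_shape
        da = np.broadcast_to(dgap[:, :, None, None], pooled_shape) / (H * W)
        grads_k = [None] * len(self.kernels)
        grads_b = [None] * len(self.kernels)
        for i in reversed(range(len(self.kernels))):
            a_in, z, r_shape = cache[i]
            B, C, H, W = r_shape
            # un-pool: spread the gradient of each 2x2 mean over its window
            dr = np.repeat(np.repeat(da, 2, axis=2), 2, axis=3) / 4.0
            dz = dr * (z > 0)
            kh = self.kernels[i].shape[2]
            pad = kh // 2
            xp = np.pad(a_in, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kh), axis=(2, 3))
            grads_k[i] = np.einsum("bchwij,bohw->ocij", windows, dz, optimize=True)
            grads_b[i] = dz.sum(axis=(0, 2, 3))
            if i > 0:
                flipped = self.kernels[i][:, :, ::-1, ::-1]
                da = _conv2d(dz, flipped.transpose(1, 0, 2, 3))
        return grads_k + grads_b + [d_head_w, d_head_b]


def expand_input_channels(kernel: np.ndarray, target_channels: int = 5) -> np.ndarray:
    """Widen a 3-input-channel conv kernel stack to ``target_channels`` inputs.

    The extra input channels are copies of channels 1 and 2 in alternation
    (1, 2, 1, 2, ...); the first three channels are untouched.  This is the
    standard trick for feeding 5-channel stains to an RGB-pretrained filter
    bank.
    """
    kernel = np.asarray(kernel)
    if kernel.ndim != 4 or kernel.shape[1] != 3:
        raise ValueError(f"expected kernel of shape (out, 3, kh, kw), got {kernel.shape}")
    if target_channels < 3:
        raise ValueError(f"target_channels must be >= 3, got {target_channels}")
    extra = [kernel[:, i % 2] for i in range(target_channels - 3)]
    return np.concatenate([kernel] + [e[:, None] for e in extra], axis=1)


def build_model(config: ModelConfig, input_spec, n_assays: int):
    """Instantiate an untrained network for the given modality.

    ``input_spec`` is the input dimensionality for MLP modalities or a
    ``(channels, height, width)`` tuple for images.  Initialisation is
    deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, 11]))
    if config.modality in ("features", "structure"):
        return MLP(int(input_spec), n_assays, config.hidden_layers, config.hidden_width, rng)
    if config.modality == "image":
        c, h, w = input_spec
        if h != w:
            raise ValueError("image inputs must be square")
        return CNN(c, h, n_assays, config.conv_channels, rng)
    raise ValueError(f"unknown modality {config.modality!r}")


# ---------------------------------------------------------------------------
# optimisers


class _SGD:
    def __init__(self, params, lr, weight_decay):
        self.lr = lr
        self.wd = weight_decay

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * (g + self.wd * p)


class _Adam:
    def __init__(self, params, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training / prediction


@dataclass
class PredictionMatrix:
    """Per-compound, per-assay activity scores in [0, 1] for one CV split."""

    compounds: list[str]
    scores: np.ndarray
    split_id: int = -1


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auc: float = float("nan")
    train_groups: set = field(default_factory=set)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)


def _mean_val_auc(model, val_x, val_y, val_groups) -> float:
    from .evaluate import roc_auc

    pm = predict(model, val_x, groups=val_groups)
    # per-compound labels: first replicate row of each compound
    _, first_idx = np.unique(np.asarray(val_groups), return_index=True)
    order = np.sort(first_idx)
    y = np.asarray(val_y, dtype=float)[order]
    aucs = [roc_auc(pm.scores[:, j], y[:, j]) for j in range(y.shape[1])]
    aucs = [a for a in aucs if not np.isnan(a)]
    return float(np.mean(aucs)) if aucs else float("nan")


def train(model, train_x, train_y, val_x, val_y, config: ModelConfig,
          train_groups=None, val_groups=None):
    """Fit ``model`` by minimising the masked focal BCE.

    ``train_x``/``val_x`` are replicate-level input rows; ``train_y``/``val_y``
    the matching ternary label rows (NaN = unknown).  ``*_groups`` name the
    compound of each row so validation scores are aggregated per compound
    before scoring; they default to one compound per row.

    After each epoch the mean per-assay validation ROC-AUC is computed and the
    best checkpoint kept.  When validation AUC fails to improve for
    ``config.patience`` epochs the learning rate is divided by 10; after two
    reductions without improvement training stops.  Returns ``(model,
    history)`` with the best checkpoint restored.
    """
    train_x = np.asarray(train_x, dtype=float)
    train_y = np.asarray(train_y, dtype=float)
    if train_x.shape[0] == 0:
        raise ValueError("empty training set")
    if train_groups is None:
        train_groups = [f"row{i}" for i in range(train_x.shape[0])]
    if val_groups is None:
        val_groups = [f"row{i}" for i in range(np.asarray(val_x).shape[0])]

    history = TrainingHistory(train_groups=set(map(str, train_groups)))
    if config.max_epochs == 0:
        return model, history

    # prior-probability output bias: start scores near the observed base rate
    base = np.nanmean(train_y, axis=0)
    base = np.clip(np.nan_to_num(base, nan=0.5), 1e-4, 1 - 1e-4)
    model.set_output_bias(np.log(base / (1 - base)))

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, 13]))
    params = model.parameters()
    opt_cls = _SGD if config.optimizer == "sgd" else _Adam
    lr = config.learning_rate
    opt = opt_cls(params, lr, config.weight_decay)

    best_state = model.state_dict()
    best_auc = -np.inf
    stale = 0
    n_reductions = 0
    n = train_x.shape[0]

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, cache = model.forward(train_x[idx])
            loss, dlogits = _loss_grad_logits(logits, train_y[idx], config.gamma, config.loss)
            grads = model.backward(cache, dlogits)
            opt.step(model.parameters(), grads)
            epoch_loss += loss
            n_batches += 1
        val_auc = _mean_val_auc(model, val_x, val_y, val_groups)
        history.epochs.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
             "val_auc": val_auc, "lr": opt.lr}
        )
        if np.isfinite(val_auc) and val_auc > best_auc + 1e-6:
            best_auc = val_auc
            best_state = model.state_dict()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                n_reductions += 1
                if n_reductions > 2:
                    break
                opt.lr *= 0.1
                stale = 0
    model.load_state_dict(best_state)
    history.best_val_auc = best_auc if np.isfinite(best_auc) else float("nan")
    return model, history


def predict(model, inputs, groups=None, split_id: int = -1,
            batch_size: int = 512) -> PredictionMatrix:
    """Score inputs and average replicate rows per compound.

    ``groups`` names the compound of each input row; rows sharing a name are
    averaged with :func:`~phenoscreen.preprocess.aggregate_replicates`.
    Compounds appear in order of first occurrence.
    """
    inputs = np.asarray(inputs, dtype=float)
    expected = model.in_channels if isinstance(model, CNN) else model.weights[0].shape[0]
    got = inputs.shape[1] if inputs.ndim > 1 else None
    if got != expected:
        raise ValueError(f"input dimension mismatch: model expects {expected}, got {got}")
    scores = np.concatenate(
        [model.predict_proba(inputs[i:i + batch_size]) for i in range(0, len(inputs), batch_size)]
    ) if len(inputs) else np.zeros((0, model.n_outputs))
    if groups is None:
        groups = [f"row{i}" for i in range(len(inputs))]
    groups = np.asarray([str(g) for g in groups])
    uniq, first = np.unique(groups, return_index=True)
    order = uniq[np.argsort(first)]
    agg = np.stack([aggregate_replicates(scores[groups == g]) for g in order]) if len(order) else (
        np.zeros((0, model.n_outputs)))
    return PredictionMatrix(compounds=list(order), scores=agg, split_id=split_id)
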