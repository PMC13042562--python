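"""Patch-level prognosis scoring: labels, training schedule, backbone, Grad-CAM.

Patients are labeled by recurrence-free survival (recurrence within 12 months
= poor prognosis; recurrence-free beyond 36 months = good; otherwise
intermediate and excluded from classifier training), every tile inherits its
patient's label, and a pluggable backbone is trained with softmax
cross-entropy under a cosine-decay learning-rate schedule with early stopping
on validation loss. Trained scorers emit two-decimal patch probabilities and
binary labels, the raw material of the downstream multi-instance aggregation,
plus gradient-weighted class-activation (risk-activation) heatmaps.

The reference backbone is a deliberately small convolutional net written in
NumPy (one convolution, global average pooling, a linear head) that trains on
a CPU in seconds and exposes the activation/gradient access Grad-CAM needs.
Any scorer following the same contract (``predict_proba`` plus
``activations_and_gradients``) can be plugged in instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize
from sklearn.metrics import roc_auc_score

from .fixtures import PatchPrediction, PatientBag, SurvivalOutcome
from .preprocess import Tile, zscore_tile

__all__ = [
    "PrognosisLabel",
    "CosineSchedule",
    "TrainConfig",
    "TinyConvNet",
    "assign_prognosis_label",
    "cosine_lr",
    "train_patch_classifier",
    "score_patches",
    "wsi_level_score",
    "auc_with_ci",
    "grad_cam",
]

POOR, GOOD, INTERMEDIATE = "poor", "good", "intermediate"
PrognosisLabel = str

# Printed per-architecture training configurations (reference values):
# conventional CNNs: initial lr 0.01, 8 epochs;
# transformer-style: initial lr 0.001, 16 epochs, early-stop patience 128.
CNN_TRAIN_CONFIG = {"initial_lr": 0.01, "epochs": 8}
TRANSFORMER_TRAIN_CONFIG = {"initial_lr": 0.001, "epochs": 16, "early_stop_patience": 128}


def assign_prognosis_label(rfs: SurvivalOutcome) -> PrognosisLabel:
    """Label a patient by recurrence-free survival.

    Recurrence (event) within 12 months -> poor; recurrence-free for more
    than 36 months (event or censoring after 36) -> good; anything in between
    -> intermediate. All of a patient's patches inherit this label.
    """
    if rfs.event == 1 and rfs.time <= 12.0:
        return POOR
    if rfs.time > 36.0:
        return GOOD
    return INTERMEDIATE


# ---------------------------------------------------------------------------
# cosine-decay learning-rate schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CosineSchedule:
    """eta_t = eta_min + (eta_max - eta_min)/2 * (1 + cos(pi * T_cur / T_i))."""

    eta_min: float = 0.0
    eta_max: float = 0.01
    T_i: int = 16

    def __post_init__(self) -> None:
        if not (self.eta_max > self.eta_min >= 0):
            raise ValueError("require eta_max > eta_min >= 0")
        if self.T_i <= 0:
            raise ValueError("T_i must be positive")


def cosine_lr(T_cur: float, s: CosineSchedule) -> float:
    """Closed-form cosine decay rate at epoch ``T_cur`` of ``s.T_i``."""
    if not 0 <= T_cur <= s.T_i:
        raise ValueError(f"T_cur must lie in [0, {s.T_i}], got {T_cur}")
    return s.eta_min + 0.5 * (s.eta_max - s.eta_min) * (1.0 + math.cos(math.pi * T_cur / s.T_i))


# ---------------------------------------------------------------------------
# reference backbone: a tiny NumPy CNN with Grad-CAM access
# ---------------------------------------------------------------------------

def _as_pixels(tile) -> np.ndarray:
    return tile.pixels if isinstance(tile, Tile) else np.asarray(tile)


class TinyConvNet:
    """One conv layer + ReLU + global average pooling + linear softmax head.

    Inputs are downsampled to ``input_size`` and per-tile Z-scored. The final
    (only) convolutional feature map and the gradient of a class logit with
    respect to it are exposed for Grad-CAM.
    """

    def __init__(
        self,
        n_filters: int = 8,
        kernel: int = 5,
        stride: int = 2,
        input_size: int = 32,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.kernel, self.stride, self.input_size = kernel, stride, input_size
        d = kernel * kernel * 3
        self.W1 = rng.normal(0.0, math.sqrt(2.0 / d), size=(d, n_filters))
        self.b1 = np.zeros(n_filters)
        self.W2 = np.zeros((n_filters, 2))  # zero head: class orientation is learned, not inherited from init
        self.b2 = np.zeros(2)

    # -- input pipeline ----------------------------------------------------
    def _prep(self, tiles: Sequence) -> np.ndarray:
        out = []
        for t in tiles:
            px = _as_pixels(t).astype(float)
            if px.shape[0] != self.input_size:
                px = resize(px, (self.input_size, self.input_size, 3), order=1,
                            anti_aliasing=px.shape[0] > self.input_size)
            out.append(zscore_tile(px))
        return np.stack(out)

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, int]:
        b, h = x.shape[0], x.shape[1]
        k, s = self.kernel, self.stride
        n_out = (h - k) // s + 1
        cols = np.empty((b, n_out * n_out, k * k * 3))
        idx = 0
        for i in range(n_out):
            for j in range(n_out):
                patch = x[:, i * s : i * s + k, j * s : j * s + k, :]
                cols[:, idx] = patch.reshape(b, -1)
                idx += 1
        return cols, n_out

    def _forward(self, x: np.ndarray):
        cols, n_out = self._im2col(x)                     # (B, P, D)
        pre = cols @ self.W1 + self.b1                    # (B, P, F)
        act = np.maximum(pre, 0.0)
        feat = act.mean(axis=1)                           # (B, F) global average pool
        logits = feat @ self.W2 + self.b2
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        return cols, act, feat, logits, probs, n_out

    # -- public scorer contract --------------------------------------------
    def predict_proba(self, tiles: Sequence) -> np.ndarray:
        if len(tiles) == 0:
            return np.zeros((0, 2))
        return self._forward(self._prep(tiles))[4]

    def activations_and_gradients(self, tile, target_class: int):
        """Final conv feature map A (h, w, F) and dlogit_c/dA of equal shape."""
        x = self._prep([tile])
        _, act, _, _, _, n_out = self._forward(x)
        a = act[0].reshape(n_out, n_out, -1)
        # logit_c = sum_k W2[k, c] * mean_{ij} A[i, j, k] + b2[c]
        grad = np.broadcast_to(self.W2[:, target_class] / (n_out * n_out), a.shape).copy()
        return a, grad

    # -- training ----------------------------------------------------------
    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        cols, act, feat, _, probs, _ = self._forward(x)
        b = x.shape[0]
        loss = -np.log(np.clip(probs[np.arange(b), y], 1e-12, None)).mean()
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b
        gW2 = feat.T @ dlogits
        gb2 = dlogits.sum(axis=0)
        dfeat = dlogits @ self.W2.T                       # (B, F)
        dact = dfeat[:, None, :] / act.shape[1]           # (B, P, F)
        dpre = dact * (act > 0)
        gW1 = np.einsum("bpd,bpf->df", cols, dpre)
        gb1 = dpre.sum(axis=(0, 1))
        return loss, (gW1, gb1, gW2, gb2)

    def sgd_step(self, grads, lr: float) -> None:
        for p, g in zip((self.W1, self.b1, self.W2, self.b2), grads):
            p -= lr * g

    def eval_loss(self, x: np.ndarray, y: np.ndarray) -> float:
        probs = self._forward(x)[4]
        return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())

    # -- (de)serialization for the CLI model artifact ----------------------
    def to_dict(self) -> dict:
        return {
            "kind": "tiny_conv_net",
            "kernel": self.kernel,
            "stride": self.stride,
            "input_size": self.input_size,
            "weights": {k: getattr(self, k).tolist() for k in ("W1", "b1", "W2", "b2")},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TinyConvNet":
        net = cls(kernel=d["kernel"], stride=d["stride"], input_size=d["input_size"])
        for k, v in d["weights"].items():
            setattr(net, k, np.asarray(v, dtype=float))
        return net


@dataclass
class TrainConfig:
    initial_lr: float = 0.01
    epochs: int = 8
    early_stop_patience: int = 128
    loss: str = "softmax_cross_entropy"
    batch_size: int = 16
    val_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stop_patience <= 0:
            raise ValueError("early_stop_patience must be positive")
        if self.loss != "softmax_cross_entropy":
            raise ValueError("only softmax cross-entropy loss is supported")


@dataclass
class TrainResult:
    scorer: object
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None


def train_patch_classifier(
    tiles: Sequence,
    labels: Sequence[int],
    cfg: TrainConfig | None = None,
    backbone: TinyConvNet | None = None,
    val_loss_fn: Callable[[object, int], float] | None = None,
) -> TrainResult:
    """Train a patch classifier with cosine LR decay and early stopping.

    A stratified validation split is held out; after each epoch the
    validation loss is evaluated and training halts once it has failed to
    improve for ``early_stop_patience`` consecutive evaluations. Deterministic
    under ``cfg.seed``.

    ``val_loss_fn(scorer, epoch)``, when given, replaces the internal
    validation-loss computation (used to test the early-stopping contract).
    """
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires tiles from both classes")
    net = backbone if backbone is not None else TinyConvNet(seed=cfg.seed)

    rng = np.random.default_rng(cfg.seed)
    x = net._prep(tiles)
    idx0, idx1 = np.flatnonzero(labels == 0), np.flatnonzero(labels == 1)
    rng.shuffle(idx0), rng.shuffle(idx1)
    n_val0 = max(1, int(round(cfg.val_fraction * len(idx0))))
    n_val1 = max(1, int(round(cfg.val_fraction * len(idx1))))
    val_idx = np.concatenate([idx0[:n_val0], idx1[:n_val1]])
    tr_idx = np.concatenate([idx0[n_val0:], idx1[n_val1:]])
    xtr, ytr, xva, yva = x[tr_idx], labels[tr_idx], x[val_idx], labels[val_idx]

    schedule = CosineSchedule(0.0, cfg.initial_lr, cfg.epochs)
    result = TrainResult(scorer=net)
    best, since_best = math.inf, 0
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, schedule)
        order = rng.permutation(len(xtr))
        ep_loss = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            loss, grads = net.loss_and_grads(xtr[batch], ytr[batch])
            net.sgd_step(grads, lr)
            ep_loss.append(loss)
        result.train_loss.append(float(np.mean(ep_loss)))
        vloss = val_loss_fn(net, epoch) if val_loss_fn else net.eval_loss(xva, yva)
        result.val_loss.append(float(vloss))
        if vloss < best - 1e-12:
            best, since_best = vloss, 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                result.stopped_epoch = epoch + 1
                break
    return result


# ---------------------------------------------------------------------------
# scoring, aggregation to WSI level, discrimination
# ---------------------------------------------------------------------------

def score_patches(scorer, tiles: Sequence, patient_id: str = "unknown") -> list[PatchPrediction]:
    """Score tiles; probabilities rounded half-even to two decimals, pred = [prob > 0.5]."""
    if len(tiles) == 0:
        return []
    probs = np.asarray(scorer.predict_proba(tiles))[:, 1]
    out = []
    for t, p in zip(tiles, probs):
        slide = t.slide_id if isinstance(t, Tile) else f"{patient_id}_S1"
        p2 = float(np.round(p, 2))
        out.append(PatchPrediction(patient_id, slide, p2, int(p2 > 0.5)))
    return out


def wsi_level_score(bag: PatientBag, method: str = "mean") -> float:
    """Aggregate a patient's patch probabilities to one slide-level probability."""
    probs = bag.probs
    if method == "mean":
        return float(probs.mean())
    if method == "median":
        return float(np.median(probs))
    if method == "majority":
        return float(bag.preds.mean() > 0.5)
    raise ValueError(f"unknown aggregation method {method!r}")


def auc_with_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Rank-statistic AUC with a percentile bootstrap 95% CI over patients.

    Ties in score count one half; bootstrap resamples with only one class
    present are redrawn implicitly by being skipped.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    auc = float(roc_auc_score(labels, scores))
    rng = np.random.default_rng(seed)
    boots = []
    while len(boots) < n_boot:
        idx = rng.integers(0, len(scores), size=len(scores))
        if labels[idx].min() == labels[idx].max():
            continue
        boots.append(roc_auc_score(labels[idx], scores[idx]))
    lo, hi = np.percentile(boots, (2.5, 97.5))
    return auc, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Grad-CAM / risk-activation mapping
# ---------------------------------------------------------------------------

def grad_cam(scorer, tile, target_class: int = 1) -> np.ndarray:
    """Gradient-weighted class-activation heatmap at tile resolution.

    Channel weights are the spatial means of the target-class logit gradient
    over the final convolutional feature map; the ReLU of the weighted sum is
    upsampled bilinearly to tile size and min-max scaled to [0, 1]. A map that
    is all zero before normalization is returned as zeros.
    """
    if not hasattr(scorer, "activations_and_gradients"):
        raise TypeError("scorer does not expose activation/gradient access required for Grad-CAM")
    a, g = scorer.activations_and_gradients(tile, target_class)
    alpha = g.mean(axis=(0, 1))
    cam = np.maximum((a * alpha).sum(axis=2), 0.0)
    px = _as_pixels(tile)
    cam = resize(cam, px.shape[:2], order=1, anti_aliasing=False)
    if cam.max() <= 0:
        return np.zeros(px.shape[:2])
    span = cam.max() - cam.min()
    if span == 0:  # uniformly positive activation
        return np.ones(px.shape[:2])
    return (cam - cam.min()) / span
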