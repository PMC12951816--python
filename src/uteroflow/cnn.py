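"""Grouped cross-validated training of per-image success scorers.

Combined motion images are scored by classifiers trained under a grouped
6-fold cross-validation scheme repeated 12 times for each of the four ROI
image types — a full grid of 6 x 12 x 4 = 288 model slots.  All images of
a patient share that patient's fold, so no model ever scores a patient it
trained on.  Training images are augmented 40-fold (small rotations,
translations, horizontal flips, mild intensity jitter) and each of the 20
epochs randomly samples one-twentieth of the augmented pool.

Two scorer backbones are provided behind one contract (image -> success
probability):

* ``small_cnn`` — a compact convolutional network written on numpy
  (3 conv blocks, global average pooling, sigmoid head, Adam), sized for
  CPU-scale experiments;
* ``motion_energy`` — a logistic model on the per-image mean absolute
  deviation from neutral gray, fitted on a per-repetition bootstrap of the
  training images; a fast deterministic reference scorer.

A ``mobilenet_v2`` backbone slot exists in the config contract but
requires a deep-learning framework and raises if requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, warp

from .encoding import NEUTRAL_GRAY

IMAGE_TYPES = ("O", "R", "C", "P")
GRID_FOLDS = 6
GRID_REPETITIONS = 12


@dataclass(frozen=True)
class ModelSlot:
    fold: int
    repetition: int
    image_type: str

    def __post_init__(self) -> None:
        if self.image_type not in IMAGE_TYPES:
            raise ValueError(f"unknown image type {self.image_type!r}")
        if self.fold < 1 or self.repetition < 1:
            raise ValueError("fold and repetition are 1-based")


def full_grid(
    folds: int = GRID_FOLDS,
    repetitions: int = GRID_REPETITIONS,
    image_types: Sequence[str] = IMAGE_TYPES,
) -> list[ModelSlot]:
    """Enumerate all slots; the full protocol has 6 x 12 x 4 = 288."""
    return [
        ModelSlot(fold=f, repetition=r, image_type=t)
        for t in image_types
        for r in range(1, repetitions + 1)
        for f in range(1, folds + 1)
    ]


@dataclass
class TrainConfig:
    backbone: str = "small_cnn"
    input_size: tuple[int, int] = (224, 224)
    epochs: int = 20
    augmentation_factor: int = 40
    per_epoch_fraction: float = 1.0 / 20.0
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.augmentation_factor < 1:
            raise ValueError("augmentation_factor must be >= 1")
        if not (0.0 < self.per_epoch_fraction <= 1.0):
            raise ValueError("per_epoch_fraction must lie in (0, 1]")
        if self.backbone not in ("small_cnn", "motion_energy", "mobilenet_v2"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class ScoreRecord:
    case_id: str
    window_start: int
    slot: ModelSlot
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    def as_row(self) -> dict:
        return {
            "case_id": self.case_id,
            "window_start": self.window_start,
            "image_type": self.slot.image_type,
            "fold": self.slot.fold,
            "repetition": self.slot.repetition,
            "score": self.score,
        }


# ---------------------------------------------------------------------------
# Fold assignment
# ---------------------------------------------------------------------------

def assign_folds(
    case_ids: Sequence[str], k: int = GRID_FOLDS, seed: int = 0
) -> dict[str, int]:
    """Grouped fold map: every case (and hence all its images) in exactly
    one of k folds, sizes differing by at most 1."""
    case_ids = sorted(set(case_ids))
    if k > len(case_ids):
        raise ValueError(f"cannot split {len(case_ids)} cases into {k} folds")
    order = np.array(case_ids, dtype=object)
    np.random.default_rng(seed).shuffle(order)
    folds: dict[str, int] = {}
    for fold_idx, chunk in enumerate(np.array_split(order, k), start=1):
        for cid in chunk:
            folds[str(cid)] = fold_idx
    return folds


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _augment_one(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random transform: rotation +/-10 deg, translation +/-5%,
    horizontal flip, gain [0.9, 1.1] and offset +/-8 gray levels."""
    h, w = image.shape[:2]
    angle = np.deg2rad(rng.uniform(-10.0, 10.0))
    tx = rng.uniform(-0.05, 0.05) * w
    ty = rng.uniform(-0.05, 0.05) * h
    # rotate about the image center
    center = np.array([w / 2.0, h / 2.0])
    shift = AffineTransform(translation=-center)
    rot = AffineTransform(rotation=angle, translation=(tx, ty))
    unshift = AffineTransform(translation=center)
    out = warp(
        image,
        (shift + rot + unshift).inverse,
        order=1,
        mode="edge",
        preserve_range=True,
    )
    if rng.random() < 0.5:
        out = out[:, ::-1]
    gain = rng.uniform(0.9, 1.1)
    offset = rng.uniform(-8.0, 8.0)
    out = (out - NEUTRAL_GRAY) * gain + NEUTRAL_GRAY + offset
    return np.clip(out, 0.0, 255.0)


def augment(
    images: Sequence[np.ndarray] | np.ndarray,
    factor: int = 40,
    seed: int = 0,
    labels: Sequence[int] | None = None,
):
    """Expand each image into ``factor`` replicas (the first is the
    untouched original, the rest are random transforms).  Labels, when
    given, are replicated alongside."""
    images = list(images)
    if not images:
        raise ValueError("cannot augment an empty image set")
    rng = np.random.default_rng(seed)
    out_images, out_labels = [], []
    for idx, img in enumerate(images):
        for rep in range(factor):
            out_images.append(
                np.asarray(img, dtype=np.float64)
                if rep == 0
                else _augment_one(np.asarray(img, dtype=np.float64), rng)
            )
            if labels is not None:
                out_labels.append(labels[idx])
    if labels is not None:
        return out_images, out_labels
    return out_images


# ---------------------------------------------------------------------------
# Small CNN on numpy
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H-k+1, W-k+1, k*k*C) patch matrix (a view)."""
    n, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(n, oh, ow, k, k, c), strides=(s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return patches.reshape(n, oh, ow, k * k * c)


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.W = rng.normal(0.0, scale, size=(k * k * c_in, c_out))
        self.b = np.zeros(c_out)
        self.k = k
        self.c_in = c_in

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._patches = _im2col(np.ascontiguousarray(x), self.k)
        return self._patches @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, oh, ow, c_out = dy.shape
        flat_dy = dy.reshape(-1, c_out)
        self.dW = self._patches.reshape(-1, self.W.shape[0]).T @ flat_dy
        self.db = flat_dy.sum(axis=0)
        dpatch = (flat_dy @ self.W.T).reshape(n, oh, ow, self.k, self.k, self.c_in)
        dx = np.zeros(self._x_shape)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i : i + oh, j : j + ow, :] += dpatch[:, :, :, i, j, :]
        return dx

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool2:
    def forward(self, x):
        n, h, w, c = x.shape
        ph, pw = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, : 2 * ph, : 2 * pw, :].reshape(n, ph, 2, pw, 2, c)
        out = xc.max(axis=(2, 4))
        self._mask = xc == out[:, :, None, :, None, :]
        return out

    def backward(self, dy):
        n, h, w, c = self._in_shape
        ph, pw = h // 2, w // 2
        dxc = self._mask * dy[:, :, None, :, None, :]
        dx = np.zeros(self._in_shape)
        dx[:, : 2 * ph, : 2 * pw, :] = dxc.reshape(n, 2 * ph, 2 * pw, c)
        return dx


class SmallCNN:
    """3 conv blocks + global average pooling + sigmoid head.

    Inputs are (N, H, W, 3) combined images in [0, 255]; internally
    centered on neutral gray ((x - 128) / 64) so a static scene maps to a
    zero tensor.
    """

    def __init__(self, seed: int = 0, channels: tuple[int, int, int] = (8, 16, 32)):
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.conv1, self.relu1, self.pool1 = _Conv(3, c1, 3, rng), _ReLU(), _MaxPool2()
        self.conv2, self.relu2, self.pool2 = _Conv(c1, c2, 3, rng), _ReLU(), _MaxPool2()
        self.conv3, self.relu3 = _Conv(c2, c3, 3, rng), _ReLU()
        self.w_out = rng.normal(0.0, 1.0 / np.sqrt(c3), size=c3)
        self.b_out = 0.0
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- forward / backward ------------------------------------------------
    def _features(self, x: np.ndarray) -> np.ndarray:
        h = self.pool1.forward(self.relu1.forward(self.conv1.forward(x)))
        h = self.pool2.forward(self.relu2.forward(self.conv2.forward(h)))
        h = self.relu3.forward(self.conv3.forward(h))
        self._gap_shape = h.shape
        return h.mean(axis=(1, 2))  # (N, C)

    def forward_logits(self, images: np.ndarray) -> np.ndarray:
        x = (np.asarray(images, dtype=np.float64) - NEUTRAL_GRAY) / 64.0
        feats = self._features(x)
        self._feats = feats
        return feats @ self.w_out + self.b_out

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Success probabilities in [0, 1] for a (N, H, W, 3) batch."""
        return 1.0 / (1.0 + np.exp(-self.forward_logits(images)))

    def train_batch(self, images: np.ndarray, labels: np.ndarray, lr: float) -> float:
        """One Adam step on binary cross-entropy; returns the batch loss."""
        z = self.forward_logits(images)
        p = 1.0 / (1.0 + np.exp(-z))
        y = np.asarray(labels, dtype=np.float64)
        eps = 1e-12
        loss = float(-(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean())
        dz = (p - y) / len(y)
        self.dw_out = self._feats.T @ dz
        self.db_out = dz.sum()
        dfeat = np.outer(dz, self.w_out)
        n, gh, gw, c = self._gap_shape
        dh = np.broadcast_to(
            dfeat[:, None, None, :] / (gh * gw), self._gap_shape
        )
        dh = self.conv3.backward(self.relu3.backward(np.ascontiguousarray(dh)))
        dh = self.conv2.backward(
            self.relu2.backward(self.pool2.backward(dh))
        )
        self.conv1.backward(self.relu1.backward(self.pool1.backward(dh)))
        self._adam_step(lr)
        return loss

    # -- optimizer ---------------------------------------------------------
    def _named_params(self):
        yield self.conv1.W, self.conv1.dW
        yield self.conv1.b, self.conv1.db
        yield self.conv2.W, self.conv2.dW
        yield self.conv2.b, self.conv2.db
        yield self.conv3.W, self.conv3.dW
        yield self.conv3.b, self.conv3.db
        yield self.w_out, self.dw_out
        # scalar bias handled separately

    def _adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for i, (param, grad) in enumerate(self._named_params()):
            m, v = self._adam_state.get(
                i, (np.zeros_like(param), np.zeros_like(param))
            )
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            self._adam_state[i] = (m, v)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            param -= lr * mhat / (np.sqrt(vhat) + eps)
        mb, vb = self._adam_state.get(-1, (0.0, 0.0))
        mb = beta1 * mb + (1 - beta1) * self.db_out
        vb = beta2 * vb + (1 - beta2) * self.db_out**2
        self._adam_state[-1] = (mb, vb)
        self.b_out -= lr * (mb / (1 - beta1**t)) / (
            np.sqrt(vb / (1 - beta2**t)) + 1e-8
        )

    # -- bookkeeping -------------------------------------------------------
    def parameter_counts(self) -> dict[str, int]:
        """Total and trainable parameter counts (identical here: every
        parameter is trainable)."""
        n = sum(
            p.size
            for p in (
                self.conv1.W, self.conv1.b, self.conv2.W, self.conv2.b,
                self.conv3.W, self.conv3.b, self.w_out,
            )
        ) + 1
        return {"total": int(n), "trainable": int(n)}


class MotionEnergyScorer:
    """Logistic scorer on the per-image mean |value - 128| statistic."""

    def __init__(self):
        from sklearn.linear_model import LogisticRegression

        self._model = LogisticRegression()

    @staticmethod
    def _feature(images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        return np.abs(x - NEUTRAL_GRAY).mean(axis=(1, 2, 3))[:, None]

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "MotionEnergyScorer":
        self._model.fit(self._feature(images), np.asarray(labels, dtype=int))
        return self

    def predict(self, images: np.ndarray) -> np.ndarray:
        proba = self._model.predict_proba(self._feature(images))
        return proba[:, list(self._model.classes_).index(1)]


# ---------------------------------------------------------------------------
# Slot training and scoring
# ---------------------------------------------------------------------------

def _slot_seed(config: TrainConfig, slot: ModelSlot) -> list[int]:
    return [config.seed, IMAGE_TYPES.index(slot.image_type), slot.fold, slot.repetition]


def train_slot(
    slot: ModelSlot,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    config: TrainConfig,
):
    """Train one slot's scorer on its training-fold combined images.

    The augmented pool of size ``n x augmentation_factor`` is materialized
    lazily: each epoch draws ``per_epoch_fraction`` of pool indices without
    replacement, and index ``i`` deterministically maps to source image
    ``i // factor`` under replica ``i % factor`` (replica 0 is the
    untouched image).  All randomness derives from the slot seed, so
    repetitions differ only in their stochastic draws.
    """
    train_images = np.asarray(train_images, dtype=np.float64)
    train_labels = np.asarray(train_labels, dtype=int)
    if len(train_images) == 0:
        raise ValueError(f"slot {slot}: empty training set")
    if len(train_images) != len(train_labels):
        raise ValueError("images/labels length mismatch")
    rng = np.random.default_rng(_slot_seed(config, slot))

    if config.backbone == "mobilenet_v2":
        raise RuntimeError(
            "the mobilenet_v2 backbone requires a deep-learning framework "
            "(torch/tensorflow), which is not installed; use small_cnn"
        )
    if config.backbone == "motion_energy":
        idx = rng.integers(0, len(train_images), size=len(train_images))
        if len(set(train_labels[idx])) < 2:  # bootstrap must keep both classes
            idx = np.arange(len(train_images))
        return MotionEnergyScorer().fit(train_images[idx], train_labels[idx])

    net = SmallCNN(seed=int(rng.integers(0, 2**31)))
    factor = config.augmentation_factor
    pool_size = len(train_images) * factor
    per_epoch = max(1, int(round(pool_size * config.per_epoch_fraction)))
    for _ in range(config.epochs):
        chosen = rng.choice(pool_size, size=min(per_epoch, pool_size), replace=False)
        batch_imgs = np.empty((len(chosen),) + train_images.shape[1:])
        batch_labels = train_labels[chosen // factor]
        for row, pool_idx in enumerate(chosen):
            src, replica = divmod(int(pool_idx), factor)
            if replica == 0:
                batch_imgs[row] = train_images[src]
            else:
                replica_rng = np.random.default_rng(
                    _slot_seed(config, slot) + [int(pool_idx)]
                )
                batch_imgs[row] = _augment_one(train_images[src], replica_rng)
        order = rng.permutation(len(chosen))
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            net.train_batch(batch_imgs[sel], batch_labels[sel], config.learning_rate)
    return net


def score_images(scorer, images: np.ndarray) -> np.ndarray:
    """Deterministic inference: one success probability per image."""
    images = np.asarray(images, dtype=np.float64)
    scores = scorer.predict(images)
    if len(scores) != len(images):
        raise RuntimeError("scorer returned a wrong-sized score vector")
    return np.clip(scores, 0.0, 1.0)


def score_grid(
    case_images: Mapping[str, np.ndarray],
    truth_map: Mapping[str, int],
    image_type: str,
    config: TrainConfig,
    folds: int = GRID_FOLDS,
    repetitions: int = GRID_REPETITIONS,
    fold_map: Mapping[str, int] | None = None,
    fold_seed: int | None = None,
) -> pd.DataFrame:
    """Run the grouped CV grid for one image type and collect all scores.

    ``case_images`` maps case_id -> (K, H, W, 3) combined-image stack.
    Returns the tidy score table (one row per image per repetition); every
    image is scored by the model of the fold holding out its case.
    """
    case_ids = sorted(case_images)
    if fold_map is None:
        fold_map = assign_folds(
            case_ids, k=folds, seed=config.seed if fold_seed is None else fold_seed
        )
    rows: list[dict] = []
    for rep in range(1, repetitions + 1):
        for fold in range(1, folds + 1):
            slot = ModelSlot(fold=fold, repetition=rep, image_type=image_type)
            train_ids = [c for c in case_ids if fold_map[c] != fold]
            eval_ids = [c for c in case_ids if fold_map[c] == fold]
            if not train_ids or not eval_ids:
                raise ValueError(f"fold {fold} leaves an empty partition")
            train_images = np.concatenate([case_images[c] for c in train_ids])
            train_labels = np.concatenate(
                [
                    np.full(len(case_images[c]), truth_map[c], dtype=int)
                    for c in train_ids
                ]
            )
            scorer = train_slot(slot, train_images, train_labels, config)
            for cid in eval_ids:
                assert cid not in train_ids  # patient-level leakage guard
                scores = score_images(scorer, case_images[cid])
                for w, s in enumerate(scores):
                    rows.append(
                        ScoreRecord(
                            case_id=cid, window_start=w, slot=slot, score=float(s)
                        ).as_row()
                    )
    return pd.DataFrame(rows)
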