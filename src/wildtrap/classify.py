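"""Classifier backends and ensemble voting.

The pipeline is backend-agnostic: anything satisfying the
:class:`ClassifierBackend` contract (an ordered label list fixed at fit
time and ``predict_proba`` returning per-class probability vectors) can
be trained and evaluated.  Two kinds of backends exist:

* :class:`SoftmaxPixelClassifier` — the built-in desk-scale reference:
  multinomial logistic regression on 16×16 grayscale-downsampled
  pixels, trained by Adam on minibatches drawn from the rebalanced,
  augmented training stream.  It trains in well under a second, is
  bit-deterministic per seed, and is sensitive to both sprite shape and
  background statistics — enough to exercise every pipeline stage,
  including the domain-shift effect of unseen backgrounds.
* entries in the backend registry for GPU-scale convolutional networks
  (DenseNet201, Inception-ResNet-V2, InceptionV3, NASNetMobile,
  MobileNetV2, Xception).  These are deliberately not implemented here;
  registering a factory that wraps an external deep-learning stack
  plugs them into the identical protocol.

Ensembling is by hard plurality over each model's top-1 label, ties
broken by the highest mean predicted probability among the tied labels;
soft (summed-probability) voting is available as an option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .augment import AugmentationConfig, augment
from .catalog import Catalog, ImageRecord
from .sampling import ClassRatioTable, SamplerConfig, compute_class_ratios, rebalanced_stream

__all__ = [
    "ClassifierBackend",
    "TrainConfig",
    "EnsembleResult",
    "SoftmaxPixelClassifier",
    "fit",
    "predict_top1",
    "ensemble_vote",
    "ensemble_predict",
    "register_backend",
    "make_backend",
    "available_backends",
]


@runtime_checkable
class ClassifierBackend(Protocol):
    """Contract every backend satisfies: after ``fit``, ``class_labels``
    is an ordered tuple and ``predict_proba(images)`` returns one
    probability vector per input, non-negative, summing to 1 (±1e-6),
    ordered by ``class_labels``."""

    name: str

    @property
    def class_labels(self) -> tuple[str, ...]: ...

    def fit_arrays(self, images: Sequence[np.ndarray], labels: Sequence[str],
                   train_config: "TrainConfig") -> "ClassifierBackend": ...

    def predict_proba(self, images: Sequence[np.ndarray]) -> np.ndarray: ...


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop settings shared by all backends.

    ``epochs`` counts passes over the nominal training-set size (the
    stream itself is endless); the heavyweight CNN backends of the
    original study used Adam for 500 epochs — the reference backend's
    desk-scale default is far smaller.
    """

    sampler: SamplerConfig = SamplerConfig()
    augmentation: AugmentationConfig = AugmentationConfig.none()
    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class EnsembleResult:
    """Outcome of one ensemble vote over a single image."""

    per_model_top1: Mapping[str, str]
    vote_counts: Mapping[str, int]
    winner: str
    tie_broken: bool


# ---------------------------------------------------------------------------
# Reference backend
# ---------------------------------------------------------------------------

def _gray16(images: Sequence[np.ndarray]) -> np.ndarray:
    """Feature map: grayscale, block-mean downsample to 16×16, flatten,
    subtract the per-image mean (cheap illumination invariance — night
    frames would otherwise swamp the shape signal)."""
    feats = []
    for img in images:
        arr = np.asarray(img, dtype=float)
        if arr.ndim == 3:
            arr = arr @ np.array([0.299, 0.587, 0.114])
        h, w = arr.shape
        bh, bw = h // 16, w // 16
        if bh < 1 or bw < 1:
            raise ValueError("images must be at least 16x16")
        arr = arr[: bh * 16, : bw * 16].reshape(16, bh, 16, bw).mean(axis=(1, 3))
        feats.append(arr.ravel() / 255.0)
    X = np.asarray(feats)
    return X - X.mean(axis=1, keepdims=True)


class SoftmaxPixelClassifier:
    """Multinomial logistic regression on 16×16 grayscale pixels,
    trained with Adam on minibatches from the rebalanced stream.

    Deterministic per ``TrainConfig.seed``: two fits with identical data
    and seed produce bitwise-identical weights.
    """

    def __init__(self, name: str = "pixel-logistic"):
        self.name = name
        self._labels: tuple[str, ...] | None = None
        self.weights: np.ndarray | None = None  # (n_features + 1, K)

    @property
    def class_labels(self) -> tuple[str, ...]:
        if self._labels is None:
            raise RuntimeError("backend is not fitted")
        return self._labels

    @property
    def is_fitted(self) -> bool:
        return self.weights is not None

    def fit_arrays(self, images, labels, train_config: TrainConfig = TrainConfig()):
        labels = list(labels)
        classes = tuple(dict.fromkeys(labels))
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to fit a classifier")
        y_index = {c: k for k, c in enumerate(classes)}

        # in-memory catalog drives the rebalanced training stream
        records = tuple(
            ImageRecord(image_id=str(i), path="", class_label=labels[i], location_id="mem")
            for i in range(len(labels)))
        cat = Catalog(records)
        ratios = compute_class_ratios(
            {c: labels.count(c) for c in classes})
        stream = rebalanced_stream(cat, ratios, train_config.sampler)

        feats_cache: dict[int, np.ndarray] = {}
        aug = train_config.augmentation
        use_aug = any(aug.probability(op) > 0 for op in
                      ("mirror", "channel_shift", "blur", "grayscale", "rotate",
                       "pixel_dropout", "contrast_normalize", "local_affine"))
        rng = np.random.default_rng(train_config.seed)

        n_feat = _gray16([images[0]]).shape[1]
        K = len(classes)
        W = rng.normal(0.0, 0.01, (n_feat + 1, K))
        m = np.zeros_like(W)
        v = np.zeros_like(W)
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = train_config.learning_rate
        n_steps = max(1, train_config.epochs * -(-len(labels) // train_config.batch_size))

        t = 0
        for step in range(n_steps):
            idx = [int(next(stream).image_id) for _ in range(train_config.batch_size)]
            if use_aug:
                batch_imgs = [augment(images[i], aug,
                                      seed=int(rng.integers(2**31))) for i in idx]
                X = _gray16(batch_imgs)
            else:
                for i in idx:
                    if i not in feats_cache:
                        feats_cache[i] = _gray16([images[i]])[0]
                X = np.asarray([feats_cache[i] for i in idx])
            Xb = np.c_[X, np.ones(len(idx))]
            y = np.array([y_index[labels[i]] for i in idx])
            logits = Xb @ W
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(len(y)), y] -= 1.0
            grad = Xb.T @ p / len(y) + 1e-4 * W
            t += 1
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad**2
            W = W - lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)

        self._labels = classes
        self.weights = W
        return self

    def predict_proba(self, images) -> np.ndarray:
        if self.weights is None:
            raise RuntimeError("backend is not fitted")
        X = _gray16(images)
        Xb = np.c_[X, np.ones(len(X))]
        logits = Xb @ self.weights
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    # -- serialization ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        if self.weights is None:
            raise RuntimeError("backend is not fitted")
        payload = {"name": self.name, "labels": list(self._labels),
                   "weights": self.weights.tolist()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SoftmaxPixelClassifier":
        payload = json.loads(Path(path).read_text())
        obj = cls(payload["name"])
        obj._labels = tuple(payload["labels"])
        obj.weights = np.asarray(payload["weights"], dtype=float)
        return obj


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def fit(backend: ClassifierBackend, images: Sequence[np.ndarray],
        labels: Sequence[str], train_config: TrainConfig = TrainConfig()):
    """Fit a backend on aligned ``(images, labels)``; training consumes
    images through the rebalanced stream and the augmentation operators
    configured in ``train_config``."""
    return backend.fit_arrays(images, labels, train_config)


def predict_top1(backend: ClassifierBackend, images: Sequence[np.ndarray]) -> list[str]:
    """Highest-confidence label per image (ties go to the lowest-index
    class in ``class_labels`` order)."""
    probas = backend.predict_proba(images)
    return [backend.class_labels[int(k)] for k in np.argmax(probas, axis=1)]


def ensemble_vote(per_model_probas: Sequence[np.ndarray],
                  class_labels: Sequence[str],
                  model_names: Sequence[str] | None = None,
                  voting: str = "hard") -> EnsembleResult:
    """Combine one image's probability vectors from several models.

    ``hard`` voting: each model casts its top-1 label; plurality wins,
    ties broken by the highest mean predicted probability among the tied
    labels.  ``soft`` voting: labels are ranked by summed probability.
    """
    if len(per_model_probas) < 2:
        raise ValueError("an ensemble needs at least 2 models")
    K = len(class_labels)
    probas = [np.asarray(p, dtype=float) for p in per_model_probas]
    if any(p.shape != (K,) for p in probas):
        raise ValueError("all probability vectors must match the shared label order")
    names = list(model_names) if model_names is not None else [
        f"model_{i}" for i in range(len(probas))]
    top1 = {name: class_labels[int(np.argmax(p))] for name, p in zip(names, probas)}
    mean_p = np.mean(probas, axis=0)

    if voting == "soft":
        winner = class_labels[int(np.argmax(mean_p))]
        votes: dict[str, int] = {}
        for lab in top1.values():
            votes[lab] = votes.get(lab, 0) + 1
        return EnsembleResult(top1, votes, winner, tie_broken=False)
    if voting != "hard":
        raise ValueError("voting must be 'hard' or 'soft'")

    votes = {}
    for lab in top1.values():
        votes[lab] = votes.get(lab, 0) + 1
    best = max(votes.values())
    tied = [lab for lab, n in votes.items() if n == best]
    tie_broken = len(tied) > 1
    winner = max(tied, key=lambda lab: mean_p[list(class_labels).index(lab)])
    return EnsembleResult(top1, votes, winner, tie_broken)


def ensemble_predict(per_model_probas: Sequence[np.ndarray],
                     class_labels: Sequence[str],
                     model_names: Sequence[str] | None = None,
                     voting: str = "hard") -> list[str]:
    """Vectorized ensemble over a batch: ``per_model_probas`` is a list
    of (N, K) arrays, one per model; returns N winning labels."""
    stacked = [np.asarray(p) for p in per_model_probas]
    n = stacked[0].shape[0]
    return [
        ensemble_vote([p[i] for p in stacked], class_labels, model_names, voting).winner
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Backend registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable[[], ClassifierBackend]] = {}


def register_backend(name: str, factory: Callable[[], ClassifierBackend]) -> None:
    _REGISTRY[name] = factory


def make_backend(name: str) -> ClassifierBackend:
    if name not in _REGISTRY:
        raise KeyError(f"unknown backend {name!r}; available: {sorted(_REGISTRY)}")
    return _REGISTRY[name]()


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


def _cnn_placeholder(arch: str) -> Callable[[], ClassifierBackend]:
    def factory() -> ClassifierBackend:
        raise RuntimeError(
            f"backend {arch!r} requires an external deep-learning stack; "
            "register a factory wrapping your own implementation via "
            "register_backend() to use it")
    return factory


register_backend("pixel-logistic", SoftmaxPixelClassifier)
for _arch in ("DenseNet201", "Inception-ResNet-V2", "InceptionV3",
              "NASNetMobile", "MobileNetV2", "Xception"):
    register_backend(_arch, _cnn_placeholder(_arch))
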