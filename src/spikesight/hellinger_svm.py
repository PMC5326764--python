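"""Linear SVM on Hellinger-mapped spatial-pyramid histograms.

The Hellinger kernel between two histograms, K(h, h') = sum_i sqrt(h_i h'_i),
is realized as an explicit feature map: L1-normalize the histogram and take
the elementwise square root, after which the plain inner product of mapped
vectors equals the Hellinger kernel of the originals and the mapped vectors
have unit Euclidean norm. Classification is one-vs-all: one binary linear
SVM per class (+1 inside the class, -1 for the rest), predicting by the
highest decision value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from .spm import SpmVector

__all__ = ["TrainedModel", "EvalReport", "hellinger_map", "train", "predict", "evaluate"]


@dataclass
class TrainedModel:
    """Per-class linear weights and biases on Hellinger-mapped inputs."""

    classes: list
    weights: np.ndarray  # (n_classes, d)
    biases: np.ndarray  # (n_classes,)
    C: float
    seed: int
    normalization: str = "l1-sqrt"
    loss: str = "squared_hinge"
    codebook_hash: str | None = None

    @property
    def dim(self) -> int:
        return self.weights.shape[1]


@dataclass
class EvalReport:
    precision: float | None
    recall: float
    accuracy: float
    confusion: dict
    positive_label: object

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "confusion": {f"{t}->{p}": n for (t, p), n in self.confusion.items()},
            "positive_label": self.positive_label,
        }


def _values(h) -> np.ndarray:
    if isinstance(h, SpmVector):
        return h.values
    return np.asarray(h, dtype=np.float64).ravel()


def hellinger_map(h) -> np.ndarray:
    """Explicit Hellinger feature map: L1-normalize then elementwise sqrt.

    Non-degenerate output has unit L2 norm; an all-zero histogram maps to
    the zero vector (such an image is classified by bias alone).
    """
    v = _values(h)
    if np.any(v < 0):
        raise ValueError("Hellinger map requires a non-negative histogram")
    s = v.sum()
    if s <= 0:
        return np.zeros_like(v)
    return np.sqrt(v / s)


def train(samples, labels, C: float = 1.0, seed: int = 0,
          codebook_hash: str | None = None) -> TrainedModel:
    """Fit one-vs-all linear SVMs on Hellinger-mapped sample vectors.

    Uses the liblinear primal solver with squared-hinge loss, which is
    deterministic for fixed inputs; the seed is recorded for provenance.
    """
    X = np.stack([hellinger_map(s) for s in samples])
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    weights = np.zeros((len(classes), X.shape[1]))
    biases = np.zeros(len(classes))
    for i, c in enumerate(classes):
        t = np.where(y == c, 1, -1)
        clf = LinearSVC(C=C, loss="squared_hinge", dual=False, random_state=seed)
        clf.fit(X, t)
        sign = 1.0 if clf.classes_[1] == 1 else -1.0
        weights[i] = sign * clf.coef_.ravel()
        biases[i] = sign * float(clf.intercept_[0])
    return TrainedModel(classes=classes, weights=weights, biases=biases,
                        C=C, seed=seed, codebook_hash=codebook_hash)


def predict(model: TrainedModel, vector):
    """(label, per-class decision scores); argmax, lowest class on ties."""
    x = hellinger_map(vector)
    if x.shape[0] != model.dim:
        raise ValueError(
            f"vector dimension {x.shape[0]} does not match model {model.dim}")
    scores = model.weights @ x + model.biases
    return model.classes[int(np.argmax(scores))], dict(zip(model.classes, scores))


def evaluate(predictions, truth, positive_label=None) -> EvalReport:
    """Retrieval-style precision/recall plus accuracy and confusion counts.

    Precision = retrieved-relevant / retrieved (None when nothing is
    retrieved, not 0); recall = retrieved-relevant / total-relevant. The
    positive ("retrieved") label defaults to 'ear' when present, else the
    first class in sorted order.
    """
    preds = list(predictions)
    gold = list(truth)
    if len(preds) != len(gold):
        raise ValueError("predictions and truth must have equal length")
    labels = sorted(set(gold) | set(preds))
    if positive_label is None:
        positive_label = "ear" if "ear" in labels else labels[0]
    confusion = {}
    for p, t in zip(preds, gold):
        confusion[(t, p)] = confusion.get((t, p), 0) + 1
    retrieved = sum(1 for p in preds if p == positive_label)
    relevant = sum(1 for t in gold if t == positive_label)
    hits = sum(1 for p, t in zip(preds, gold) if p == t == positive_label)
    correct = sum(1 for p, t in zip(preds, gold) if p == t)
    precision = hits / retrieved if retrieved > 0 else None
    recall = hits / relevant if relevant > 0 else 0.0
    return EvalReport(
        precision=precision, recall=recall,
        accuracy=correct / len(gold) if gold else 0.0,
        confusion=confusion, positive_label=positive_label,
    )
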