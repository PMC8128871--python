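"""Multi-class linear SVM on BoVW vectors, trained by SGD.

The classifier is a bank of one-vs-rest linear SVMs minimizing the primal
hinge-loss + L2 objective with a stochastic-gradient-descent solver.  Each
binary problem is fit with :class:`sklearn.linear_model.SGDClassifier` via
``partial_fit`` over explicitly shuffled epochs, which makes training
deterministic under a fixed seed and lets the primal objective be evaluated
at every epoch end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.linear_model import SGDClassifier

from .vocabulary import BoVWVector

logger = logging.getLogger(__name__)


class VectorIntegrityError(ValueError):
    """Input vectors disagree in length or normalization."""


@dataclass(frozen=True)
class SvmHyperParams:
    """Solver settings.

    ``alpha`` is the L2 regularization strength of the primal objective
    ``mean hinge + alpha/2 * ||w||^2``; ``epochs`` is the number of full
    passes; the step size follows sklearn's "optimal" schedule
    ``eta_t = 1 / (alpha * (t0 + t))``, a decaying inverse-in-t schedule.
    ``class_weight="balanced"`` enables inverse-frequency sample weighting
    (off by default).
    """

    alpha: float = 1e-4
    epochs: int = 50
    seed: int = 0
    class_weight: str | None = None


@dataclass(frozen=True)
class LinearSvmModel:
    """One-vs-rest linear SVM: one weight vector and bias per class.

    ``classes`` fixes both the row order of ``weights`` and prediction
    tie-breaking (lowest index wins).
    """

    classes: tuple[str, ...]
    weights: np.ndarray  # (n_classes, vocsize)
    biases: np.ndarray  # (n_classes,)
    hyper: SvmHyperParams
    metadata: dict = field(default_factory=dict)

    @property
    def vocsize(self) -> int:
        return self.weights.shape[1]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.vocsize:
            raise VectorIntegrityError(
                f"vector length {X.shape[1]} != model vocsize {self.vocsize}"
            )
        return X @ self.weights.T + self.biases

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        return np.asarray(self.classes, dtype=object)[np.argmax(scores, axis=1)]


class PredictionResult(NamedTuple):
    label: str
    scores: np.ndarray
    low_confidence: bool


def _as_design_matrix(
    vectors: Sequence[BoVWVector] | np.ndarray,
) -> tuple[np.ndarray, str | None]:
    if isinstance(vectors, np.ndarray):
        return np.atleast_2d(vectors.astype(float)), None
    norms = {v.normalization for v in vectors}
    if len(norms) > 1:
        raise VectorIntegrityError(f"mixed normalization tags: {sorted(norms)}")
    lengths = {len(v.counts) for v in vectors}
    if len(lengths) > 1:
        raise VectorIntegrityError(f"mixed vector lengths: {sorted(lengths)}")
    return np.vstack([v.counts for v in vectors]), norms.pop()


def _objective(
    X: np.ndarray, Y: np.ndarray, W: np.ndarray, b: np.ndarray, alpha: float
) -> float:
    """Summed one-vs-rest primal objective: mean hinge + alpha/2 ||w||^2."""
    margins = Y * (X @ W.T + b)  # Y is (n, K) of +-1
    hinge = np.maximum(0.0, 1.0 - margins).mean(axis=0)
    reg = 0.5 * alpha * np.sum(W**2, axis=1)
    return float(np.sum(hinge + reg))


def train_svm_sgd(
    vectors: Sequence[BoVWVector] | np.ndarray,
    labels: Sequence[str],
    hyper: SvmHyperParams | None = None,
    class_order: Sequence[str] | None = None,
) -> LinearSvmModel:
    """Fit the one-vs-rest linear SVM bank.

    All binary problems see the same per-epoch shuffles, drawn from
    ``hyper.seed``, so identical data and seed reproduce identical weights.
    The per-epoch primal objective is stored in
    ``model.metadata["objective_history"]`` and per-class training support in
    ``metadata["n_per_class"]``.
    """
    hyper = hyper or SvmHyperParams()
    X, norm_tag = _as_design_matrix(vectors)
    y = np.asarray(labels, dtype=object)
    if len(y) != X.shape[0]:
        raise VectorIntegrityError(
            f"{X.shape[0]} vectors but {len(y)} labels"
        )
    classes = tuple(class_order) if class_order is not None else tuple(
        sorted(set(y))
    )
    unknown = set(y) - set(classes)
    if unknown:
        raise ValueError(f"labels outside class order: {sorted(unknown)}")
    if len(set(y)) < 2:
        raise ValueError("training requires at least two classes")

    rng = np.random.default_rng(hyper.seed)
    n = X.shape[0]
    sample_weight = None
    if hyper.class_weight == "balanced":
        freq = {c: np.sum(y == c) for c in classes}
        sample_weight = np.array([n / (len(classes) * freq[c]) for c in y])

    fitters = {
        c: SGDClassifier(
            loss="hinge",
            penalty="l2",
            alpha=hyper.alpha,
            learning_rate="optimal",
            shuffle=False,
            random_state=0,
        )
        for c in classes
    }
    Y = np.stack([np.where(y == c, 1.0, -1.0) for c in classes], axis=1)
    history = []
    from threadpoolctl import threadpool_limits

    # Single-threaded epochs keep float summation order, and therefore the
    # fitted weights, identical across machines.
    with threadpool_limits(limits=1):
        for _epoch in range(hyper.epochs):
            order = rng.permutation(n)
            for k, c in enumerate(classes):
                sw = sample_weight[order] if sample_weight is not None else None
                fitters[c].partial_fit(
                    X[order], Y[order, k], classes=[-1.0, 1.0], sample_weight=sw
                )
            W = np.vstack([fitters[c].coef_[0] for c in classes])
            b = np.array([fitters[c].intercept_[0] for c in classes])
            history.append(_objective(X, Y, W, b, hyper.alpha))

    W = np.vstack([fitters[c].coef_[0] for c in classes])
    b = np.array([fitters[c].intercept_[0] for c in classes])
    n_per_class = {c: int(np.sum(y == c)) for c in classes}
    logger.info(
        "trained %d-class linear SVM on %d vectors; final objective %.4f",
        len(classes),
        n,
        history[-1],
    )
    return LinearSvmModel(
        classes=classes,
        weights=W,
        biases=b,
        hyper=hyper,
        metadata={
            "n_per_class": n_per_class,
            "objective_history": history,
            "normalization": norm_tag,
        },
    )


def predict_label(
    model: LinearSvmModel, vector: BoVWVector | np.ndarray
) -> PredictionResult:
    """Classify one BoVW vector.

    Returns the argmax class of the decision scores (ties -> the earlier
    class in ``model.classes``), the per-class scores in stored class order,
    and a low-confidence flag set for zero-keypoint (all-zero) vectors,
    whose prediction reduces to the argmax of the biases.
    """
    low_confidence = False
    if isinstance(vector, BoVWVector):
        low_confidence = vector.n_keypoints == 0
        vector = vector.counts
    scores = model.decision_scores(vector)[0]
    if low_confidence:
        logger.warning("zero-keypoint vector: prediction driven by biases only")
    return PredictionResult(
        label=model.classes[int(np.argmax(scores))],
        scores=scores,
        low_confidence=low_confidence,
    )
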