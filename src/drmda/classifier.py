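"""Linear SVM scoring of encoded association candidates.

A soft-margin linear SVM is fit on encoded positive versus sampled-negative
pairs; candidates are scored by their signed Euclidean distance to the
separating hyperplane, oriented so training positives score positive on
average.  Rankings are identical to raw decision values since the distance
is a positive rescaling.  An RBF kernel is available behind a flag for
experimentation; it scores by raw decision value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .io import RankedPredictions

__all__ = ["SVMModel", "train_svm", "score_samples", "rank_candidates"]


@dataclass
class SVMModel:
    """Separating hyperplane in encoded space (columns are samples)."""

    w: np.ndarray | None
    b: float
    C: float
    kernel: str = "linear"
    sign: float = 1.0
    estimator: SVC | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kernel == "linear":
            if self.w is None or float(np.linalg.norm(self.w)) == 0.0:
                raise ValueError("degenerate linear model: zero weight vector")


def _identical_sets(pos: np.ndarray, neg: np.ndarray) -> bool:
    if pos.shape != neg.shape:
        return False
    order_p = np.lexsort(pos)
    order_n = np.lexsort(neg)
    return bool(np.allclose(pos[:, order_p], neg[:, order_n]))


def train_svm(
    pos: np.ndarray,
    neg: np.ndarray,
    C: float = 1.0,
    seed: int = 0,
    kernel: str = "linear",
) -> SVMModel:
    """Fit a soft-margin SVM on encoded positives vs negatives.

    ``pos`` and ``neg`` hold one sample per column.  The returned model is
    oriented so the mean score of the training positives is positive.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    neg = np.atleast_2d(np.asarray(neg, dtype=float))
    if pos.shape[1] == 0 or neg.shape[1] == 0:
        raise ValueError("need at least one positive and one negative sample")
    if pos.shape[0] != neg.shape[0]:
        raise ValueError("positive and negative samples have different dimensionality")
    if _identical_sets(pos, neg):
        raise ValueError("degenerate model: positive and negative sets are identical")
    X = np.hstack([pos, neg]).T
    y = np.concatenate([np.ones(pos.shape[1]), np.zeros(neg.shape[1])])
    svc = SVC(kernel=kernel, C=C, random_state=seed)
    svc.fit(X, y)
    if kernel == "linear":
        w = svc.coef_.ravel().copy()
        b = float(svc.intercept_[0])
        if float(np.mean(w @ pos + b)) < 0.0:
            w, b = -w, -b
        return SVMModel(w=w, b=b, C=C, kernel="linear")
    sign = 1.0 if float(np.mean(svc.decision_function(pos.T))) >= 0.0 else -1.0
    return SVMModel(w=None, b=0.0, C=C, kernel=kernel, sign=sign, estimator=svc)


def score_samples(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Signed distance to the hyperplane for each column of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.kernel == "linear":
        if X.shape[0] != model.w.shape[0]:
            raise ValueError("sample dimensionality does not match model")
        return (model.w @ X + model.b) / float(np.linalg.norm(model.w))
    return model.sign * model.estimator.decision_function(X.T)


def rank_candidates(
    scores: Sequence[float], pairs: Sequence[tuple[str, str]]
) -> RankedPredictions:
    """Per-disease descending-score ranking; ties break by miRNA label."""
    if len(scores) != len(pairs):
        raise ValueError("scores and pairs have different lengths")
    by_disease: dict[str, list[tuple[str, float]]] = {}
    for (d, m), s in zip(pairs, scores):
        by_disease.setdefault(d, []).append((m, float(s)))
    rows: list[tuple[str, str, float, int]] = []
    for d in sorted(by_disease):
        entries = sorted(by_disease[d], key=lambda e: (-e[1], e[0]))
        rows.extend((d, m, s, rank) for rank, (m, s) in enumerate(entries, start=1))
    return RankedPredictions(rows)
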