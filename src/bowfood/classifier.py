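"""One-vs-rest linear classifiers over bag-of-words histograms.

For N food categories, N binary soft-margin linear SVMs are trained; the
classifier for category C_i treats every image whose label set contains
C_i as a positive (so a multi-food image is a positive for each category
it contains) and everything else as a negative.  Prediction is either
single-label (the argmax of the decision scores) or multi-label (every
category whose score strictly exceeds a recognition sensitivity
threshold).

The SVM cost follows the mean-loss convention (the per-sample cost is
C / n_samples), which makes the fitted boundary invariant to duplicating
the training set; with inverse-frequency class weighting (default on)
the handful of positives per category is not swamped by the negatives.
The primal solver is used, so retraining on identical inputs reproduces
identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Set

import numpy as np
from sklearn.svm import LinearSVC

from .codebook import BowHistogram


@dataclass
class CategoryModel:
    """Linear decision function ``w . h + b`` for one food category."""

    category: str
    weights: np.ndarray
    bias: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.bias = float(self.bias)


@dataclass
class PredictionScores:
    """Per-category decision values, ordered by the model's category list."""

    categories: tuple
    values: np.ndarray

    def __post_init__(self):
        self.categories = tuple(self.categories)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.categories) != len(self.values):
            raise ValueError("one score per category required")

    def __getitem__(self, category: str) -> float:
        return float(self.values[self.categories.index(category)])

    def as_dict(self) -> dict:
        return {c: float(v) for c, v in zip(self.categories, self.values)}


def _histogram_matrix(histograms: Sequence) -> np.ndarray:
    rows = [h.values if isinstance(h, BowHistogram) else np.asarray(h, float)
            for h in histograms]
    lengths = {r.shape[0] for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"histograms have mixed lengths {sorted(lengths)}")
    return np.vstack(rows)


#: Default soft-margin cost.  The loss term is a weighted *mean* over
#: samples (so the fit is invariant to duplicating the training set);
#: 64 corresponds to a per-sample cost near 1 — the standard linear-SVM
#: operating point — for study-scale training sets of a few dozen images.
DEFAULT_REGULARIZATION = 64.0


def train_ovr(histograms: Sequence,
              label_sets: Sequence[Set[str]],
              regularization: float = DEFAULT_REGULARIZATION,
              class_weight: bool = True) -> list:
    """Train one binary linear SVM per category (one-vs-rest).

    Parameters
    ----------
    histograms
        Encoded training images (BowHistogram or plain vectors), all the
        same length.
    label_sets
        Ground-truth category sets, aligned with ``histograms``; an image
        labelled with several categories is a positive example for each.
    regularization
        Soft-margin cost C (> 0), mean-loss convention.
    class_weight
        Inverse-frequency weighting of the hinge loss (on by default;
        training sets here typically have 4-8 positives per category
        against many negatives).

    Returns one :class:`CategoryModel` per category, in sorted category
    order.
    """
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    if len(histograms) != len(label_sets):
        raise ValueError("histograms and label_sets must align")
    X = _histogram_matrix(histograms)
    labels = [frozenset(s) for s in label_sets]
    categories = sorted(set().union(*labels)) if labels else []
    if not categories:
        raise ValueError("no categories in label sets")
    n = X.shape[0]
    models = []
    for cat in categories:
        y = np.array([1 if cat in s else 0 for s in labels])
        if y.sum() == 0:
            raise ValueError(f"category {cat!r} has no positive examples")
        if y.sum() == n:
            raise ValueError(f"category {cat!r} has no negative examples")
        svc = LinearSVC(C=regularization / n,
                        loss="squared_hinge",
                        dual=False,
                        class_weight="balanced" if class_weight else None,
                        tol=1e-8,
                        max_iter=20000)
        svc.fit(X, y)
        models.append(CategoryModel(category=cat,
                                    weights=svc.coef_[0],
                                    bias=svc.intercept_[0]))
    return models


def score(models: Sequence[CategoryModel], h) -> PredictionScores:
    """Signed linear decision values ``w . h + b`` for every category."""
    vec = h.values if isinstance(h, BowHistogram) else np.asarray(h, float)
    for m in models:
        if m.weights.shape[0] != vec.shape[0]:
            raise ValueError(
                f"histogram length {vec.shape[0]} does not match model "
                f"{m.category!r} (expects {m.weights.shape[0]})")
    values = np.array([float(m.weights @ vec + m.bias) for m in models])
    return PredictionScores(categories=tuple(m.category for m in models),
                            values=values)


def predict_single(scores: PredictionScores) -> str:
    """The single most likely category (argmax; first wins on ties)."""
    if len(scores.categories) == 0:
        raise ValueError("no categories to predict from")
    return scores.categories[int(np.argmax(scores.values))]


def predict_multi(scores: PredictionScores, sensitivity: float) -> set:
    """Categories whose score strictly exceeds the recognition sensitivity.

    May be empty (sensitivity above every score) or the full category set
    (below every score); monotonically shrinks as sensitivity grows.
    """
    return {c for c, v in zip(scores.categories, scores.values)
            if v > sensitivity}
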