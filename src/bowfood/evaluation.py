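"""Jaccard recognition accuracy with a sensitivity sweep.

For each category C_i the test set splits into M_i (images truly
containing C_i) and its complement.  At sensitivity threshold eps the
recognized set M_i^R(eps) holds every test image whose decision score
strictly exceeds eps, and the per-category accuracy is the Jaccard index

    r_i(eps) = |M_i^R(eps) & M_i| / |M_i^R(eps) | M_i|.

The reported accuracy is r_i = max_eps r_i(eps).  Because the recognized
set only changes when eps crosses an observed score, evaluating r_i on
the grid {s - delta : s an observed score} plus {max score + delta}
realizes every achievable recognized set, so the maximum is exact.  The
overall accuracy is the unweighted mean of the per-category r_i.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from typing import Mapping, Set

import numpy as np

from .classifier import score as score_histogram
from .codebook import UnencodableImageError, encode_image
from .features import extract_features
from .image_prep import load_image, maybe_downscale

logger = logging.getLogger(__name__)

_SWEEP_DELTA = 1e-9


def jaccard_accuracy(recognized: Set, truth: Set) -> float:
    """|recognized & truth| / |recognized | truth|, in [0, 1].

    Both sets empty is defined as 1.0 (nothing to find, nothing claimed);
    the event is logged since it usually signals a degenerate split.
    """
    recognized, truth = set(recognized), set(truth)
    union = recognized | truth
    if not union:
        logger.info("jaccard_accuracy: both sets empty, returning 1.0")
        return 1.0
    return len(recognized & truth) / len(union)


def sweep_sensitivity(scores_per_image: Mapping, truth: Set):
    """Maximize the Jaccard accuracy of one category over the threshold.

    Parameters
    ----------
    scores_per_image
        Mapping image-id -> decision score for this category, covering
        the whole test set.  Scores of ``-inf`` mark images that could
        not be encoded; they are never recognized.
    truth
        Image ids truly containing the category.

    Returns ``(best_eps, r)`` with the smallest maximizing threshold.
    """
    if not scores_per_image:
        raise ValueError("empty test set")
    ids = list(scores_per_image)
    values = np.array([scores_per_image[i] for i in ids], dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        # nothing encodable: only the empty recognized set is achievable
        return 0.0, jaccard_accuracy(set(), truth)
    distinct = np.unique(finite)
    candidates = np.concatenate([distinct - _SWEEP_DELTA,
                                 [distinct[-1] + _SWEEP_DELTA]])
    best_eps, best_r = None, -1.0
    for eps in sorted(candidates):
        recognized = {i for i, v in zip(ids, values) if v > eps}
        r = jaccard_accuracy(recognized, set(truth))
        if r > best_r + 1e-15:
            best_eps, best_r = float(eps), r
    return best_eps, best_r


@dataclass
class CategoryResult:
    """Sweep outcome for one category."""

    category: str
    epsilon: float        # best sensitivity threshold
    accuracy: float       # r_i at that threshold, in [0, 1]
    n_truth: int          # |M_i|
    n_recognized: int     # |M_i^R(eps*)|


@dataclass
class EvalReport:
    """Per-category accuracies plus their unweighted mean."""

    categories: list
    n_images: int = 0
    n_unencodable: int = 0

    @property
    def overall(self) -> float:
        return float(np.mean([c.accuracy for c in self.categories]))

    def accuracy_of(self, category: str) -> float:
        for c in self.categories:
            if c.category == category:
                return c.accuracy
        raise KeyError(category)

    def to_dict(self) -> dict:
        return {
            "categories": [
                {"category": c.category, "epsilon": c.epsilon,
                 "accuracy": c.accuracy, "n_truth": c.n_truth,
                 "n_recognized": c.n_recognized}
                for c in self.categories
            ],
            "overall": self.overall,
            "n_images": self.n_images,
            "n_unencodable": self.n_unencodable,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["category", "epsilon", "accuracy",
                             "n_truth", "n_recognized"])
            for c in self.categories:
                writer.writerow([c.category, repr(c.epsilon),
                                 repr(c.accuracy), c.n_truth, c.n_recognized])
            writer.writerow(["Overall", "", repr(self.overall), "", ""])


def score_test_images(models, codebooks, rows, channels=None,
                      hellinger=False):
    """Decision scores for every (path, labels) row of a test manifest.

    Returns ``(score_table, truth_sets, n_unencodable)`` where
    score_table maps path -> PredictionScores-like dict and unencodable
    images get ``-inf`` everywhere (counted as never recognized).
    ``hellinger`` applies the square-root histogram map the trained
    pipeline uses; pass whatever the models were trained with.
    """
    categories = [m.category for m in models]
    score_table = {}
    truth_sets = {c: set() for c in categories}
    n_unencodable = 0
    for path, labels in rows:
        unknown = set(labels) - set(categories)
        if unknown:
            raise ValueError(
                f"manifest labels {sorted(unknown)} absent from the model "
                f"(image {path})")
        image = maybe_downscale(load_image(path, labels=labels))
        fs = extract_features(image, channels=channels or
                              [c for c in ("shape", "texture", "colour")
                               if c in codebooks])
        try:
            h = encode_image(fs, codebooks, channels=channels)
            vec = np.sqrt(h.values) if hellinger else h.values
            s = score_histogram(models, vec)
            score_table[path] = s.as_dict()
        except UnencodableImageError:
            logger.warning("unencodable test image (no interest points): %s",
                           path)
            score_table[path] = {c: float("-inf") for c in categories}
            n_unencodable += 1
        for c in labels:
            truth_sets[c].add(path)
    return score_table, truth_sets, n_unencodable


def evaluate_scores(score_table: Mapping, truth_sets: Mapping,
                    n_unencodable: int = 0) -> EvalReport:
    """Build an EvalReport from precomputed per-image score dictionaries."""
    results = []
    for cat in truth_sets:
        per_image = {p: score_table[p][cat] for p in score_table}
        eps, r = sweep_sensitivity(per_image, truth_sets[cat])
        recognized = sum(1 for v in per_image.values() if v > eps)
        results.append(CategoryResult(category=cat, epsilon=eps, accuracy=r,
                                      n_truth=len(truth_sets[cat]),
                                      n_recognized=recognized))
    return EvalReport(categories=results, n_images=len(score_table),
                      n_unencodable=n_unencodable)


def evaluate_dataset(models, codebooks, test_manifest,
                     channels=None, hellinger=False) -> EvalReport:
    """Score a test manifest and report threshold-maximized accuracies.

    Parameters
    ----------
    models
        CategoryModel list (one-vs-rest classifiers).
    codebooks
        Mapping channel -> Codebook used for encoding.
    test_manifest
        Iterable of ``(image_path, label_set)`` rows; row order does not
        affect the report.
    channels
        Optional channel subset (ablation); defaults to every channel
        with a codebook.
    """
    rows = list(test_manifest)
    if not rows:
        raise ValueError("empty test manifest")
    score_table, truth_sets, n_bad = score_test_images(
        models, codebooks, rows, channels=channels, hellinger=hellinger)
    return evaluate_scores(score_table, truth_sets, n_unencodable=n_bad)
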