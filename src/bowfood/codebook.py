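"""Chi-squared K-means codebooks and bag-of-words image encoding.

Per-channel descriptor pools are vector-quantized into codebooks of K
centroids with Lloyd's algorithm under the chi-squared histogram
dissimilarity

    d(u, v) = 1/2 * sum_i (u_i - v_i)^2 / (u_i + v_i),

with zero-denominator terms contributing zero (the limit as both entries
vanish).  Assignment uses the chi-squared metric; the centroid update is
the arithmetic mean, the standard approximation since exact chi-squared
centroids have no closed form.  An image is encoded by counting the
best-matching codeword of each interest point per channel, L1-normalizing
each channel's count histogram, and concatenating the blocks in the fixed
order [shape | texture | colour].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .features import CHANNELS, FeatureSet

#: Default codebook size per channel.
DEFAULT_CODEBOOK_SIZES = {"shape": 100, "texture": 40, "colour": 50}

_KMEANS_MAX_ITER = 300


class UnencodableImageError(ValueError):
    """Raised when an image has no interest points and cannot be encoded."""


def _validate_nonneg(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError(f"{name} must be non-negative for the chi-squared "
                         "dissimilarity")
    return a


def chi2_distance(u, v) -> float:
    """Chi-squared dissimilarity between two non-negative vectors.

    Symmetric, non-negative, zero iff ``u == v``.  Bins where both
    entries are zero contribute nothing.
    """
    u = _validate_nonneg(u, "u")
    v = _validate_nonneg(v, "v")
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    denom = u + v
    diff2 = (u - v) ** 2
    mask = denom > 0
    return 0.5 * float(np.sum(diff2[mask] / denom[mask]))


def chi2_cdist(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pairwise chi-squared distances between rows of X (n,D) and C (K,D).

    Zero-denominator bins contribute 0: when ``x_i + c_i == 0`` both
    entries are 0 (non-negativity), so the numerator is 0 as well and the
    denominator can safely be replaced by 1.
    """
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    if X.ndim != 2 or C.ndim != 2 or X.shape[1] != C.shape[1]:
        raise ValueError(
            f"dimension mismatch: X is {X.shape}, C is {C.shape}")
    out = np.empty((X.shape[0], C.shape[0]))
    for k in range(C.shape[0]):
        diff = X - C[k]
        np.square(diff, out=diff)
        denom = X + C[k]
        denom[denom == 0.0] = 1.0
        diff /= denom
        out[:, k] = diff.sum(axis=1)
    out *= 0.5
    return out


@dataclass
class Codebook:
    """K centroid vectors ("codewords") for one feature channel."""

    channel: str
    centroids: np.ndarray                      # (K, D), non-negative
    objective_history: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.centroids = _validate_nonneg(self.centroids, "centroids")
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 1:
            raise ValueError("centroids must be a (K, D) array with K >= 1")

    @property
    def K(self) -> int:
        return self.centroids.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.centroids.shape[1]


def _kmeanspp_init(X: np.ndarray, K: int, rng: np.random.Generator):
    """k-means++ seeding under the chi-squared metric."""
    n = X.shape[0]
    centroids = np.empty((K, X.shape[1]))
    first = rng.integers(n)
    centroids[0] = X[first]
    d2 = chi2_cdist(X, centroids[:1])[:, 0]
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centroids[k] = X[idx]
        d2 = np.minimum(d2, chi2_cdist(X, centroids[k:k + 1])[:, 0])
    return centroids


def _lloyd_chi2(X: np.ndarray, centroids: np.ndarray, max_iter: int):
    """Lloyd iterations with chi-squared assignment and mean update.

    Stops when assignments stop changing, when the objective would rise
    (mean update is only approximately optimal under chi-squared, so a
    guard keeps the recorded objective monotone), or at ``max_iter``.
    Empty clusters are re-seeded with the feature farthest from its
    assigned centroid.
    """
    K = centroids.shape[0]
    centroids = centroids.copy()
    prev_labels = None
    history = []
    for _ in range(max_iter):
        dist = chi2_cdist(X, centroids)
        labels = dist.argmin(axis=1)
        objective = float(dist[np.arange(len(X)), labels].sum())
        if history and objective > history[-1] + 1e-12:
            centroids = prev_centroids
            labels = prev_labels
            break
        history.append(objective)
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break
        prev_labels = labels
        prev_centroids = centroids.copy()
        new_centroids = centroids.copy()
        mind = dist[np.arange(len(X)), labels]
        for k in range(K):
            members = X[labels == k]
            if len(members):
                new_centroids[k] = members.mean(axis=0)
            else:
                far = int(np.argmax(mind))
                new_centroids[k] = X[far]
                mind = mind.copy()
                mind[far] = -1.0   # don't reuse the same point twice
        centroids = new_centroids
    else:
        dist = chi2_cdist(X, centroids)
        labels = dist.argmin(axis=1)
        objective = float(dist[np.arange(len(X)), labels].sum())
        if objective <= history[-1] + 1e-12:
            history.append(objective)
    return centroids, labels, history


def kmeans_chi2(features, K: int, seed: int, channel: str = "shape",
                max_iter: int = _KMEANS_MAX_ITER,
                n_init: int = 3) -> Codebook:
    """Cluster a descriptor pool into a K-word codebook.

    Runs ``n_init`` seeded k-means++ initializations under the
    chi-squared metric and keeps the lowest-objective result, so the
    outcome is reproducible bit-for-bit for a fixed ``seed``.

    Parameters
    ----------
    features
        ``(n, D)`` array (or sequence of 1-D vectors) of non-negative
        descriptors, all from the same channel.
    K
        Number of codewords; requires at least K distinct features.
    seed
        Seeds both the k-means++ draws and restart streams.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    X = _validate_nonneg(X, "features")
    if K < 1:
        raise ValueError("K must be >= 1")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < K:
        raise ValueError(
            f"need at least K={K} distinct features, got {n_distinct}")
    rng = np.random.default_rng(seed)
    # Tiny pools are where k-means++ local optima actually bite, and
    # restarts there are essentially free: widen the restart budget.
    if X.shape[0] <= 100:
        n_init = max(n_init, 25)
    best = None
    for _ in range(max(1, n_init)):
        init = _kmeanspp_init(X, K, rng)
        centroids, labels, history = _lloyd_chi2(X, init, max_iter)
        if best is None or history[-1] < best[2][-1] - 1e-12:
            best = (centroids, labels, history)
    centroids, _, history = best
    return Codebook(channel=channel, centroids=centroids,
                    objective_history=history)


def assign_codeword(v, codebook: Codebook) -> int:
    """Index of the best-matching codeword (argmin chi-squared distance).

    Ties are broken toward the lowest index.
    """
    v = _validate_nonneg(v, "v")
    if v.shape != (codebook.feature_dim,):
        raise ValueError(
            f"feature has dimension {v.shape}, codebook expects "
            f"({codebook.feature_dim},)")
    d = chi2_cdist(v[None, :], codebook.centroids)[0]
    return int(d.argmin())


@dataclass
class BowHistogram:
    """Concatenated per-channel codeword-occurrence histogram of one image.

    ``layout`` records the (channel, K) blocks in concatenation order;
    each block is L1-normalized before concatenation so channels with
    different vocabulary sizes carry equal weight.
    """

    values: np.ndarray
    layout: tuple          # ((channel, K), ...)
    n_points: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expect = sum(k for _, k in self.layout)
        if self.values.shape != (expect,):
            raise ValueError(
                f"histogram length {self.values.shape} does not match "
                f"layout total {expect}")


def encode_image(featureset: FeatureSet,
                 codebooks: Mapping[str, Codebook],
                 channels: Optional[Sequence[str]] = None) -> BowHistogram:
    """Encode a FeatureSet as a concatenated codeword histogram.

    Channels are concatenated in the fixed order shape, texture, colour
    (restricted to the requested/available subset).  Raises
    :class:`UnencodableImageError` for images with no interest points.
    """
    if channels is None:
        channels = [c for c in CHANNELS if c in codebooks]
    else:
        channels = [c for c in CHANNELS if c in channels]
        missing = [c for c in channels if c not in codebooks]
        if missing:
            raise ValueError(f"no codebook for channels {missing}")
    if not channels:
        raise ValueError("at least one channel required")
    if featureset.n_points == 0:
        raise UnencodableImageError(
            "image has no interest points and cannot be encoded")
    blocks = []
    layout = []
    for ch in channels:
        cb = codebooks[ch]
        X = featureset.by_channel[ch]
        dist = chi2_cdist(X, cb.centroids)
        counts = np.bincount(dist.argmin(axis=1), minlength=cb.K).astype(float)
        blocks.append(counts / counts.sum())
        layout.append((ch, cb.K))
    return BowHistogram(values=np.concatenate(blocks),
                        layout=tuple(layout),
                        n_points=featureset.n_points)
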