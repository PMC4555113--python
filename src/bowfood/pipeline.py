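"""End-to-end orchestration: train, evaluate, ablate, serialize.

Training pools descriptors from every training image per channel, builds
one shared codebook per channel by chi-squared K-means, encodes the
training images, and fits one-vs-rest linear SVMs.  Codebooks and
classifiers are bundled into a single archive with a codebook checksum,
so a classifier can never silently be applied to histograms encoded
against different codebooks.

Per-channel codebooks do not depend on the other channels, so the
channel-ablation study builds all codebooks once and only retrains the
(cheap) classifiers per channel configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classifier import CategoryModel, score as score_histogram, train_ovr
from .codebook import Codebook, UnencodableImageError, encode_image, kmeans_chi2
from .config import PipelineConfig
from .evaluation import EvalReport, evaluate_scores
from .features import CHANNELS, extract_features
from .image_prep import load_image, maybe_downscale

logger = logging.getLogger(__name__)

_FORMAT_VERSION = 1


def codebook_checksum(codebooks: dict) -> str:
    """SHA-256 over the centroid matrices, in fixed channel order."""
    digest = hashlib.sha256()
    for ch in CHANNELS:
        if ch in codebooks:
            cb = codebooks[ch]
            digest.update(ch.encode())
            digest.update(str(cb.centroids.shape).encode())
            digest.update(np.ascontiguousarray(cb.centroids).tobytes())
    return digest.hexdigest()


@dataclass
class ModelBundle:
    """Trained codebooks + classifiers + the config that produced them."""

    codebooks: dict                 # channel -> Codebook
    models: list                    # CategoryModel, sorted by category
    config: PipelineConfig
    checksum: str = ""

    def __post_init__(self):
        expect = codebook_checksum(self.codebooks)
        if self.checksum and self.checksum != expect:
            raise ValueError(
                "codebook checksum mismatch: classifiers were trained "
                "against different codebooks")
        self.checksum = expect

    @property
    def categories(self) -> list:
        return [m.category for m in self.models]


def _load_and_prep(path, labels, config: PipelineConfig):
    image = load_image(path, labels=labels)
    return maybe_downscale(image, threshold=config.resize_threshold,
                           factor=config.resize_factor)


def extract_manifest_features(rows, config: PipelineConfig,
                              channels=None) -> dict:
    """FeatureSet per manifest row; logs per-image interest-point counts."""
    channels = tuple(channels or config.channels)
    featuresets = {}
    for path, labels in rows:
        image = _load_and_prep(path, labels, config)
        fs = extract_features(image, channels=channels)
        logger.info("image %s: %d interest points", path, fs.n_points)
        featuresets[path] = fs
    return featuresets


def build_codebooks(featuresets: dict, config: PipelineConfig,
                    channels=None) -> dict:
    """One shared codebook per channel from the pooled training descriptors."""
    channels = tuple(channels or config.channels)
    codebooks = {}
    for i, ch in enumerate(ch for ch in CHANNELS if ch in channels):
        pool = np.vstack([fs.by_channel[ch] for fs in featuresets.values()
                          if fs.n_points > 0])
        cap = getattr(config, "max_codebook_features", None)
        if cap and len(pool) > cap:
            rng = np.random.default_rng(config.kmeans_seed + 1000 * i + 7)
            pool = pool[rng.choice(len(pool), size=cap, replace=False)]
        logger.info("channel %s: %d pooled descriptors -> K=%d",
                    ch, len(pool), config.codebook_sizes[ch])
        codebooks[ch] = kmeans_chi2(
            pool, K=config.codebook_sizes[ch],
            seed=config.kmeans_seed + 1000 * i, channel=ch,
            max_iter=config.kmeans_max_iter, n_init=config.kmeans_n_init)
    return codebooks


def _classifier_input(h, config) -> np.ndarray:
    """Histogram vector as the classifier sees it (Hellinger-mapped)."""
    if getattr(config, "hellinger", False):
        return np.sqrt(h.values)
    return h.values


def score_image(bundle: "ModelBundle", featureset, channels=None):
    """Decision scores of one image's FeatureSet under a trained bundle.

    Raises :class:`UnencodableImageError` for images without keypoints.
    """
    h = encode_image(featureset, bundle.codebooks,
                     channels=channels or bundle.config.channels)
    return score_histogram(bundle.models,
                           _classifier_input(h, bundle.config))


def _encode_rows(rows, featuresets, codebooks, channels):
    histograms, label_sets, paths = [], [], []
    for path, labels in rows:
        fs = featuresets[path]
        try:
            h = encode_image(fs, codebooks, channels=channels)
        except UnencodableImageError:
            logger.warning("skipping unencodable image: %s", path)
            continue
        histograms.append(h)
        label_sets.append(labels)
        paths.append(path)
    return histograms, label_sets, paths


def train_from_manifest(manifest, config: PipelineConfig = None,
                        featuresets: dict = None) -> ModelBundle:
    """Train codebooks and one-vs-rest classifiers from a manifest.

    ``manifest`` is a :class:`~bowfood.synthetic.DatasetManifest` (its
    train split is used) or an iterable of (path, labels) rows.
    ``featuresets`` may carry precomputed features keyed by path.
    """
    config = config or PipelineConfig()
    rows = manifest.rows("train") if hasattr(manifest, "rows") else list(manifest)
    if not rows:
        raise ValueError("empty training manifest")
    if featuresets is None:
        featuresets = extract_manifest_features(rows, config)
    codebooks = build_codebooks(featuresets, config)
    histograms, label_sets, _ = _encode_rows(rows, featuresets, codebooks,
                                             config.channels)
    if not histograms:
        raise ValueError("no encodable training images")
    models = train_ovr([_classifier_input(h, config) for h in histograms],
                       label_sets,
                       regularization=config.regularization,
                       class_weight=config.class_weight)
    return ModelBundle(codebooks=codebooks, models=models, config=config)


def _check_no_leakage(manifest) -> None:
    if hasattr(manifest, "frame"):
        train = set(manifest.frame[manifest.frame["split"] == "train"]
                    ["image_path"])
        test = set(manifest.frame[manifest.frame["split"] == "test"]
                   ["image_path"])
        overlap = train & test
        if overlap:
            raise ValueError(
                f"train/test leakage: {sorted(overlap)[:5]} appear in both "
                "splits")


def _score_rows(bundle: ModelBundle, rows, featuresets, channels):
    score_table, truth_sets = {}, {c: set() for c in bundle.categories}
    n_unencodable = 0
    for path, labels in rows:
        unknown = set(labels) - set(bundle.categories)
        if unknown:
            raise ValueError(
                f"manifest labels {sorted(unknown)} absent from the model "
                f"(image {path})")
        fs = featuresets[path]
        try:
            score_table[path] = score_image(bundle, fs,
                                            channels=channels).as_dict()
        except UnencodableImageError:
            logger.warning("unencodable test image: %s", path)
            score_table[path] = {c: float("-inf") for c in bundle.categories}
            n_unencodable += 1
        for c in labels:
            truth_sets[c].add(path)
    return score_table, truth_sets, n_unencodable


def evaluate_bundle(bundle: ModelBundle, manifest,
                    featuresets: dict = None,
                    channels=None) -> EvalReport:
    """Evaluate a trained bundle on a manifest's test split."""
    _check_no_leakage(manifest)
    rows = manifest.rows("test") if hasattr(manifest, "rows") else list(manifest)
    if not rows:
        raise ValueError("empty test manifest")
    if featuresets is None:
        featuresets = extract_manifest_features(rows, bundle.config)
    table, truth, n_bad = _score_rows(bundle, rows, featuresets, channels)
    return evaluate_scores(table, truth, n_unencodable=n_bad)


def ablation_study(manifest, config: PipelineConfig = None,
                   configurations: dict = None):
    """Train and evaluate per-channel ablations of the pipeline.

    Default configurations are shape-only, texture-only, colour-only and
    the combined channel set — the column structure of the study's
    accuracy table.  Features are extracted once and per-channel
    codebooks are shared across configurations; only the classifiers are
    retrained.

    Returns ``{configuration name: EvalReport}``.
    """
    config = config or PipelineConfig()
    if configurations is None:
        configurations = {ch: (ch,) for ch in config.channels}
        if len(config.channels) > 1:
            configurations["combined"] = config.channels
    _check_no_leakage(manifest)
    train_rows = manifest.rows("train")
    test_rows = manifest.rows("test")
    all_channels = tuple(sorted({c for chs in configurations.values()
                                 for c in chs},
                                key=CHANNELS.index))
    train_fs = extract_manifest_features(train_rows, config,
                                         channels=all_channels)
    test_fs = extract_manifest_features(test_rows, config,
                                        channels=all_channels)
    codebooks = build_codebooks(train_fs, config, channels=all_channels)
    reports = {}
    for name, chans in configurations.items():
        chans = tuple(chans)
        cbs = {c: codebooks[c] for c in chans}
        hists, labels, _ = _encode_rows(train_rows, train_fs, cbs, chans)
        models = train_ovr([_classifier_input(h, config) for h in hists],
                           labels,
                           regularization=config.regularization,
                           class_weight=config.class_weight)
        bundle = ModelBundle(codebooks=cbs, models=models, config=config)
        reports[name] = evaluate_bundle(bundle, test_rows,
                                        featuresets=test_fs, channels=chans)
    return reports


def ablation_table(reports: dict):
    """Accuracy table: rows = categories + Overall, columns = configs."""
    import pandas as pd

    names = list(reports)
    cats = [c.category for c in next(iter(reports.values())).categories]
    data = {}
    for name in names:
        rep = reports[name]
        col = [rep.accuracy_of(c) for c in cats] + [rep.overall]
        data[name] = col
    return pd.DataFrame(data, index=cats + ["Overall"])


# ---------------------------------------------------------------------------
# serialization

def save_bundle(path, bundle: ModelBundle) -> None:
    """Write the bundle to a single .npz archive (atomically)."""
    path = Path(path)
    meta = {
        "format_version": _FORMAT_VERSION,
        "config": bundle.config.to_dict(),
        "categories": bundle.categories,
        "codebook_channels": [c for c in CHANNELS if c in bundle.codebooks],
        "codebook_checksum": bundle.checksum,
    }
    arrays = {"meta": np.array(json.dumps(meta, sort_keys=True))}
    for ch, cb in bundle.codebooks.items():
        arrays[f"codebook_{ch}"] = cb.centroids
    arrays["weights"] = np.vstack([m.weights for m in bundle.models])
    arrays["biases"] = np.array([m.bias for m in bundle.models])
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            np.savez(fh, **arrays)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_bundle(path) -> ModelBundle:
    """Load a bundle archive, verifying format and codebook checksum."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported archive format {meta.get('format_version')}")
        codebooks = {ch: Codebook(channel=ch, centroids=data[f"codebook_{ch}"])
                     for ch in meta["codebook_channels"]}
        weights = data["weights"]
        biases = data["biases"]
    if codebook_checksum(codebooks) != meta["codebook_checksum"]:
        raise ValueError("codebook checksum mismatch: archive is corrupt or "
                         "was assembled from mismatched parts")
    models = [CategoryModel(category=c, weights=w, bias=b)
              for c, w, b in zip(meta["categories"], weights, biases)]
    config = PipelineConfig.from_dict(meta["config"])
    return ModelBundle(codebooks=codebooks, models=models, config=config,
                       checksum=meta["codebook_checksum"])
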