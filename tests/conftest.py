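"""Shared fixtures: small rendered images and trained pipelines.

The expensive fixtures (the study-scale dataset and its channel-ablation
reports) are session-scoped so the end-to-end tests share one run.
"""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from bowfood.config import PipelineConfig
from bowfood.image_prep import ImageRecord
from bowfood.pipeline import ablation_study, train_from_manifest
from bowfood.synthetic import default_category_specs, generate_dataset

#: Seed of the study-scale run shared by the end-to-end tests.
STUDY_SEED = 0


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def textured_image(rng):
    """A smooth random-texture greyscale image with many interest points."""
    base = gaussian_filter(rng.normal(0.0, 1.0, (128, 128)), 2.0)
    base = ((base - base.min()) / np.ptp(base) * 255).astype(np.uint8)
    return ImageRecord("textured", np.repeat(base[:, :, None], 3, axis=2))


@pytest.fixture(scope="session")
def tiny_config():
    return PipelineConfig(codebook_sizes={"shape": 20, "texture": 12,
                                          "colour": 12},
                          kmeans_n_init=2)


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory):
    """3 categories, 3 train / 4 test rows each, quarter multi-label."""
    out = tmp_path_factory.mktemp("tiny_dataset")
    return generate_dataset(n_categories=3, train_per_category=3,
                            test_per_category=4, multi_label_fraction=0.25,
                            seed=7, out_dir=out, image_size=96)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_manifest, tiny_config):
    return train_from_manifest(tiny_manifest, tiny_config)


@pytest.fixture(scope="session")
def study_manifest(tmp_path_factory):
    """The default study-scale profile: 10 categories, 4-8 train images,
    13-20 test rows per category, 30% multi-label composites."""
    out = tmp_path_factory.mktemp("study_dataset")
    return generate_dataset(seed=STUDY_SEED, out_dir=out)


@pytest.fixture(scope="session")
def study_reports(study_manifest):
    """Channel-ablation reports of the full pipeline on the study profile."""
    config = PipelineConfig()
    configurations = {ch: (ch,) for ch in config.channels}
    configurations["no_colour"] = ("shape", "texture")
    configurations["combined"] = config.channels
    return ablation_study(study_manifest, config,
                          configurations=configurations)
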