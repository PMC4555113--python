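"""Pipeline configuration.

Defaults follow the deployed system: codebook sizes 100 (shape), 40
(texture), 50 (colour); images halved once when a side exceeds 2000 px;
linear SVMs with C = 1 and inverse-frequency class weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codebook import DEFAULT_CODEBOOK_SIZES
from .features import CHANNELS


@dataclass
class PipelineConfig:
    codebook_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_CODEBOOK_SIZES))
    kmeans_seed: int = 0
    kmeans_max_iter: int = 300
    kmeans_n_init: int = 3
    #: Cap on pooled descriptors per channel for codebook training (a
    #: seeded subsample; standard bag-of-words practice to bound K-means
    #: cost on large pools).  None disables the cap.
    max_codebook_features: int = 6000
    regularization: float = 64.0
    class_weight: bool = True
    #: Hellinger (element-wise square root) normalization of the encoded
    #: histogram before classification: a linear kernel on
    #: sqrt-histograms approximates the chi-squared kernel that the
    #: vector quantizer is built on.
    hellinger: bool = True
    resize_threshold: int = 2000
    resize_factor: int = 2
    channels: tuple = CHANNELS

    def __post_init__(self):
        self.channels = tuple(self.channels)
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}")
        if not self.channels:
            raise ValueError("at least one feature channel must be enabled")
        for ch in self.channels:
            if self.codebook_sizes.get(ch, 0) < 1:
                raise ValueError(f"codebook size for {ch!r} must be >= 1")
        if self.resize_threshold <= 0:
            raise ValueError("resize threshold must be positive")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")

    def to_dict(self) -> dict:
        return {
            "codebook_sizes": dict(self.codebook_sizes),
            "kmeans_seed": self.kmeans_seed,
            "kmeans_max_iter": self.kmeans_max_iter,
            "kmeans_n_init": self.kmeans_n_init,
            "max_codebook_features": self.max_codebook_features,
            "regularization": self.regularization,
            "class_weight": self.class_weight,
            "hellinger": self.hellinger,
            "resize_threshold": self.resize_threshold,
            "resize_factor": self.resize_factor,
            "channels": list(self.channels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["channels"] = tuple(d.get("channels", CHANNELS))
        return cls(**d)
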