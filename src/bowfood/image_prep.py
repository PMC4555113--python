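"""Image loading and normalization.

All downstream stages work on 8-bit RGB rasters.  Greyscale inputs are
replicated to three channels and alpha channels are dropped at load time,
so the rest of the pipeline never has to branch on pixel format.  Large
photographs (straight off a phone camera) are halved once if either side
exceeds 2000 px, which speeds up interest-point detection and thins the
keypoint set without hurting recognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

#: Side length above which an image is halved once at load time.
RESIZE_THRESHOLD = 2000
#: Linear downscale factor applied when the threshold is exceeded.
RESIZE_FACTOR = 2


@dataclass(frozen=True)
class ImageRecord:
    """A decoded RGB photograph plus its ground-truth label set.

    Parameters
    ----------
    path
        Origin of the raster (may be a placeholder for in-memory images).
    pixels
        ``(H, W, 3)`` uint8 array, RGB channel order.
    labels
        Food-category names present in the image; empty for unlabeled
        prediction inputs.
    """

    path: str
    pixels: np.ndarray
    labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"zero-area image: {self.path}")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "labels", frozenset(self.labels))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_image(path, labels=()) -> ImageRecord:
    """Decode a PNG or JPEG file into an :class:`ImageRecord`.

    Greyscale images are replicated to 3 channels; any alpha channel is
    dropped.  EXIF orientation is ignored (images are used as stored).

    Raises
    ------
    IOError
        If the file is missing, truncated, or not a decodable image.
    ValueError
        If the decoded image has zero area.
    """
    path = str(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("RGBA", "LA", "PA"):
                # Drop alpha without compositing.
                im = im.convert(im.mode[:-1] or "L")
            if im.mode != "RGB":
                im = im.convert("RGB")
            pixels = np.asarray(im, dtype=np.uint8)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot decode image file {path!r}: {exc}") from exc
    if pixels.size == 0:
        raise ValueError(f"zero-area image: {path}")
    return ImageRecord(path=path, pixels=pixels, labels=frozenset(labels))


def maybe_downscale(image: ImageRecord,
                    threshold: int = RESIZE_THRESHOLD,
                    factor: int = RESIZE_FACTOR) -> ImageRecord:
    """Halve an oversized image once.

    If either side exceeds ``threshold`` pixels, both dimensions are
    divided by ``factor`` (floor) using area-average (BOX) resampling;
    otherwise the record is returned unchanged.  The rule is applied
    once, never iterated, even if the result still exceeds the threshold.
    """
    h, w = image.height, image.width
    if w <= threshold and h <= threshold:
        return image
    new_w, new_h = w // factor, h // factor
    im = Image.fromarray(image.pixels, mode="RGB")
    resized = im.resize((new_w, new_h), resample=Image.BOX)
    return ImageRecord(path=image.path,
                       pixels=np.asarray(resized, dtype=np.uint8),
                       labels=image.labels)
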