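"""Synthetic labelled food-like images for exercising the pipeline.

The study-scale dataset this package targets (ten food categories, 4-8
positive training photographs each, a few dozen test photographs per
category, with multi-food images containing up to five categories) was
never released, so the generator emulates its *structure*: every
category gets a colour/texture/shape signature, training images are
single-label, and a configurable fraction of test images are multi-label
composites.  Categories are separable by construction — that is the
point: the generator provides ground truth against which the pipeline's
end-to-end recovery can be measured.

Two default categories ("custard" and "milk") are rendered identically
except for base colour, so disabling the colour channel must selectively
hurt exactly that pair; :data:`COLOUR_ONLY_PAIR` names them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .image_prep import ImageRecord

#: Categories distinguishable only through the colour channel.
COLOUR_ONLY_PAIR = ("custard", "milk")

_TEXTURES = ("smooth", "speckle", "stripe", "blob")
_SHAPES = ("disc", "ellipse", "rod", "heap")


class GenerationError(RuntimeError):
    """Raised when items cannot be placed without overlap."""


@dataclass(frozen=True)
class CategorySpec:
    """Visual signature of one synthetic food category.

    Parameters
    ----------
    name
        Category label written to manifests.
    base_colour
        Mean RGB of the item body, each channel in [0, 255].
    colour_jitter
        Per-pixel, per-channel Gaussian noise std (gives every item a
        fine grain so interest points are found on its surface).
    texture
        One of smooth / speckle / stripe / blob.
    texture_frequency
        Stripe period in pixels, or bump spacing for blobs (ignored for
        smooth/speckle).
    texture_contrast
        Relative modulation depth (multiplicative for stripes and
        speckle, additive scale for blobs).
    shape
        One of disc / ellipse / rod / heap.
    size_range
        (min, max) characteristic radius in pixels.
    """

    name: str
    base_colour: tuple
    colour_jitter: float = 6.0
    texture: str = "smooth"
    texture_frequency: float = 8.0
    texture_contrast: float = 0.25
    shape: str = "disc"
    size_range: tuple = (13, 19)

    def __post_init__(self):
        if not all(0 <= c <= 255 for c in self.base_colour):
            raise ValueError("base_colour channels must be in [0, 255]")
        if self.texture not in _TEXTURES:
            raise ValueError(f"texture must be one of {_TEXTURES}")
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.texture_frequency <= 0 or self.texture_contrast <= 0:
            raise ValueError("texture frequency and contrast must be positive")
        lo, hi = self.size_range
        if not (0 < lo <= hi):
            raise ValueError("size_range must be 0 < min <= max")


def default_category_specs() -> list:
    """Ten food-like category signatures spanning the signature space."""
    # Base colours sit at the centres of the 4-bin channel quantization
    # ([0,64),[64,128),[128,192),[192,256) -> centres 32/96/160/224), so a
    # +-10% illumination change never moves an item across a colour bin.
    # Texture contrasts are kept small enough that the modulation never
    # moves a channel across a bin boundary either: LBP responds to the
    # sign pattern of local differences, not their depth, so the texture
    # channel keeps its signal while the colour channel stays clean.
    return [
        CategorySpec("beans", (160, 32, 32), 8, "speckle", 4, 0.15, "rod"),
        CategorySpec("carrots", (224, 96, 32), 7, "stripe", 6, 0.12, "rod"),
        CategorySpec("cheese", (224, 224, 32), 8, "smooth", 8, 0.25,
                     "ellipse"),
        CategorySpec("custard", (224, 160, 96), 8, "smooth", 8, 0.25, "disc"),
        CategorySpec("milk", (224, 224, 224), 8, "smooth", 8, 0.25, "disc"),
        CategorySpec("muscle_meat", (160, 96, 96), 9, "stripe", 10, 0.15,
                     "ellipse"),
        CategorySpec("oranges", (224, 160, 32), 8, "speckle", 5, 0.12,
                     "disc"),
        CategorySpec("peas", (96, 160, 32), 8, "blob", 7, 0.25, "heap"),
        CategorySpec("tomato", (224, 32, 32), 10, "smooth", 8, 0.25, "disc"),
        CategorySpec("yoghurt", (224, 224, 160), 7, "blob", 9, 0.20, "heap"),
    ]


# ---------------------------------------------------------------------------
# rendering

def _signed_distance(spec: CategorySpec, shape_hw, position, size,
                     rng: np.random.Generator) -> np.ndarray:
    """Signed distance to the item boundary (positive inside), per pixel."""
    h, w = shape_hw
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = position
    u, v = xx - cx, yy - cy
    if spec.shape == "disc":
        return size - np.hypot(u, v)
    if spec.shape == "ellipse":
        angle = rng.uniform(0, math.pi)
        c, s = math.cos(angle), math.sin(angle)
        a, b = size, 0.7 * size
        ru, rv = c * u + s * v, -s * u + c * v
        f = np.hypot(ru / a, rv / b)
        return (1.0 - f) * b
    if spec.shape == "rod":
        angle = rng.uniform(0, math.pi)
        c, s = math.cos(angle), math.sin(angle)
        ru, rv = c * u + s * v, -s * u + c * v
        half_len, width = 1.1 * size, 0.5 * size
        d_axis = np.hypot(np.maximum(np.abs(ru) - half_len, 0.0), rv)
        return width - d_axis
    # heap: union of overlapping discs
    d = np.full((h, w), -np.inf)
    for _ in range(4):
        off = rng.uniform(-0.4 * size, 0.4 * size, size=2)
        r = rng.uniform(0.6 * size, 0.8 * size)
        d = np.maximum(d, r - np.hypot(u - off[0], v - off[1]))
    return d


def _texture_field(spec: CategorySpec, shape_hw,
                   rng: np.random.Generator) -> np.ndarray:
    """Multiplicative (stripe/speckle) or additive (blob) modulation field."""
    h, w = shape_hw
    if spec.texture == "smooth":
        return np.ones((h, w))
    if spec.texture == "stripe":
        xx = np.arange(w, dtype=float)[None, :]
        return 1.0 + spec.texture_contrast * np.sin(
            2.0 * math.pi * xx / spec.texture_frequency) * np.ones((h, 1))
    if spec.texture == "speckle":
        # band-limited speckle; per-pixel white noise would vanish under
        # the detector's base smoothing
        grain = gaussian_filter(rng.uniform(-1, 1, (h, w)), 0.8)
        peak = np.abs(grain).max()
        if peak > 0:
            grain /= peak
        return 1.0 + spec.texture_contrast * grain
    # blob: additive Gaussian bumps (returned as 1 + additive term)
    bumps = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    n_bumps = max(3, int(h * w / (spec.texture_frequency ** 2 * 2)))
    for _ in range(n_bumps):
        bx, by = rng.uniform(0, w), rng.uniform(0, h)
        sgn = 1.0 if rng.random() < 0.5 else -1.0
        sigma = spec.texture_frequency / 3.0
        bumps += sgn * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2)
                              / (2 * sigma ** 2))
    return 1.0 + spec.texture_contrast * np.clip(bumps, -1, 1)


def render_item(spec: CategorySpec, canvas: np.ndarray, position,
                rng: np.random.Generator, size: float = None) -> np.ndarray:
    """Draw one food item onto a float canvas (in place) and return it.

    The item is a shape mask filled with the base colour plus per-pixel
    jitter, modulated by the texture field, composited with a one-pixel
    anti-aliased edge.  Deterministic given the generator state.
    """
    h, w = canvas.shape[:2]
    if size is None:
        size = rng.uniform(*spec.size_range)
    if 2 * size > min(h, w):
        raise ValueError(
            f"item of size {size:.0f} does not fit a {w}x{h} canvas")
    cx, cy = position
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"position {position} outside canvas")
    dist = _signed_distance(spec, (h, w), position, size, rng)
    alpha = np.clip(dist + 0.5, 0.0, 1.0)
    colour = np.empty((h, w, 3))
    colour[:] = np.asarray(spec.base_colour, dtype=float)
    if spec.colour_jitter > 0:
        # Band-limited grain shared across channels (shading-like, keeps
        # chromaticity): white noise carries no energy at the scales a
        # scale-space detector sees, so smooth it lightly and rescale back
        # to the requested per-pixel std.
        grain = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=0.9)
        grain_std = grain.std()
        if grain_std > 0:
            colour += (grain * (spec.colour_jitter / grain_std))[:, :, None]
    tex = _texture_field(spec, (h, w), rng)
    if spec.texture == "blob":
        colour += (tex[:, :, None] - 1.0) * 100.0
    else:
        colour *= tex[:, :, None]
    colour = np.clip(colour, 0, 255)
    canvas[:] = canvas * (1.0 - alpha[:, :, None]) + colour * alpha[:, :, None]
    return canvas


def _background(size, rng: np.random.Generator) -> np.ndarray:
    """Weak-texture neutral grey (a flat field would yield no keypoints)."""
    h, w = size
    noise = gaussian_filter(rng.normal(0.0, 10.0, (h, w)), 1.2)
    # mid-bin grey so illumination scaling never moves the background
    # across a colour quantization bin
    grey = np.clip(96.0 + noise, 0, 255)
    return np.repeat(grey[:, :, None], 3, axis=2)


def generate_image(specs, size=(128, 128), n_items: int = 1, seed=None,
                   rng: np.random.Generator = None,
                   illumination: float = None):
    """Compose a labelled image from 1-5 distinct category specs.

    Items (``n_items`` per spec) are placed at non-overlapping random
    positions on a weak-texture grey background.  ``illumination``
    optionally scales the whole image (nominal range [0.7, 1.3]).

    Returns ``(ImageRecord, label_set)``.
    """
    specs = list(specs)
    names = [s.name for s in specs]
    if not (1 <= len(specs) <= 5) or len(set(names)) != len(names):
        raise ValueError("need 1 to 5 distinct category specs")
    if rng is None:
        rng = np.random.default_rng(seed)
    h, w = size
    total = len(specs) * n_items
    for attempt in range(5):
        canvas = _background(size, rng)
        shrink = 1.0 - 0.15 * attempt
        placed = []   # (cx, cy, r)
        ok = True
        for spec in specs:
            for _ in range(n_items):
                lo, hi = spec.size_range
                r = rng.uniform(lo, max(lo, hi * shrink))
                for _ in range(100):
                    cx = rng.uniform(r + 2, w - r - 2)
                    cy = rng.uniform(r + 2, h - r - 2)
                    if all(math.hypot(cx - px, cy - py) > r + pr + 2
                           for px, py, pr in placed):
                        break
                else:
                    ok = False
                    break
                render_item(spec, canvas, (cx, cy), rng, size=r)
                placed.append((cx, cy, r))
            if not ok:
                break
        if ok:
            break
    else:
        raise GenerationError(
            f"could not place {total} items on a {w}x{h} canvas "
            "without overlap after 100 attempts")
    if illumination is not None:
        canvas = np.clip(canvas * float(illumination), 0, 255)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    record = ImageRecord(path="<synthetic>", pixels=pixels,
                         labels=frozenset(names))
    return record, frozenset(names)


# ---------------------------------------------------------------------------
# dataset generation

@dataclass
class DatasetManifest:
    """Rows of (image path, labels, split) plus generation provenance."""

    frame: pd.DataFrame           # columns: image_path, labels, split
    root: Path
    seed: int = None
    specs: list = field(default_factory=list)

    @property
    def categories(self) -> list:
        cats = set()
        for lab in self.frame["labels"]:
            cats.update(lab.split(";"))
        return sorted(cats)

    def rows(self, split: str) -> list:
        """(absolute path, frozenset of labels) rows of one split."""
        sub = self.frame[self.frame["split"] == split]
        return [(str(self.root / r.image_path),
                 frozenset(r.labels.split(";")))
                for r in sub.itertuples()]

    @property
    def path(self) -> Path:
        return self.root / "manifest.csv"

    def save(self) -> Path:
        self.frame.to_csv(self.path, index=False)
        return self.path


def load_manifest(path) -> DatasetManifest:
    """Read a manifest CSV (columns image_path, labels, split)."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    required = {"image_path", "labels", "split"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"manifest {path} must have columns {sorted(required)}")
    return DatasetManifest(frame=frame, root=path.parent)


def generate_dataset(n_categories: int = 10,
                     train_per_category=(4, 8),
                     test_per_category=(13, 20),
                     multi_label_fraction: float = 0.3,
                     seed: int = 0,
                     out_dir=None,
                     image_size: int = 128,
                     specs=None,
                     illumination_range=(0.9, 1.1),
                     max_categories_per_image: int = 5) -> DatasetManifest:
    """Write a labelled synthetic dataset and its manifest CSV.

    The default profile mirrors the study-scale structure: 10 categories,
    4-8 single-label training images each, 13-20 test rows per category,
    and 30% of test rows as multi-label composites of 2-5 categories.

    Parameters accepting a (lo, hi) pair draw per-category counts
    uniformly from that inclusive range; an int fixes the count.
    Deterministic: the same seed yields byte-identical images and
    manifest.
    """
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    if out_dir is None:
        raise ValueError("out_dir is required")
    if specs is None:
        specs = default_category_specs()
    if n_categories > len(specs):
        raise ValueError(f"only {len(specs)} category specs available")
    specs = list(specs)[:n_categories]
    by_name = {s.name: s for s in specs}
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}")

    def draw_count(rc):
        if isinstance(rc, int):
            return rc
        lo, hi = rc
        return int(rng.integers(lo, hi + 1))

    size = (image_size, image_size)
    records = []

    def write(record, labels, split, idx):
        name = f"images/{split}_{idx:04d}.png"
        Image.fromarray(record.pixels, mode="RGB").save(out_dir / name)
        records.append({"image_path": name,
                        "labels": ";".join(sorted(labels)),
                        "split": split})

    # --- train: single-label, one or two items of the same category
    idx = 0
    for spec in specs:
        for _ in range(draw_count(train_per_category)):
            n_items = int(rng.integers(2, 4))
            rec, labels = generate_image([spec], size=size, n_items=n_items,
                                         rng=rng)
            write(rec, labels, "train", idx)
            idx += 1

    # --- test: per-category quotas; a fraction of rows are composites
    quotas = {s.name: draw_count(test_per_category) for s in specs}
    primary_pool = [name for name, q in quotas.items() for _ in range(q)]
    rng.shuffle(primary_pool)
    n_rows = len(primary_pool)
    n_multi = int(round(multi_label_fraction * n_rows))
    multi_rows = set(rng.choice(n_rows, size=n_multi, replace=False).tolist())
    max_k = min(max_categories_per_image, n_categories)
    idx = 0
    for row, primary in enumerate(primary_pool):
        row_specs = [by_name[primary]]
        if row in multi_rows and max_k >= 2:
            k = int(rng.integers(2, max_k + 1))
            others = [n for n in by_name if n != primary]
            extra = rng.choice(len(others), size=k - 1, replace=False)
            row_specs += [by_name[others[j]] for j in sorted(extra)]
        illum = float(rng.uniform(*illumination_range))
        n_items = 1 if len(row_specs) > 1 else int(rng.integers(1, 3))
        rec, labels = generate_image(row_specs, size=size, n_items=n_items,
                                     rng=rng, illumination=illum)
        write(rec, labels, "test", idx)
        idx += 1

    frame = pd.DataFrame.from_records(
        records, columns=["image_path", "labels", "split"])
    manifest = DatasetManifest(frame=frame, root=out_dir, seed=seed,
                               specs=specs)
    manifest.save()
    return manifest
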