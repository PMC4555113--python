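"""Interest-point detection and the three descriptor channels."""

import math

import numpy as np
import pytest
from PIL import Image
from scipy.ndimage import gaussian_filter

from bowfood.features import (
    CHANNEL_DIMS,
    InterestPoint,
    colour_descriptors,
    colour_histogram_global,
    detect_interest_points,
    extract_features,
    shape_descriptors,
    texture_descriptors,
)
from bowfood.image_prep import ImageRecord, load_image


def _rgb(grey):
    return np.repeat(np.asarray(grey, np.uint8)[:, :, None], 3, axis=2)


class TestDetection:
    def test_constant_image_yields_no_points(self):
        img = ImageRecord("c", np.full((256, 256, 3), 128, np.uint8))
        assert detect_interest_points(img) == []

    def test_gaussian_blob_detected_near_centre(self):
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        blob = 40 + 180 * np.exp(-((xx - 64) ** 2 + (yy - 64) ** 2)
                                 / (2 * 8.0 ** 2))
        img = ImageRecord("b", _rgb(np.clip(blob, 0, 255)))
        points = detect_interest_points(img)
        assert points, "an isotropic blob is a scale-space extremum"
        assert min(math.hypot(p.x - 64, p.y - 64) for p in points) <= 3.0

    def test_halved_image_yields_no_more_points(self, textured_image):
        n_full = len(detect_interest_points(textured_image))
        half = Image.fromarray(textured_image.pixels).resize(
            (64, 64), Image.BOX)
        n_half = len(detect_interest_points(
            ImageRecord("h", np.asarray(half, np.uint8))))
        assert n_half <= n_full

    def test_deterministic(self, textured_image):
        a = detect_interest_points(textured_image)
        b = detect_interest_points(textured_image)
        assert a == b

    def test_points_within_bounds_with_valid_geometry(self, textured_image):
        for p in detect_interest_points(textured_image):
            assert 0 <= p.x < textured_image.width
            assert 0 <= p.y < textured_image.height
            assert p.scale > 0
            assert 0 <= p.orientation < 2 * math.pi


class TestShapeDescriptors:
    def test_empty_point_list(self, textured_image):
        assert shape_descriptors(textured_image, []).shape == (0, 128)

    def test_unit_norm_and_nonnegative(self, textured_image):
        points = detect_interest_points(textured_image)
        desc = shape_descriptors(textured_image, points)
        assert desc.shape == (len(points), CHANNEL_DIMS["shape"])
        assert (desc >= 0).all()
        norms = np.linalg.norm(desc, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_point_outside_image_rejected(self, textured_image):
        bad = InterestPoint(x=500.0, y=10.0, scale=2.0, orientation=0.0)
        with pytest.raises(ValueError, match="outside"):
            shape_descriptors(textured_image, [bad])

    def test_rotation_normalization(self, textured_image):
        """Rotating image and keypoint by 90 deg leaves the descriptor
        (nearly) unchanged thanks to orientation normalization."""
        w = textured_image.width
        p = InterestPoint(x=70.0, y=50.0, scale=2.5, orientation=0.7)
        d0 = shape_descriptors(textured_image, [p])[0]
        rotated = ImageRecord("rot", np.rot90(textured_image.pixels,
                                              k=1).copy())
        p_rot = InterestPoint(
            x=p.y, y=w - 1 - p.x, scale=p.scale,
            orientation=(p.orientation - math.pi / 2) % (2 * math.pi))
        d1 = shape_descriptors(rotated, [p_rot])[0]
        assert np.linalg.norm(d0 - d1) <= 0.15


class TestTextureDescriptors:
    def test_flat_patch_single_uniform_bin(self):
        img = ImageRecord("f", np.full((64, 64, 3), 77, np.uint8))
        p = InterestPoint(x=32.0, y=32.0, scale=2.0, orientation=0.0)
        hist = texture_descriptors(img, [p])[0]
        # every pixel of a flat patch carries the same uniform pattern
        assert (hist > 0).sum() == 1
        assert hist.max() == pytest.approx(1.0)

    def test_l1_normalized(self, textured_image):
        points = detect_interest_points(textured_image)[:10]
        desc = texture_descriptors(textured_image, points)
        assert desc.shape[1] == CHANNEL_DIMS["texture"]
        assert (desc >= 0).all()
        assert np.allclose(desc.sum(axis=1), 1.0, atol=1e-9)

    def test_invariant_to_intensity_shift(self, rng):
        base = gaussian_filter(rng.integers(0, 200, (64, 64)).astype(float),
                               1.0).astype(np.uint8)
        img = ImageRecord("a", _rgb(base))
        shifted = ImageRecord("b", np.clip(_rgb(base).astype(int) + 40,
                                           0, 255).astype(np.uint8))
        p = InterestPoint(x=32.0, y=32.0, scale=1.5, orientation=0.0)
        assert np.array_equal(texture_descriptors(img, [p])[0],
                              texture_descriptors(shifted, [p])[0])


class TestColourDescriptors:
    def test_pure_red_single_bin(self):
        px = np.zeros((40, 40, 3), np.uint8)
        px[:, :, 0] = 255
        img = ImageRecord("r", px)
        p = InterestPoint(x=20.0, y=20.0, scale=1.0, orientation=0.0)
        hist = colour_descriptors(img, [p])[0]
        assert hist[3 * 16 + 0 * 4 + 0] == pytest.approx(1.0)  # (R3, G0, B0)
        assert (hist > 0).sum() == 1

    def test_half_red_half_blue(self):
        px = np.zeros((40, 40, 3), np.uint8)
        px[:, :20, 0] = 255
        px[:, 20:, 2] = 255
        img = ImageRecord("rb", px)
        hist = colour_histogram_global(img)
        assert hist[48] == pytest.approx(0.5)   # (3,0,0)
        assert hist[3] == pytest.approx(0.5)    # (0,0,3)

    def test_l1_normalized(self, textured_image):
        points = detect_interest_points(textured_image)[:10]
        desc = colour_descriptors(textured_image, points)
        assert desc.shape[1] == CHANNEL_DIMS["colour"]
        assert np.allclose(desc.sum(axis=1), 1.0, atol=1e-9)


class TestGlobalColourHistogram:
    def test_all_black(self):
        img = ImageRecord("k", np.zeros((5, 5, 3), np.uint8))
        hist = colour_histogram_global(img)
        assert hist[0] == pytest.approx(1.0)

    def test_four_grey_levels(self):
        px = np.array([[0, 80], [160, 240]], np.uint8)
        img = ImageRecord("g", _rgb(px))
        hist = colour_histogram_global(img)
        for idx in (0, 21, 42, 63):   # (0,0,0),(1,1,1),(2,2,2),(3,3,3)
            assert hist[idx] == pytest.approx(0.25)

    def test_tile_additivity(self, rng):
        px = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        img = ImageRecord("t", px)
        top = colour_histogram_global(ImageRecord("a", px[:8]))
        bottom = colour_histogram_global(ImageRecord("b", px[8:]))
        assert np.allclose(colour_histogram_global(img),
                           0.5 * top + 0.5 * bottom, atol=1e-12)


class TestExtractFeatures:
    def test_channels_index_aligned(self, textured_image):
        fs = extract_features(textured_image)
        n = fs.n_points
        for mat in fs.by_channel.values():
            assert mat.shape[0] == n
            assert (mat >= 0).all()

    def test_deterministic_for_identical_bytes(self, textured_image):
        a = extract_features(textured_image)
        b = extract_features(textured_image)
        assert a.points == b.points
        for ch in a.by_channel:
            assert np.array_equal(a.by_channel[ch], b.by_channel[ch])

    def test_unknown_channel_rejected(self, textured_image):
        with pytest.raises(ValueError, match="unknown"):
            extract_features(textured_image, channels=("depth",))
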