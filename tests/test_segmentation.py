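import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from osteocount.errors import DegenerateImageError, ValidationError
from osteocount.imaging import MicroscopyImage
from osteocount.segmentation import (
    SegmentationConfig,
    SegmentLabelMap,
    distance_transform,
    extract_crops,
    filter_small_segments,
    morphological_clean,
    otsu_threshold,
    segment_centers,
    segment_image,
    select_markers,
    to_grayscale,
    watershed_segment,
)
from osteocount.synth import SceneConfig, generate_scene


# ---------------------------------------------------------------------------
# independent oracles

def otsu_bruteforce(gray):
    """Exhaustive 256-threshold scan maximizing between-class variance."""
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:  # strict: smallest maximizer wins ties
            best_t, best_v = t, v
    return best_t


def edt_bruteforce(mask):
    """Exact nearest-background Euclidean distance; virtual background border."""
    padded = np.pad(mask.astype(bool), 1, constant_values=False)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    out = np.zeros(padded.shape, float)
    if fg.size:
        out[tuple(fg.T)] = cdist(fg, bg).min(axis=1)
    return out[1:-1, 1:-1]


def dilate_bruteforce(mask):
    """Set-definition 3x3 dilation."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            src = mask[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)]
            out[max(0, dy) : h - max(0, -dy), max(0, dx) : w - max(0, -dx)] |= src
    return out


def erode_bruteforce(mask):
    return ~dilate_bruteforce(~mask)


# ---------------------------------------------------------------------------

class TestGrayscale:
    @pytest.mark.parametrize("v", [0, 1, 128, 254, 255])
    def test_equal_channels_map_to_value(self, v):
        img = np.full((4, 4, 3), v, dtype=np.uint8)
        assert (to_grayscale(img) == v).all()

    def test_pure_primaries(self):
        red = np.zeros((2, 2, 3), np.uint8)
        red[..., 0] = 255
        blue = np.zeros((2, 2, 3), np.uint8)
        blue[..., 2] = 255
        assert (to_grayscale(red) == 76).all()  # round(0.299 * 255)
        assert (to_grayscale(blue) == 29).all()  # round(0.114 * 255)


class TestOtsu:
    def test_perfect_bimodal(self):
        gray = np.full((10, 10), 200, np.uint8)
        gray[:5] = 50
        t, mask = otsu_threshold(gray)
        assert 50 <= t <= 199
        assert t == otsu_bruteforce(gray)  # smallest maximizer
        assert (mask.astype(bool) == (gray == 50)).all()

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((8, 8), 7, np.uint8))

    def test_matches_bruteforce_on_random_grids(self, rng):
        for _ in range(20):
            gray = rng.integers(0, 256, (64, 64)).astype(np.uint8)
            t, _ = otsu_threshold(gray)
            assert t == otsu_bruteforce(gray)

    def test_polarity_inverts_mask(self):
        gray = np.full((10, 10), 200, np.uint8)
        gray[:5] = 50
        _, dark = otsu_threshold(gray, polarity="dark_cells")
        _, bright = otsu_threshold(gray, polarity="bright_cells")
        assert (dark + bright == 1).all()


class TestMorphology:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), np.uint8)
        mask[4, 4] = 1
        assert not morphological_clean(mask).any()

    def test_interior_pinhole_filled(self):
        mask = np.zeros((25, 25), np.uint8)
        mask[5:20, 5:20] = 1
        mask[12, 12] = 0
        cleaned = morphological_clean(mask)
        assert cleaned[12, 12] == 1
        expected = np.zeros((25, 25), np.uint8)
        expected[5:20, 5:20] = 1
        assert np.array_equal(cleaned, expected)

    def test_matches_bruteforce_composition(self, rng):
        config = SegmentationConfig()
        for _ in range(10):
            mask = rng.random((20, 20)) < 0.45
            expected = mask.copy()
            for _ in range(config.opening_iterations):
                expected = erode_bruteforce(expected)
            for _ in range(config.opening_iterations):
                expected = dilate_bruteforce(expected)
            for _ in range(config.closing_iterations):
                expected = dilate_bruteforce(expected)
            for _ in range(config.closing_iterations):
                expected = erode_bruteforce(expected)
            assert np.array_equal(morphological_clean(mask.astype(np.uint8)), expected)


class TestDistanceTransform:
    def test_all_background_zero(self):
        assert (distance_transform(np.zeros((6, 6), np.uint8)) == 0).all()

    def test_single_pixel_distance_one(self):
        mask = np.zeros((7, 7), np.uint8)
        mask[3, 3] = 1
        dist = distance_transform(mask)
        assert dist[3, 3] == 1.0
        assert (dist[mask == 0] == 0).all()

    def test_solid_square_matches_bruteforce(self):
        mask = np.zeros((31, 31), np.uint8)
        mask[8:23, 8:23] = 1
        assert np.allclose(distance_transform(mask), edt_bruteforce(mask))

    def test_random_masks_match_bruteforce(self, rng):
        for density in (0.2, 0.5, 0.8):
            for _ in range(8):
                mask = rng.random((32, 32)) < density
                assert np.allclose(distance_transform(mask), edt_bruteforce(mask))

    def test_all_foreground_uses_virtual_border(self):
        mask = np.ones((8, 8), np.uint8)
        dist = distance_transform(mask)
        assert np.allclose(dist, edt_bruteforce(mask))
        assert dist[0, 0] == 1.0 and dist[4, 4] == 4.0  # min(4+1, 8-4)


def disc_mask(shape, cy, cx, r):
    yy, xx = np.indices(shape)
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2).astype(np.uint8)


class TestMarkers:
    def test_two_separated_discs_two_markers(self):
        mask = disc_mask((64, 64), 16, 16, 8) | disc_mask((64, 64), 48, 48, 8)
        dist = distance_transform(mask)
        markers = select_markers(dist, cleaned_mask=mask)
        assert markers.max() == 3  # labels 2 and 3
        assert (markers == 1).any()  # sure background present

    def test_empty_mask_no_markers(self):
        mask = np.zeros((32, 32), np.uint8)
        markers = select_markers(distance_transform(mask), cleaned_mask=mask)
        assert markers.max() == 1  # only the background marker

    def test_disc_marker_equals_bruteforce_superlevel_set(self):
        # one 41-px-wide disc: marker region is the 0.7-of-max superlevel set
        mask = disc_mask((64, 64), 32, 32, 20)
        dist_oracle = edt_bruteforce(mask)
        markers = select_markers(distance_transform(mask), cleaned_mask=mask)
        expected = dist_oracle >= 0.7 * dist_oracle.max()
        assert np.array_equal(markers >= 2, expected)
        _, n = ndi.label(markers >= 2, structure=np.ones((3, 3), bool))
        assert n == 1

    def test_image_scope_misses_small_cells(self):
        """Thresholding at 0.7 of the whole-image maximum loses cells much
        smaller than the largest one; the per-component scope keeps them."""
        mask = disc_mask((128, 128), 40, 40, 30) | disc_mask((128, 128), 100, 100, 10)
        dist = distance_transform(mask)
        cfg_img = SegmentationConfig(marker_scope="image")
        markers_img = select_markers(dist, cleaned_mask=mask, config=cfg_img)
        markers_comp = select_markers(dist, cleaned_mask=mask)
        assert markers_img.max() == 2  # only the big disc gets a marker
        assert markers_comp.max() == 3  # both discs marked


def scene_image(mask, dark=120, light=240):
    px = np.full((*mask.shape, 3), light, np.uint8)
    px[mask.astype(bool)] = dark
    return MicroscopyImage(px)


class TestWatershed:
    def test_one_blob_one_marker_one_segment(self):
        mask = disc_mask((64, 64), 32, 32, 14)
        dist = distance_transform(mask)
        markers = select_markers(dist, cleaned_mask=mask)
        segments = watershed_segment(scene_image(mask), markers, dist)
        assert segments.segment_ids() == [1]
        covered = segments.labels[mask.astype(bool)]
        assert ((covered == 1) | (covered == -1)).all()

    def test_no_markers_all_background(self):
        mask = np.zeros((50, 50), np.uint8)
        markers = select_markers(distance_transform(mask), cleaned_mask=mask)
        segments = watershed_segment(scene_image(mask), markers, distance_transform(mask))
        assert (segments.labels == 0).all()

    def test_touching_discs_split_by_boundary(self):
        mask = disc_mask((64, 96), 32, 34, 16) | disc_mask((64, 96), 32, 60, 16)
        dist = distance_transform(mask)
        markers = select_markers(dist, cleaned_mask=mask)
        segments = watershed_segment(scene_image(mask), markers, dist)
        assert len(segments.segment_ids()) == 2
        assert (segments.labels == -1).any()
        assert segments.labels[32, 34] != segments.labels[32, 60]
        assert segments.labels[32, 34] > 0 and segments.labels[32, 60] > 0

    def test_partition_and_marker_preservation(self, default_scene):
        _, image, _ = default_scene
        from osteocount.segmentation import morphological_clean, otsu_threshold

        _, mask = otsu_threshold(to_grayscale(image))
        cleaned = morphological_clean(mask)
        dist = distance_transform(cleaned)
        markers = select_markers(dist, cleaned_mask=cleaned)
        segments = watershed_segment(image, markers, dist)
        labels = segments.labels
        ids = segments.segment_ids()
        # tiling: only {0, -1, 1..K}
        assert set(np.unique(labels)) <= ({0, -1} | set(ids))
        # marker pixels keep their label
        for marker_id in range(2, markers.max() + 1):
            assert (labels[markers == marker_id] == marker_id - 1).all()
        assert (labels[markers == 1] == 0).all()
        # each segment is one 8-connected region
        for seg_id in ids:
            _, n = ndi.label(labels == seg_id, structure=np.ones((3, 3), bool))
            assert n == 1


class TestFilter:
    @staticmethod
    def rectangles_label_map(areas):
        h = 40
        width = sum(a // 20 + 2 for a in areas) + 2
        labels = np.zeros((h, width), np.int32)
        x = 1
        for i, area in enumerate(areas, start=1):
            w = area // 20
            labels[2 : 2 + 20, x : x + w] = i
            assert (labels == i).sum() == area
            x += w + 2
        return SegmentLabelMap(labels)

    def test_strictly_less_than_rule(self):
        # areas {499, 500, 1200}: 500 survives the "less than 500" filter
        labels = np.pad(self.rectangles_label_map([500, 1200]).labels,
                        ((0, 2), (0, 500)), constant_values=0)
        labels[-1, :499] = 3
        retained, removed = filter_small_segments(SegmentLabelMap(labels), 500)
        assert removed == [(3, 499)]
        assert sorted(retained.areas().values()) == [500, 1200]

    def test_empty_map(self):
        retained, removed = filter_small_segments(
            SegmentLabelMap(np.zeros((10, 10), np.int32)), 500
        )
        assert retained.areas() == {} and removed == []

    def test_conservation_pixel_exact(self, default_scene):
        _, image, _ = default_scene
        from osteocount.segmentation import morphological_clean, otsu_threshold

        _, mask = otsu_threshold(to_grayscale(image))
        cleaned = morphological_clean(mask)
        dist = distance_transform(cleaned)
        markers = select_markers(dist, cleaned_mask=cleaned)
        segments = watershed_segment(image, markers, dist)
        pre_areas = segments.areas()
        retained, removed = filter_small_segments(segments, 500)
        total = sum(retained.areas().values()) + sum(a for _, a in removed)
        assert total == sum(pre_areas.values())

    def test_shattered_cell_keeps_largest_piece(self):
        """A big cell split into many pieces keeps only the >=500-px piece."""
        labels = np.zeros((60, 100), np.int32)
        labels[5:35, 5:35] = 1  # 900 px "largest piece"
        x = 2
        for i in range(2, 13):  # 11 small shards
            labels[40:48, x : x + 5] = i
            x += 7
        retained, removed = filter_small_segments(SegmentLabelMap(labels), 500)
        assert retained.segment_ids() == [1]
        assert len(removed) == 11


class TestCentersAndCrops:
    def test_symmetric_square_center(self):
        labels = np.zeros((10, 10), np.int32)
        labels[4:7, 4:7] = 1
        assert segment_centers(SegmentLabelMap(labels)) == [(1, 5, 5)]

    def test_single_pixel_center(self):
        labels = np.zeros((10, 10), np.int32)
        labels[2, 7] = 1  # row y=2, col x=7
        assert segment_centers(SegmentLabelMap(labels)) == [(1, 7, 2)]

    def test_l_shape_center_is_coordinate_mean(self):
        labels = np.zeros((10, 10), np.int32)
        pixels = [(1, 1), (2, 1), (3, 1), (3, 2), (3, 3)]
        for r, c in pixels:
            labels[r, c] = 1
        xs = [c for _, c in pixels]
        ys = [r for r, _ in pixels]
        expected = (
            int(np.floor(np.mean(xs) + 0.5)),
            int(np.floor(np.mean(ys) + 0.5)),
        )
        assert segment_centers(SegmentLabelMap(labels)) == [(1, *expected)]

    def test_interior_crop_equals_window(self, rng):
        pixels = rng.integers(0, 256, (100, 100, 3), dtype=np.uint8)
        image = MicroscopyImage(pixels)
        (crop,) = extract_crops(image, [(1, 25, 25)])
        assert np.array_equal(crop.pixels, pixels[0:50, 0:50])

    def test_corner_crop_uses_reflection(self, rng):
        pixels = rng.integers(0, 256, (100, 100, 3), dtype=np.uint8)
        (crop,) = extract_crops(MicroscopyImage(pixels), [(1, 0, 0)])
        assert crop.pixels.shape == (50, 50, 3)
        # the in-image quadrant is copied verbatim
        assert np.array_equal(crop.pixels[25:, 25:], pixels[0:25, 0:25])

    def test_gradient_crop_index_bookkeeping(self):
        yy, xx = np.indices((120, 120))
        pixels = np.stack([(yy % 256), (xx % 256), np.zeros_like(yy)], axis=2).astype(
            np.uint8
        )
        (crop,) = extract_crops(MicroscopyImage(pixels), [(1, 60, 40)])
        for i, j in [(0, 0), (10, 30), (49, 49)]:
            assert crop.pixels[i, j, 0] == (40 - 25 + i) % 256
            assert crop.pixels[i, j, 1] == (60 - 25 + j) % 256

    def test_center_outside_image_rejected(self, rng):
        image = MicroscopyImage(rng.integers(0, 256, (60, 60, 3), dtype=np.uint8))
        with pytest.raises(ValidationError):
            extract_crops(image, [(1, 60, 10)])


class TestSegmentImage:
    def test_scene_above_filter_yields_one_crop_per_cell(self, default_scene):
        _, image, truth = default_scene
        _, crops = segment_image(image)
        assert len(crops) == len(truth.cells)

    def test_debris_only_scene_yields_no_crops(self):
        config = SceneConfig(n_osteoclasts=0, n_non_osteoclasts=0, n_debris=3, seed=2)
        image, truth = generate_scene(config)
        assert len(truth.debris) == 3
        _, crops = segment_image(image)
        assert crops == []

    def test_blank_background_yields_no_crops(self):
        config = SceneConfig(
            n_osteoclasts=0, n_non_osteoclasts=0, n_debris=0, noise_sd=0.0, seed=0
        )
        image, _ = generate_scene(config)
        _, crops = segment_image(image)
        assert crops == []

    def test_touching_pair_split_into_two_segments(self):
        config = SceneConfig(
            n_osteoclasts=2,
            n_non_osteoclasts=0,
            n_debris=0,
            touching_pairs=1,
            oc_radius=(20.0, 24.0),
            seed=5,
        )
        image, truth = generate_scene(config)
        segments, crops = segment_image(image)
        assert len(crops) == 2
        seg_at = {
            segments.labels[c.center[1], c.center[0]] for c in truth.cells
        }
        assert len(seg_at) == 2 and 0 not in seg_at and -1 not in seg_at


def test_config_validation():
    with pytest.raises(ValidationError):
        SegmentationConfig(marker_fraction=0.0)
    with pytest.raises(ValidationError):
        SegmentationConfig(crop_size=49)
    with pytest.raises(ValidationError):
        SegmentationConfig(marker_scope="per-blob")
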