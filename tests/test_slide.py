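import numpy as np
import pytest
from skimage.color import rgb2hsv

from lcmil import (
    AlignmentError,
    BinaryMask,
    ConfigError,
    DegenerateInputError,
    SlideImage,
    StateError,
    assemble_score_map,
    assign_noisy_labels,
    compute_tissue_mask_hsv,
    compute_tissue_mask_rgb,
    extract_patch_grid,
)


def _brute_otsu(values: np.ndarray) -> float:
    """Exhaustive between-class-variance maximization on a 256-bin histogram."""
    counts, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_t = -1.0, centers[0]
    for k in range(255):
        w0, w1 = counts[: k + 1].sum(), counts[k + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best:
            best, best_t = v, centers[k]
    return best_t


class TestTissueMasks:
    def test_hsv_mask_finds_saturated_square(self):
        px = np.full((64, 64, 3), 255, dtype=np.uint8)
        px[20:40, 10:30] = (230, 60, 140)  # saturated pink square
        mask = compute_tissue_mask_hsv(SlideImage(px))
        expected = np.zeros((64, 64), dtype=bool)
        expected[20:40, 10:30] = True
        np.testing.assert_array_equal(mask.values, expected)

    def test_hsv_mask_matches_per_channel_otsu_and(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, size=(40, 40, 3), dtype=np.uint8)
        mask = compute_tissue_mask_hsv(SlideImage(px))
        hsv = rgb2hsv(px)
        expected = (hsv[..., 0] > _brute_otsu(hsv[..., 0])) & (
            hsv[..., 1] > _brute_otsu(hsv[..., 1])
        )
        np.testing.assert_array_equal(mask.values, expected)

    def test_hsv_mask_rejects_constant_image(self):
        px = np.zeros((32, 32, 3), dtype=np.uint8)
        with pytest.raises(DegenerateInputError):
            compute_tissue_mask_hsv(SlideImage(px))

    @pytest.mark.parametrize(
        "pixel,expected",
        [((255, 255, 255), False), ((0, 0, 0), True), ((235, 210, 235), False),
         ((234, 209, 234), True)],
    )
    def test_rgb_threshold_is_strict(self, pixel, expected):
        px = np.full((4, 4, 3), pixel, dtype=np.uint8)
        mask = compute_tissue_mask_rgb(SlideImage(px))
        assert mask.values.all() == expected

    def test_rgb_threshold_range_checked(self):
        px = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(ConfigError):
            compute_tissue_mask_rgb(SlideImage(px), thresholds=(300, 0, 0))


class TestPatchGrid:
    def _slide(self, h, w, fill=100):
        return SlideImage(np.full((h, w, 3), fill, dtype=np.uint8))

    def test_exact_tiling(self):
        pset = extract_patch_grid(self._slide(512, 512), None, 256)
        assert sorted(map(tuple, pset.coords)) == [(0, 0), (0, 256), (256, 0), (256, 256)]

    def test_overlap_075_gives_stride_64(self):
        pset = extract_patch_grid(self._slide(512, 512), None, 256, overlap_fraction=0.75)
        assert pset.stride == 64

    def test_partial_patches_not_emitted(self):
        pset = extract_patch_grid(self._slide(300, 300), None, 256)
        assert len(pset) == 1 and tuple(pset.coords[0]) == (0, 0)

    def test_non_integer_stride_rejected(self):
        with pytest.raises(ConfigError):
            extract_patch_grid(self._slide(512, 512), None, 256, overlap_fraction=0.3)

    def test_center_rule_against_brute_force(self, rng):
        """Grid completeness: emitted patches = lattice positions whose center is tissue."""
        for _ in range(10):
            h, w = rng.integers(40, 90, size=2)
            p = int(rng.choice([8, 16]))
            tissue = BinaryMask(rng.random((h, w)) < 0.5, role="tissue")
            slide = self._slide(h, w)
            pset = extract_patch_grid(slide, tissue, p)
            expected = {
                (r, c)
                for r in range(0, h - p + 1, p)
                for c in range(0, w - p + 1, p)
                if tissue.values[r + p // 2, c + p // 2]
            }
            assert set(map(tuple, pset.coords)) == expected

    def test_determinism(self):
        slide = self._slide(128, 128)
        a = extract_patch_grid(slide, None, 32)
        b = extract_patch_grid(slide, None, 32)
        np.testing.assert_array_equal(a.coords, b.coords)


class TestLabelAssignment:
    def test_center_rule_and_partition(self):
        slide = SlideImage(np.zeros((128, 128, 3), dtype=np.uint8))
        pset = extract_patch_grid(slide, None, 64)
        coarse = np.zeros((128, 128), dtype=bool)
        coarse[:64, :64] = True  # covers patch (0,0) center at (32,32)
        labeled = assign_noisy_labels(pset, BinaryMask(coarse))
        assert labeled.noisy_labels.tolist() == [1, 0, 0, 0]
        assert len(labeled.positive_ids) + len(labeled.negative_ids) == len(labeled)

    def test_center_one_pixel_outside_is_negative(self):
        slide = SlideImage(np.zeros((64, 64, 3), dtype=np.uint8))
        pset = extract_patch_grid(slide, None, 64)  # single patch, center (32,32)
        coarse = np.zeros((64, 64), dtype=bool)
        coarse[:32, :] = True  # rows 0..31: center just outside
        assert assign_noisy_labels(pset, BinaryMask(coarse)).noisy_labels[0] == 0
        coarse[32, :] = True  # now includes the center row
        assert assign_noisy_labels(pset, BinaryMask(coarse)).noisy_labels[0] == 1

    def test_all_false_mask(self):
        slide = SlideImage(np.zeros((128, 128, 3), dtype=np.uint8))
        pset = extract_patch_grid(slide, None, 32)
        labeled = assign_noisy_labels(pset, BinaryMask(np.zeros((128, 128), bool)))
        assert len(labeled.positive_ids) == 0
        assert len(labeled.negative_ids) == len(labeled)

    def test_shape_mismatch(self):
        slide = SlideImage(np.zeros((64, 64, 3), dtype=np.uint8))
        pset = extract_patch_grid(slide, None, 32)
        with pytest.raises(AlignmentError):
            assign_noisy_labels(pset, BinaryMask(np.zeros((32, 32), bool)))


class TestScoreMap:
    def test_row_major_placement(self):
        slide = SlideImage(np.zeros((128, 128, 3), dtype=np.uint8))
        pset = extract_patch_grid(slide, None, 64).with_scores(
            np.array([0.1, 0.2, 0.3, 0.4])
        )
        smap = assemble_score_map(pset)
        np.testing.assert_allclose(smap.scores, [[0.1, 0.2], [0.3, 0.4]])

    def test_overlap_map_stride_is_quarter_patch(self):
        slide = SlideImage(np.zeros((256, 512, 3), dtype=np.uint8))
        pset = extract_patch_grid(slide, None, 256, overlap_fraction=0.75)
        smap = assemble_score_map(pset.with_scores(np.zeros(len(pset))))
        assert smap.stride == 64

    def test_round_trip_cell_coordinates(self):
        slide = SlideImage(np.zeros((96, 96, 3), dtype=np.uint8))
        pset = extract_patch_grid(slide, None, 32)
        pset = pset.with_scores(np.arange(len(pset)) / len(pset))
        smap = assemble_score_map(pset)
        for i, (r, c) in enumerate(pset.coords):
            assert smap.scores[smap.cell_of(r, c)] == pset.scores[i]

    def test_missing_cells_are_nan(self):
        slide = SlideImage(np.zeros((64, 64, 3), dtype=np.uint8))
        tissue = np.zeros((64, 64), bool)
        tissue[:32, :32] = True  # only patch (0,0) has a tissue center
        pset = extract_patch_grid(slide, BinaryMask(tissue, role="tissue"), 32)
        smap = assemble_score_map(pset.with_scores(np.full(len(pset), 0.7)))
        assert smap.scores[0, 0] == 0.7
        assert np.isnan(smap.scores).sum() == smap.scores.size - len(pset)

    def test_unscored_patches_rejected(self):
        slide = SlideImage(np.zeros((64, 64, 3), dtype=np.uint8))
        pset = extract_patch_grid(slide, None, 32)
        with pytest.raises(StateError):
            assemble_score_map(pset)
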