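"""Unit and property tests for the image-quantification primitives."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortiquant import (
    DataError,
    DegenerateHistogramError,
    ImageGenConfig,
    NoTissueError,
    cell_density,
    entropy_threshold,
    excess_red,
    generate_ihc_image,
    quantify_image,
    segment_cells,
    tissue_mask,
)
from cortiquant.ihc import CellSegmenter, TissueSegmenter

from conftest import (
    bimodal_gray,
    count_components_8,
    flat_rgb,
    kapur_bruteforce,
    random_gray,
)

DAB = (130, 85, 60)
TISSUE = (70, 80, 150)
WHITE = (245, 245, 245)


class TestExcessRed:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((100, 100, 100), 0),  # achromatic: 2R - B - G vanishes
            ((255, 0, 0), 255),  # 510 clamped to the 8-bit ceiling
            ((150, 60, 40), 200),  # 300 - 60 - 40
            ((0, 255, 255), 0),  # negative excess clamps to 0
        ],
    )
    def test_single_pixel(self, rgb, expected):
        img = flat_rgb((1, 1), rgb)
        assert excess_red(img)[0, 0] == expected

    @settings(deadline=None, derandomize=True)
    @given(v=st.integers(0, 255))
    def test_achromatic_is_zero(self, v):
        img = flat_rgb((3, 3), (v, v, v))
        assert np.all(excess_red(img) == 0)

    def test_output_bounded(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        e = excess_red(img)
        assert e.dtype == np.uint8
        assert e.min() >= 0 and e.max() <= 255

    def test_rejects_wrong_shape(self):
        with pytest.raises(DataError):
            excess_red(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(DataError):
            excess_red(np.zeros((4, 4, 4), dtype=np.uint8))


class TestEntropyThreshold:
    def test_constant_image_raises(self):
        with pytest.raises(DegenerateHistogramError):
            entropy_threshold(np.full((8, 8), 77, dtype=np.uint8))

    def test_two_valued_tie_breaks_low(self):
        # 50/50 at levels 40 and 200: every split between them has the
        # same criterion value; the lowest maximiser must be returned.
        g = np.array([40] * 50 + [200] * 50, dtype=np.uint8).reshape(10, 10)
        t = entropy_threshold(g)
        assert t == kapur_bruteforce(g)
        assert t == 40

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_random(self, seed):
        g = random_gray(np.random.default_rng(seed))
        assert entropy_threshold(g) == kapur_bruteforce(g)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_bimodal(self, seed):
        g = bimodal_gray(np.random.default_rng(1000 + seed))
        assert entropy_threshold(g) == kapur_bruteforce(g)


class TestSegmentCells:
    def test_artifact_removal(self):
        """One ~100 px^2 cell plus five 3 px^2 specks: only the cell
        survives small-object removal."""
        img = flat_rgb((64, 64), TISSUE)
        rr, cc = np.mgrid[0:64, 0:64]
        cell = (rr - 20) ** 2 + (cc - 20) ** 2 <= 5.6**2  # ~100 px
        img[cell] = DAB
        for i, (r, c) in enumerate([(5, 50), (40, 8), (50, 50), (10, 30), (55, 20)]):
            img[r, c : c + 3] = DAB  # 1x3 speck
        mask = segment_cells(img, min_object_area=10, opening_radius=1)
        assert count_components_8(mask) == 1

    def test_blank_input_returns_empty_mask(self, caplog):
        img = flat_rgb((16, 16), TISSUE)  # pure blue tissue, no DAB
        with caplog.at_level(logging.WARNING, logger="cortiquant.ihc"):
            mask, t = segment_cells(img, return_threshold=True)
        assert not mask.any()
        assert t is None
        assert any("blank input" in r.message for r in caplog.records)

    def test_no_small_components_survive(self):
        img, _ = generate_ihc_image(ImageGenConfig(n_cells=40, seed=3))
        min_area = 20
        mask = segment_cells(img, min_object_area=min_area)
        from scipy import ndimage

        lab, n = ndimage.label(mask, structure=np.ones((3, 3), int))
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            assert sizes.min() >= min_area

    def test_overlap_with_truth(self, small_image):
        img, truth = small_image
        mask = segment_cells(img)
        jac = (mask & truth.cell_mask).sum() / (mask | truth.cell_mask).sum()
        assert jac >= 0.7

    def test_transformer_api(self, small_image):
        from sklearn.base import clone

        img, _ = small_image
        seg = CellSegmenter(min_object_area=20, opening_radius=1)
        seg2 = clone(seg)
        assert seg2.get_params() == seg.get_params()
        mask = seg.transform(img)
        assert mask.shape == img.shape[:2]
        masks = seg.transform([img, img])
        assert np.array_equal(masks[0], masks[1])


class TestTissueMask:
    def test_blue_disc_on_white(self):
        img = flat_rgb((64, 64), (255, 255, 255))
        rr, cc = np.mgrid[0:64, 0:64]
        disc = (rr - 32) ** 2 + (cc - 32) ** 2 <= 20**2
        img[disc] = TISSUE
        mask = tissue_mask(img)
        assert (mask & disc).sum() / disc.sum() > 0.99
        assert (mask & ~disc).sum() < 0.01 * disc.sum()

    def test_all_white_raises(self):
        with pytest.raises(DegenerateHistogramError):
            tissue_mask(flat_rgb((16, 16), (255, 255, 255)))

    def test_full_frame_tissue(self):
        cfg = ImageGenConfig(n_cells=60, tissue_fraction=1.0, seed=5)
        img, truth = generate_ihc_image(cfg)
        mask = tissue_mask(img)
        true_area = truth.tissue_mask.sum()
        assert abs(int(mask.sum()) - int(true_area)) <= 0.05 * true_area

    def test_transformer_api(self, small_image):
        img, truth = small_image
        mask = TissueSegmenter().fit().transform(img)
        assert mask.shape == img.shape[:2]


class TestCellDensity:
    def test_empty_cells_gives_zero(self):
        tissue = np.ones((8, 8), bool)
        res = cell_density(np.zeros((8, 8), bool), tissue)
        assert res.density == 0.0
        assert res.tissue_area == 64

    def test_cells_equal_tissue_gives_one(self):
        m = np.ones((5, 5), bool)
        assert cell_density(m, m).density == 1.0

    def test_empty_tissue_raises(self):
        with pytest.raises(NoTissueError):
            cell_density(np.ones((4, 4), bool), np.zeros((4, 4), bool))

    def test_shape_mismatch_raises(self):
        with pytest.raises(DataError):
            cell_density(np.ones((4, 4), bool), np.ones((4, 5), bool))

    def test_only_intersection_counts(self):
        cells = np.zeros((4, 4), bool)
        cells[0, :] = True  # 4 px, half outside tissue
        tissue = np.zeros((4, 4), bool)
        tissue[:, :2] = True  # 8 px
        res = cell_density(cells, tissue)
        assert res.cell_area == 2
        assert res.density == 2 / 8

    def test_scale_invariance(self, small_image):
        """Nearest-neighbour 2x upsampling leaves the density unchanged."""
        img, _ = small_image
        res, cmask, tmask = quantify_image(img, return_masks=True)
        up = np.ones((2, 2), bool)
        res2 = cell_density(np.kron(cmask, up), np.kron(tmask, up))
        assert res2.density == pytest.approx(res.density, abs=0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_under_added_cell_pixels(self, seed):
        r = np.random.default_rng(seed)
        tissue = r.random((12, 12)) < 0.8
        tissue[0, 0] = True
        cells = tissue & (r.random((12, 12)) < 0.3)
        base = cell_density(cells, tissue).density
        extra = cells | (tissue & (r.random((12, 12)) < 0.2))
        assert cell_density(extra, tissue).density >= base


def test_quantify_density_close_to_truth(small_image):
    img, truth = small_image
    res = quantify_image(img)
    assert res.density == pytest.approx(truth.true_density, abs=0.02)
    assert 0.0 <= res.density <= 1.0
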