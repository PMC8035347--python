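import numpy as np
import pytest

from fish3d.config import MATCH_METHODS, RunConfig
from fish3d.segmentation import (
    TemplateSet,
    connected_components,
    ellipse_template,
    link_3d,
    match_template,
    segment_layer,
)
from oracles import flood_fill_components, match_score_direct


class TestMatchTemplateExamples:
    """Worked 2×2 self-match examples with hand-computed scores."""

    I = np.array([[1.0, 2.0], [3.0, 4.0]])

    def test_exact_match_square_difference_is_zero(self):
        r = match_template(self.I, self.I, "SD")
        assert r.scores.shape == (1, 1)
        assert r.scores[0, 0] == pytest.approx(0.0)

    def test_cross_correlation_is_thirty(self):
        assert match_template(self.I, self.I, "C").scores[0, 0] == pytest.approx(30.0)

    def test_normalized_cross_correlation_is_one(self):
        assert match_template(self.I, self.I, "NC").scores[0, 0] == pytest.approx(1.0)

    def test_correlation_coefficient_is_five(self):
        # mean 2.5 -> T' = I' = [[-1.5,-0.5],[0.5,1.5]], sum of squares = 5
        assert match_template(self.I, self.I, "CC").scores[0, 0] == pytest.approx(5.0)

    def test_normalized_correlation_coefficient_is_one(self):
        assert match_template(self.I, self.I, "NcC").scores[0, 0] == pytest.approx(1.0)


class TestMatchTemplateOracle:
    @pytest.mark.parametrize("method", MATCH_METHODS)
    def test_random_instances_match_direct_summation(self, method):
        rng = np.random.default_rng(7)
        for _ in range(100):
            H, W = rng.integers(5, 13, size=2)
            h = int(rng.integers(1, min(6, H + 1)))
            w = int(rng.integers(1, min(6, W + 1)))
            I = rng.random((H, W)) * 10
            T = rng.random((h, w)) * 10
            got = match_template(I, T, method).scores
            want = match_score_direct(I, T, method)
            assert got.shape == (H - h + 1, W - w + 1)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    def test_result_matrix_shape(self, rng):
        r = match_template(rng.random((20, 30)), rng.random((5, 7)), "NcC")
        assert r.scores.shape == (16, 24)

    def test_score_ranges(self, rng):
        I = rng.random((15, 15)) * 100
        T = rng.random((4, 4)) * 100
        assert np.all(match_template(I, T, "SD").scores >= 0)
        assert np.all(match_template(I, T, "NSD").scores >= 0)
        nc = match_template(I, T, "NC").scores
        assert np.all(nc >= 0) and np.all(nc <= 1 + 1e-12)
        ncc = match_template(I, T, "NcC").scores
        assert np.all(ncc >= -1 - 1e-12) and np.all(ncc <= 1 + 1e-12)

    def test_ncc_matches_skimage(self, rng):
        from skimage.feature import match_template as sk_match

        I = rng.random((30, 30))
        T = rng.random((8, 8))
        ours = match_template(I, T, "NcC").scores
        theirs = sk_match(I, T, pad_input=False)
        np.testing.assert_allclose(ours, theirs, atol=1e-7)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="larger"):
            match_template(rng.random((3, 3)), rng.random((5, 5)), "NcC")
        with pytest.raises(ValueError, match="unknown"):
            match_template(rng.random((5, 5)), rng.random((2, 2)), "XX")

    def test_degenerate_window_gets_worst_score(self):
        I = np.zeros((6, 6))  # all windows have zero energy
        T = np.ones((3, 3))
        assert np.all(match_template(I, T, "NcC").scores == -1.0)
        assert np.all(match_template(I, T, "NC").scores == 0.0)


class TestMethodAgreement:
    """On a clean, exact-template image all six methods find the same peak."""

    def test_six_methods_agree_on_exact_fixture(self):
        img = np.zeros((60, 60))
        tpl = ellipse_template(10, 7, 20.0)
        img[15 : 15 + tpl.shape[0], 20 : 20 + tpl.shape[1]] = tpl * 100
        img += 1.0  # offset so normalized denominators never vanish at the peak
        peaks = {}
        for method in MATCH_METHODS:
            r = match_template(img, tpl * 100 + 1.0, method).scores
            idx = np.argmin(r) if method in ("SD", "NSD") else np.argmax(r)
            peaks[method] = np.unravel_index(idx, r.shape)
        assert len(set(peaks.values())) == 1
        assert peaks["NcC"] == (15, 20)


class TestSegmentLayer:
    def test_blank_layer_gives_empty_mask(self, config):
        templates = TemplateSet.parametric(config)
        mask = segment_layer(np.zeros((80, 80)), templates, config)
        assert mask.sum() == 0

    def test_single_ellipse_is_segmented(self, config):
        tpl = ellipse_template(3.0 / 0.16, 3.0 / 0.16)  # 3 μm circle
        img = np.full((120, 120), 100.0)
        y0, x0 = 40, 45
        img[y0 : y0 + tpl.shape[0], x0 : x0 + tpl.shape[1]] += tpl * 5000
        templates = TemplateSet.parametric(config)
        mask = segment_layer(img, templates, config)
        inside = tpl > 0.5
        covered = mask[y0 : y0 + tpl.shape[0], x0 : x0 + tpl.shape[1]][inside]
        assert covered.mean() > 0.9  # nearly the whole ellipse is foreground
        assert mask.sum() < inside.sum() * 1.5  # and little beyond it

    def test_two_disjoint_nuclei_give_two_regions(self, config):
        from scipy import ndimage

        tpl = ellipse_template(3.0 / 0.16, 3.0 / 0.16)
        img = np.full((150, 150), 100.0)
        for y0, x0 in [(20, 20), (90, 90)]:
            img[y0 : y0 + tpl.shape[0], x0 : x0 + tpl.shape[1]] += tpl * 5000
        mask = segment_layer(img, TemplateSet.parametric(config), config)
        _, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == 2


class TestConnectedComponents:
    def test_empty_mask(self):
        labels = connected_components(np.zeros((10, 10), bool))
        assert labels.max() == 0

    def test_two_blocks_get_labels_one_and_two(self):
        mask = np.zeros((20, 20), bool)
        mask[2:7, 2:7] = True
        mask[12:17, 12:17] = True
        labels = connected_components(mask, min_size=1)
        assert set(np.unique(labels)) == {0, 1, 2}
        assert labels[2, 2] == 1  # raster order: top-left block first
        assert labels[12, 12] == 2

    def test_single_pixel_erased_by_min_size(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert connected_components(mask, min_size=2).max() == 0

    def test_matches_flood_fill_on_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            mask = rng.random((25, 25)) > 0.6
            min_size = int(rng.integers(1, 5))
            labels = connected_components(mask, min_size)
            want = flood_fill_components(mask, min_size)
            got = [
                set(zip(*np.nonzero(labels == lbl)))
                for lbl in range(1, labels.max() + 1)
            ]
            assert len(got) == len(want)
            assert {frozenset(c) for c in got} == {frozenset(c) for c in want}

    def test_diagonal_pixels_are_one_component(self):
        mask = np.eye(5, dtype=bool)
        labels = connected_components(mask)
        assert labels.max() == 1


class TestLink3D:
    def _labels(self, masks):
        out = []
        for m in masks:
            out.append(connected_components(m, min_size=1))
        return out

    def test_identical_component_on_all_layers_is_one_nucleus(self, config):
        m = np.zeros((30, 30), bool)
        m[10:20, 10:20] = True
        nuclei = link_3d(self._labels([m] * 7), config)
        assert len(nuclei) == 1
        assert nuclei[0].layer_span == (0, 6)
        assert nuclei[0].qc == "clear"

    def test_zero_overlap_components_stay_separate(self, config):
        a = np.zeros((30, 30), bool)
        a[2:8, 2:8] = True
        b = np.zeros((30, 30), bool)
        b[20:26, 20:26] = True
        nuclei = link_3d(self._labels([a, b]), config)
        assert len(nuclei) == 2

    def test_border_touching_nucleus_is_discarded(self, config):
        m = np.zeros((30, 30), bool)
        m[5:12, 0:6] = True  # touches column 0
        (n,) = link_3d(self._labels([m]), config)
        assert n.qc == "discarded"
        assert n.discard_reason == "border"

    def test_projection_overlap_discards_both(self, config):
        a = np.zeros((30, 30), bool)
        a[5:15, 5:15] = True
        b = np.zeros((30, 30), bool)
        b[12:22, 12:22] = True  # overlaps a's footprint but on another layer
        blank = np.zeros((30, 30), bool)
        nuclei = link_3d(self._labels([a, blank, b]), config)
        assert len(nuclei) == 2
        assert all(n.qc == "discarded" and n.discard_reason == "overlap" for n in nuclei)

    def test_volume_bounds_discard(self):
        cfg = RunConfig(nucleus_volume_bounds=(1, 50))
        m = np.zeros((30, 30), bool)
        m[5:15, 5:15] = True  # 100 px > 50
        (n,) = link_3d([connected_components(m)], cfg)
        assert n.qc == "discarded" and n.discard_reason == "size"

    def test_centroid_is_in_um(self, config):
        m = np.zeros((30, 30), bool)
        m[10:12, 14:16] = True  # centroid at (14.5, 10.5) px
        (n,) = link_3d([connected_components(m)], config)
        assert n.centroid_um[0] == pytest.approx(14.5 * 0.16)
        assert n.centroid_um[1] == pytest.approx(10.5 * 0.16)
        assert n.centroid_um[2] == pytest.approx(0.0)
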