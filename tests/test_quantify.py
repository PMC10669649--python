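"""Depth/volume formulas, hemi-cervix split, and the group t-test."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import special

import necrovol as nv
from necrovol.segmentation import LabelMasks

DEFAULT = nv.StackGeometry()


class TestDepthFormula:
    @pytest.mark.parametrize(
        "n, expected",
        [(0, 0.0), (1, 0.02), (25, 12.5), (34, 17.18), (50, 25.5)],
    )
    def test_depth_values(self, n, expected):
        assert nv.necrosis_depth(n, DEFAULT) == pytest.approx(expected, abs=1e-12)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            nv.necrosis_depth(2.5, DEFAULT)
        with pytest.raises(ValueError):
            nv.necrosis_depth(-1, DEFAULT)

    @given(st.integers(min_value=1, max_value=200))
    def test_constant_increment(self, n):
        """Depth grows by exactly thickness + spacing per extra section."""
        step = nv.necrosis_depth(n + 1, DEFAULT) - nv.necrosis_depth(n, DEFAULT)
        assert step == pytest.approx(DEFAULT.slab_mm)


class TestVolumeFormula:
    def test_hand_evaluations(self):
        assert nv.necrosis_volume([10.0] * 10, DEFAULT) == pytest.approx(47.0)
        assert nv.necrosis_volume([1.0], DEFAULT) == pytest.approx(0.02)
        assert nv.necrosis_volume([], DEFAULT) == 0.0

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            nv.necrosis_volume([1.0, -0.1], DEFAULT)

    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=40),
        st.floats(min_value=0.1, max_value=10),
    )
    def test_linearity_in_areas(self, areas, c):
        """Scaling all areas by c scales the volume by c."""
        v = nv.necrosis_volume(areas, DEFAULT)
        assert nv.necrosis_volume([c * a for a in areas], DEFAULT) == pytest.approx(
            c * v, rel=1e-9, abs=1e-12
        )

    def test_last_section_takes_thickness_only_weight(self):
        # asymmetric stack: moving the large area to the end changes the sum
        v_front = nv.necrosis_volume([5.0, 1.0], DEFAULT)
        v_back = nv.necrosis_volume([1.0, 5.0], DEFAULT)
        assert v_front - v_back == pytest.approx((5.0 - 1.0) * 0.5)


class TestSummarize:
    def test_threshold_filters_speck_slices(self):
        areas = [0.0, 0.005, 2.0, 3.0, 0.009, 1.0]
        s = nv.summarize(areas, DEFAULT)
        assert s.n_sections_with_necrosis == 3
        assert s.volume_uL == pytest.approx((2.0 + 3.0) * 0.52 + 1.0 * 0.02)
        assert s.depth_mm == pytest.approx(nv.necrosis_depth(3, DEFAULT))

    def test_empty_stack(self):
        s = nv.summarize([], DEFAULT)
        assert (s.n_sections_with_necrosis, s.depth_mm, s.volume_uL) == (0, 0.0, 0.0)


def _masks_from_arrays(tissue, necrosis):
    return LabelMasks(tissue=tissue, necrosis=necrosis, viable=tissue & ~necrosis)


class TestSliceAreas:
    def test_pixel_count_oracle(self):
        g = nv.StackGeometry(pixel_size_mm=0.01)
        tissue = np.zeros((200, 200), bool)
        tissue[10:160, 20:180] = True
        necrosis = np.zeros_like(tissue)
        necrosis[50:150, 50:150] = True  # 10,000 px
        m = _masks_from_arrays(tissue, necrosis)
        meas = nv.slice_areas(m, g)
        assert meas.necrotic_area_mm2 == pytest.approx(1.0)

    def test_empty_mask(self):
        m = _masks_from_arrays(np.zeros((10, 10), bool), np.zeros((10, 10), bool))
        assert nv.slice_areas(m, DEFAULT).necrotic_area_mm2 == 0.0


class TestTopHalf:
    def test_necrosis_entirely_above_split(self, geom):
        tissue = np.zeros((100, 100), bool)
        tissue[10:90, 10:90] = True
        necrosis = np.zeros_like(tissue)
        necrosis[12:20, 20:40] = True
        m = _masks_from_arrays(tissue, necrosis)
        top, centroid = nv.top_half_areas(m, geom)
        assert top == pytest.approx(nv.slice_areas(m, geom).necrotic_area_mm2)
        assert centroid == pytest.approx(49.5)

    def test_mirror_symmetric_splits_in_half(self, geom):
        tissue = np.zeros((100, 100), bool)
        tissue[10:90, 10:90] = True  # centroid row 49.5
        necrosis = np.zeros_like(tissue)
        necrosis[30:70, 40:60] = True  # symmetric about 49.5
        m = _masks_from_arrays(tissue, necrosis)
        top, _ = nv.top_half_areas(m, geom)
        whole = nv.slice_areas(m, geom).necrotic_area_mm2
        assert top == pytest.approx(whole / 2, abs=geom.px_to_mm2(necrosis[30].sum()))

    def test_brute_force_row_count(self, clean_phantom, geom):
        """12 o'clock lesion: top-half area equals a direct row count."""
        _, gt = clean_phantom
        m = gt.masks[14]
        top, centroid = nv.top_half_areas(m, geom)
        rows = np.nonzero(m.necrosis)[0]
        assert top == pytest.approx(geom.px_to_mm2(int((rows < centroid).sum())))

    def test_top_plus_bottom_equals_whole(self, clean_phantom, geom):
        _, gt = clean_phantom
        for m in gt.masks[10:20]:
            top, centroid = nv.top_half_areas(m, geom)
            rows = np.nonzero(m.necrosis)[0]
            bottom = geom.px_to_mm2(int((rows >= centroid).sum()))
            whole = nv.slice_areas(m, geom).necrotic_area_mm2
            assert top + bottom == pytest.approx(whole)

    def test_empty_tissue_flagged(self, geom):
        m = _masks_from_arrays(np.zeros((10, 10), bool), np.zeros((10, 10), bool))
        top, centroid = nv.top_half_areas(m, geom)
        assert top == 0.0 and np.isnan(centroid)


def _t_test_oracle(a, b):
    """Independent closed form: pooled t statistic and the two-tailed p via
    the regularized incomplete beta tail."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = special.betainc(df / 2, 0.5, df / (df + t**2))
    return t, p


class TestCompareGroups:
    def test_identical_groups_null(self):
        res = nv.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self):
        a = [3.1, 2.7, 3.6, 2.9, 3.3]
        b = [4.0, 4.4, 3.9, 4.6, 4.2]
        res = nv.compare_groups(a, b)
        t_ref, p_ref = _t_test_oracle(a, b)
        assert res.t == pytest.approx(t_ref, rel=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-12)
        assert res.df == 8

    def test_summary_stats_match_raw_values(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(10, 2, 12), rng.normal(12, 2, 9)
        raw = nv.compare_groups(a, b)
        summ = nv.compare_groups_from_stats(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert raw.t == pytest.approx(summ.t)
        assert raw.p == pytest.approx(summ.p)

    def test_welch_df_below_pooled(self):
        res = nv.compare_groups([1, 2, 3, 4.0], [10, 30, 50, 80.0], variant="welch")
        assert res.df < 6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            nv.compare_groups([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            nv.compare_groups_from_stats(1, 0, 5, 2, 0, 5)
        with pytest.raises(ValueError):
            nv.compare_groups([1, 2.0], [3, 4.0], variant="median")
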