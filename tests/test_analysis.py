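import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icga.analysis import (
    DEFAULT_FEATURE_ORDER,
    PipelineVariant,
    class_spider_orientations,
    compare_groups,
    relative_features,
    run_pipeline,
    spider_orientation,
)
from icga.exceptions import ConfigurationError, DegenerateCurveError
from icga.kinetics import ROI
from icga.synthetic import SceneConfig, severity_presets, simulate_curve, simulate_stack


def mwu_pair_count(a, b):
    """O(n^2) oracle: pairs with a > b plus half the ties."""
    return sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)


def mwu_exact_p(a, b):
    """Exact two-sided p by enumerating the permutation null (no ties)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(comb)] = True
        us.append(mwu_pair_count(pooled[sel], pooled[~sel]))
    us = np.asarray(us)
    u_obs = mwu_pair_count(a, b)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestPipelineVariants:
    def test_named_variants_have_consistent_flags(self):
        assert PipelineVariant.from_name("NP").use_ffc is False
        assert PipelineVariant.from_name("FFC+nAUC").use_nauc is True
        with pytest.raises(ConfigurationError):
            PipelineVariant(name="NP", use_ffc=True, use_nauc=False)
        with pytest.raises(ConfigurationError):
            PipelineVariant.from_name("bogus")

    def _clean_scene(self):
        regions = tuple(
            (ROI(label=f"n{i}", cx=10 + 12 * i, cy=10, radius=4), "normal")
            for i in range(3)
        )
        return SceneConfig(
            shape=(20, 44), regions=regions, vignette="none",
            distance_falloff=False, dark_level=0.0, seed=3, duration=90.0,
        )

    def test_np_variant_matches_manual_composition(self):
        from icga.correction import subtract_baseline
        from icga.features import compute_features
        from icga.kinetics import extract_curve

        stack, rois, ffs, _ = simulate_stack(self._clean_scene())
        table = run_pipeline(stack, rois, PipelineVariant.from_name("NP"))

        manual_stack = subtract_baseline(stack, 10)
        manual = pd.DataFrame(
            [compute_features(extract_curve(manual_stack, r)).as_row() for r in rois]
        )
        for col in ("imax", "mtt_s", "fwhm_s", "rauc", "s1", "s2"):
            np.testing.assert_allclose(table[col], manual[col], rtol=1e-12)

    def test_nauc_variant_rescales_intensity_keeps_timing(self):
        stack, rois, _, _ = simulate_stack(self._clean_scene())
        np_table = run_pipeline(stack, rois, PipelineVariant.from_name("NP"))
        na_table = run_pipeline(stack, rois, PipelineVariant.from_name("nAUC"))
        np.testing.assert_allclose(na_table["mtt_s"], np_table["mtt_s"], rtol=1e-12)
        np.testing.assert_allclose(na_table["fwhm_s"], np_table["fwhm_s"], rtol=1e-12)
        np.testing.assert_array_equal(na_table["tp_s"], np_table["tp_s"])
        ratio = np_table["imax"] / na_table["imax"]
        np.testing.assert_allclose(np_table["rauc"] / na_table["rauc"], ratio, rtol=1e-9)

    def test_ffc_reduces_imax_cv_on_vignetted_phantom(self):
        positions = [(12, 12), (52, 12), (32, 32), (12, 52), (52, 52)]
        regions = tuple(
            (ROI(label=f"n{i}", cx=x, cy=y, radius=5), "normal")
            for i, (x, y) in enumerate(positions)
        )
        scene = SceneConfig(shape=(64, 64), regions=regions, seed=1, duration=90.0)
        stack, rois, ffs, _ = simulate_stack(scene)
        np_table = run_pipeline(stack, rois, PipelineVariant.from_name("NP"))
        ffc_table = run_pipeline(
            stack, rois, PipelineVariant.from_name("FFC+nAUC"), flat_field=ffs
        )
        cv = lambda x: np.std(x) / np.mean(x)
        assert cv(ffc_table["imax"]) < cv(np_table["imax"])

    def test_ffc_without_calibration_errors(self):
        stack, rois, _, _ = simulate_stack(self._clean_scene())
        with pytest.raises(ConfigurationError):
            run_pipeline(stack, rois, PipelineVariant.from_name("FFC"))


class TestRelativeFeatures:
    def _table(self):
        return pd.DataFrame(
            {
                "tissue_class": ["normal"] * 3 + ["burn"] * 2,
                "imax": [1.0, 2.0, 3.0, 4.0, 4.0],
                "rauc": [1.0, 1.0, 1.0, 0.5, 0.5],
                "mtt_s": [10.0] * 5,
                "fwhm_s": [5.0] * 5,
                "s1": [1.0] * 5,
                "s2": [-1.0] * 5,
            }
        )

    def test_all_normal_relative_medians_are_one(self):
        t = self._table()[lambda d: d.tissue_class == "normal"]
        rel = relative_features(t)
        for col in ("imax", "rauc", "mtt_s"):
            assert rel[col].median() == pytest.approx(1.0)

    def test_burn_feature_ratio(self):
        rel = relative_features(self._table())
        assert rel.loc[3, "imax"] == pytest.approx(2.0)  # 4 / median(1,2,3)
        assert rel.loc[3, "rauc"] == pytest.approx(0.5)

    def test_overall_median_mode(self):
        rel = relative_features(self._table(), mode="overall_median")
        assert rel["imax"].median() == pytest.approx(1.0)
        assert rel.attrs["relative_mode"] == "overall_median"

    def test_missing_reference_class_errors(self):
        t = self._table()
        t["tissue_class"] = "burn"
        with pytest.raises(ConfigurationError):
            relative_features(t)

    def test_zero_reference_median_errors(self):
        t = self._table()
        t.loc[t.tissue_class == "normal", "imax"] = 0.0
        with pytest.raises(DegenerateCurveError):
            relative_features(t)


class TestCompareGroups:
    def _df(self, a, b):
        return pd.DataFrame(
            {"tissue_class": ["a"] * len(a) + ["b"] * len(b), "f": list(a) + list(b)}
        )

    def test_identical_groups_give_p_one(self):
        gc = compare_groups(self._df([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]), "f", "a", "b")
        assert gc.p_value == pytest.approx(1.0)

    def test_fully_separated_groups_exact_p(self):
        gc = compare_groups(self._df([10, 11, 12, 13, 14], [1, 2, 3, 4, 5]), "f", "a", "b")
        assert gc.u_statistic == 25.0
        assert gc.p_value == pytest.approx(2 / 252)
        assert gc.tier == "p<0.01"

    def test_u_matches_pair_count_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.integers(0, 12, 6).astype(float)  # ties likely
            b = rng.integers(0, 12, 5).astype(float)
            gc = compare_groups(self._df(a, b), "f", "a", "b")
            assert gc.u_statistic == mwu_pair_count(a, b)

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(0.8, size=5)
            gc = compare_groups(self._df(a, b), "f", "a", "b")
            assert gc.p_value == pytest.approx(mwu_exact_p(a, b), rel=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=5), rng.normal(size=6)
        df = self._df(a, b)
        g1 = compare_groups(df, "f", "a", "b")
        g2 = compare_groups(df, "f", "b", "a")
        assert g1.p_value == pytest.approx(g2.p_value, rel=1e-12)
        assert g2.u_statistic == len(a) * len(b) - g1.u_statistic

    def test_small_group_errors(self):
        with pytest.raises(ConfigurationError):
            compare_groups(self._df([1, 2], [3, 4, 5]), "f", "a", "b")


class TestSpiderOrientation:
    def test_regular_hexagon_degenerate_zero(self):
        so = spider_orientation([1.0] * 6)
        assert so.degenerate and so.orientation_deg == 0.0

    def test_vertical_elongation_zero_tilt(self):
        so = spider_orientation([2, 1, 1, 2, 1, 1])
        assert not so.degenerate
        assert so.orientation_deg == pytest.approx(0.0, abs=1e-6)
        assert so.semi_major > so.semi_minor

    def _moment_axis_deg(self, radii):
        angles = np.radians(90.0 - 60.0 * np.arange(6))
        x, y = radii * np.cos(angles), radii * np.sin(angles)
        pts = np.column_stack([x - x.mean(), y - y.mean()])
        _, vecs = np.linalg.eigh(pts.T @ pts)
        major = vecs[:, -1]
        tilt = np.degrees(np.arctan2(major[1], major[0])) - 90.0
        tilt = (tilt + 90.0) % 180.0 - 90.0
        return 90.0 if tilt == -90.0 else tilt

    @pytest.mark.parametrize("shift,expected", [(1, -60.0), (2, 60.0)])
    def test_rotated_elongation_matches_second_moment_oracle(self, shift, expected):
        radii = np.roll([2.0, 1, 1, 2, 1, 1], shift)
        so = spider_orientation(radii)
        oracle = self._moment_axis_deg(np.asarray(radii, dtype=float))
        assert so.orientation_deg == pytest.approx(oracle, abs=1e-6)
        assert so.orientation_deg == pytest.approx(expected, abs=1e-6)

    @given(c=st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, c):
        radii = np.array([1.4, 0.8, 1.1, 0.7, 1.9, 1.2])
        s1 = spider_orientation(radii)
        s2 = spider_orientation(c * radii)
        assert s2.orientation_deg == pytest.approx(s1.orientation_deg, abs=1e-6)
        assert s2.degenerate == s1.degenerate

    def test_cyclic_rotation_equivariance(self):
        radii = np.array([1.4, 0.8, 1.1, 0.7, 1.9, 1.2])
        base = spider_orientation(radii).orientation_deg
        rot = spider_orientation(np.roll(radii, 1)).orientation_deg
        diff = (base - rot) % 180.0
        assert min(abs(diff - 60.0), abs(diff - 120.0)) < 1e-6 or abs(diff) < 1e-6

    def test_mapping_input_uses_absolute_slopes(self):
        row = {"imax": 1.0, "fwhm_s": 1.0, "s1": -1.5, "rauc": 1.0, "s2": -2.0, "mtt_s": 1.0}
        so = spider_orientation(row, DEFAULT_FEATURE_ORDER)
        assert so.radii[DEFAULT_FEATURE_ORDER.index("s2")] == 2.0

    def test_invalid_radii_rejected(self):
        with pytest.raises(DegenerateCurveError):
            spider_orientation([1, 1, 0, 1, 1, 1])
        with pytest.raises(DegenerateCurveError):
            spider_orientation([1, 1, np.nan, 1, 1, 1])
        with pytest.raises(ConfigurationError):
            spider_orientation([1, 1, 1])

    def test_flip_sign_convention(self):
        radii = np.roll([2.0, 1, 1, 2, 1, 1], 1)
        s = spider_orientation(radii)
        f = spider_orientation(radii, flip_sign=True)
        assert f.orientation_deg == pytest.approx(-s.orientation_deg)


class TestSeverityAnalysis:
    @pytest.fixture(scope="class")
    def severity_table(self, time_grid):
        from icga.kinetics import KineticsCurve

        curves = []
        for cls in ("normal", "superficial", "deep"):
            model = severity_presets()[cls].model
            for i in range(5):
                c, _ = simulate_curve(model, time_grid, seed=i, roi_label=f"{cls}{i}")
                curves.append(
                    KineticsCurve(
                        times=c.times, values=c.values, roi_label=c.roi_label,
                        tissue_class="normal" if cls == "normal" else cls,
                    )
                )
        return run_pipeline(curves, None, PipelineVariant.from_name("nAUC"))

    def test_relative_directionality(self, severity_table):
        rel = relative_features(severity_table)
        sup = rel[rel.tissue_class == "superficial"]
        deep = rel[rel.tissue_class == "deep"]
        for col in ("imax", "rauc", "s1"):
            assert (sup[col] > 1).all(), col
            assert (deep[col] < 1).all(), col
        assert (sup["s2"].abs() > 1).all() and (deep["s2"].abs() < 1).all()
        for col in ("mtt_s", "fwhm_s"):
            assert (sup[col] < 1).all(), col
            assert (deep[col] > 1).all(), col

    def test_spider_sign_structure(self, severity_table):
        rel = relative_features(severity_table)
        oris = class_spider_orientations(rel)
        assert oris["normal"].degenerate
        assert oris["normal"].orientation_deg == 0.0
        assert oris["superficial"].orientation_deg > 10.0
        assert oris["deep"].orientation_deg < -10.0
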