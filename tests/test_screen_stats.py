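"""Normalization, reproducibility, embedding and the group-test battery."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import angioscreen as ag
from angioscreen.screen_stats import (
    GroupComparisonResult,
    _dunn_pairwise,
    analyte_tests,
    benjamini_hochberg,
    compare_groups,
    embed,
    normalize_to_vehicle,
    replicate_correlation,
    replicate_pairs,
    signed_significance_matrix,
    significance_stars,
    welch_compare,
    wilcoxon_rank_sum,
)
from angioscreen.synth.screen import ScreenDesign, TreatmentEffect, generate_screen
from angioscreen.types import ParameterError


def layout_of(chips, plate="P1", treatment=None):
    return pd.DataFrame({
        "plate": plate, "chip": chips, "donor": "D1",
        "treatment": treatment or ["DMSO"] * len(chips),
        "replicate": range(1, len(chips) + 1),
    })


class TestNormalization:
    def test_by_definition(self):
        layout = layout_of(["a", "b", "c"], treatment=["DMSO", "DMSO", "drug"])
        via = pd.DataFrame({"chip": ["a", "b", "c"], "value": [90.0, 110.0, 80.0]})
        out = normalize_to_vehicle(via, layout)
        assert out.loc[out.chip == "c", "normalized"].item() == pytest.approx(80.0)

    def test_all_equal_gives_100(self):
        layout = layout_of(list("abcd"))
        via = pd.DataFrame({"chip": list("abcd"), "value": [7.0] * 4})
        out = normalize_to_vehicle(via, layout)
        np.testing.assert_allclose(out["normalized"], 100.0)

    def test_plate_without_vehicle_raises(self):
        layout = layout_of(["a", "b"], treatment=["drug", "drug"])
        via = pd.DataFrame({"chip": ["a", "b"], "value": [1.0, 2.0]})
        with pytest.raises(ParameterError, match="P1"):
            normalize_to_vehicle(via, layout)

    @given(factor=st.floats(0.01, 100.0))
    def test_invariant_under_plate_scaling(self, factor):
        layout = layout_of(list("abcd"), treatment=["DMSO", "DMSO", "x", "y"])
        via = pd.DataFrame({"chip": list("abcd"),
                            "value": [50.0, 70.0, 30.0, 90.0]})
        base = normalize_to_vehicle(via, layout)["normalized"]
        scaled = via.assign(value=via["value"] * factor)
        out = normalize_to_vehicle(scaled, layout)["normalized"]
        np.testing.assert_allclose(out, base, rtol=1e-9)


class TestReplicateCorrelation:
    def test_identical_gives_one(self):
        assert replicate_correlation([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_negated_gives_minus_one(self):
        assert replicate_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_zero_variance_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(replicate_correlation([1, 1, 1], [1, 2, 3]))

    def test_matches_independent_covariance_computation(self):
        ds = generate_screen(ScreenDesign(
            treatments={"DMSO": TreatmentEffect(),
                        **{f"T{i}": TreatmentEffect(viability=v)
                           for i, v in enumerate((0.4, 0.6, 0.8, 1.0))}},
            seed=12))
        norm = normalize_to_vehicle(ds.viability, ds.layout)
        a, b = replicate_pairs(norm)
        r = replicate_correlation(a, b)
        # independent route: explicit sums, no library call
        n = len(a)
        cov = (a * b).sum() / n - a.mean() * b.mean()
        oracle = cov / np.sqrt(
            ((a**2).sum() / n - a.mean() ** 2) * ((b**2).sum() / n - b.mean() ** 2)
        )
        assert r == pytest.approx(oracle, abs=1e-12)


class TestEmbed:
    @staticmethod
    def line_table(n=20):
        t = np.linspace(0, 1, n)
        cols = {f"d{i}": 3.0 * i * t + i for i in range(1, 16)}
        return pd.DataFrame({"chip": [f"c{i}" for i in range(n)], **cols})

    def test_collinear_data_pc1_explains_everything(self):
        _, ev = embed(self.line_table(), "pca")
        assert ev[0] == pytest.approx(1.0, abs=1e-9)

    def test_pca_deterministic_and_sign_convention(self):
        tab = self.line_table()
        a, _ = embed(tab, "pca")
        b, _ = embed(tab, "pca")
        pd.testing.assert_frame_equal(a, b)

    def test_pca_loadings_orthonormal(self):
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler

        tab = generate_screen(ScreenDesign(seed=5)).descriptors
        Z = StandardScaler().fit_transform(tab.drop(columns="chip"))
        L = PCA(n_components=2).fit(Z).components_
        np.testing.assert_allclose(L @ L.T, np.eye(2), atol=1e-10)

    def test_tsne_requires_seed_and_perplexity_bound(self):
        tab = self.line_table()
        with pytest.raises(ParameterError, match="seed"):
            embed(tab, "tsne")
        with pytest.raises(ParameterError, match="perplexity"):
            embed(tab, "tsne", seed=0, perplexity=10.0)

    def test_tsne_deterministic_given_seed(self):
        tab = self.line_table(24)
        a, _ = embed(tab, "tsne", seed=3, perplexity=5.0)
        b, _ = embed(tab, "tsne", seed=3, perplexity=5.0)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_chips_error(self):
        with pytest.raises(ParameterError):
            embed(self.line_table(1), "pca")


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        res = compare_groups({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert res[0].p_adjusted > 0.99
        assert res[0].stars == ""

    def test_dunn_matches_hand_rank_computation(self):
        groups = {"a": [1.0, 2, 3], "b": [4.0, 5, 6], "c": [7.0, 8, 9]}
        res = {(a, b): z for a, b, z, _ in _dunn_pairwise(
            {k: np.asarray(v) for k, v in groups.items()})}
        # mean ranks 2, 5, 8; var base N(N+1)/12 = 7.5; se = sqrt(7.5 * 2/3)
        se = np.sqrt(5.0)
        assert res[("a", "b")] == pytest.approx(-3.0 / se, abs=1e-10)
        assert res[("a", "c")] == pytest.approx(-6.0 / se, abs=1e-10)
        assert res[("b", "c")] == pytest.approx(-3.0 / se, abs=1e-10)

    def test_gate_selects_nonparametric_for_skewed_data(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.lognormal(0, 2.0, 25) ** 2 for k in "abc"}
        res = compare_groups(groups, design="auto")
        assert all(r.test == "kw_dunn" for r in res)

    def test_gate_selects_parametric_for_gaussian_data(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(0, 1, 20) for k in "abc"}
        res = compare_groups(groups, design="auto")
        assert all(r.test == "anova_tukey" for r in res)

    def test_zero_variance_group_falls_back(self):
        with pytest.warns(UserWarning, match="nonparametric"):
            res = compare_groups({"a": [1.0, 1, 1], "b": [2.0, 3, 4]},
                                 design="parametric")
        assert res[0].test == "kw_dunn"

    def test_needs_two_groups_of_two(self):
        with pytest.raises(ParameterError):
            compare_groups({"a": [1.0, 2]})
        with pytest.raises(ParameterError):
            compare_groups({"a": [1.0], "b": [1.0, 2]})

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        res = compare_groups({k: rng.normal(float(i), 1, 10)
                              for i, k in enumerate("abcd")})
        for r in res:
            assert r.p_adjusted >= r.p_raw


class TestAnalyteTests:
    def test_identical_to_control_q_one(self):
        chips = [f"c{i}" for i in range(8)]
        layout = layout_of(chips, treatment=["DMSO"] * 4 + ["T"] * 4)
        tab = pd.DataFrame({"chip": chips, "IL6": [5.0] * 8})
        res = analyte_tests(tab, layout)
        assert res[0].p_adjusted == pytest.approx(1.0)

    def test_bh_step_up_by_hand(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    @given(ps=st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=30))
    def test_bh_monotone_in_sorted_raw_p(self, ps):
        p = np.sort(np.asarray(ps))
        q = benjamini_hochberg(p)
        assert (np.diff(q) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_family_option_changes_adjustment_only(self):
        ds = generate_screen(ScreenDesign(
            treatments={"DMSO": TreatmentEffect(),
                        "T": TreatmentEffect(analytes={"IL6": 0.2})}, seed=3))
        glob = analyte_tests(ds.analytes, ds.layout, family="global")
        per = analyte_tests(ds.analytes, ds.layout, family="per_analyte")
        assert [r.p_raw for r in glob] == [r.p_raw for r in per]
        assert any(r.p_adjusted != g.p_adjusted for r, g in zip(per, glob))

    def test_signed_matrix_orientation(self):
        ds = generate_screen(ScreenDesign(
            treatments={"DMSO": TreatmentEffect(),
                        "T": TreatmentEffect(analytes={"IL6": 0.1, "AFP": 4.0})},
            seed=9))
        res = analyte_tests(ds.analytes, ds.layout)
        mat = signed_significance_matrix(res, ds.analytes, ds.layout)
        assert mat.loc["T", "IL6"] < 0 < mat.loc["T", "AFP"]


class TestWelch:
    def test_equal_groups(self):
        t, p = welch_compare([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0 and p == pytest.approx(1.0)

    def test_hand_formula(self):
        t, p = welch_compare([1.0, 2, 3], [2.0, 3, 4])
        # means 2, 3; s^2 = 1 each, n = 3: t = -1/sqrt(2/3), df = 4
        t_hand = -1.0 / np.sqrt(2.0 / 3.0)
        from scipy import stats as ss
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(2 * ss.t.sf(abs(t_hand), df=4), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 9), rng.normal(1, 2, 7)
        t1, p1 = welch_compare(a, b)
        t2, p2 = welch_compare(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestStars:
    @pytest.mark.parametrize("p,expect", [
        (0.2, ""), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.00009, "****"),
        (0.05, ""), (float("nan"), ""),
    ])
    def test_convention(self, p, expect):
        assert significance_stars(p) == expect

    def test_result_invariant_enforced(self):
        with pytest.raises(ParameterError):
            GroupComparisonResult("r", "a", "b", "welch", 1.0,
                                  p_raw=0.5, p_adjusted=0.2, adjustment="bh")
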