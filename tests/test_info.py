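"""Component retention, rotation, variance components, and bits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import callsig as cs
from callsig.info import VarianceComponents, _oneway_reml

from conftest import one_way_scores


def brute_force_anova_components(y, groups):
    """Independent moment-estimator oracle for balanced one-way designs:
    S_B^2 = (MS_between - MS_within) / n0 with explicit mean squares."""
    df = pd.DataFrame({"y": y, "g": groups})
    k = df["g"].nunique()
    n0 = len(df) / k
    gm = df.groupby("g")["y"].mean()
    ms_between = n0 * ((gm - df["y"].mean()) ** 2).sum() / (k - 1)
    ms_within = sum(((grp - grp.mean()) ** 2).sum()
                    for _, grp in df.groupby("g")["y"]) / (len(df) - k)
    return (ms_between - ms_within) / n0, ms_within


class TestParallelAnalysis:
    def test_pure_noise_rarely_retains_components(self):
        zeros = 0
        runs = 20
        for s in range(runs):
            x = np.random.default_rng(100 + s).standard_normal((2000, 50))
            if cs.parallel_analysis(x, n_iterations=100, seed=s) == 0:
                zeros += 1
        assert zeros >= 0.9 * runs

    def test_planted_factor_always_detected(self):
        for s in range(5):
            rng = np.random.default_rng(s)
            f = rng.normal(0, 1, 500)
            x = 0.9 * f[:, None] + 0.44 * rng.normal(0, 1, (500, 10))
            assert cs.parallel_analysis(x, n_iterations=100, seed=s) >= 1

    def test_two_perfectly_correlated_variables(self):
        z = np.random.default_rng(1).normal(0, 1, 100)
        n = cs.parallel_analysis(pd.DataFrame({"a": z, "b": 2 * z}),
                                 n_iterations=200, seed=3)
        assert n == 1

    def test_constant_variable_named_in_error(self):
        x = pd.DataFrame({"ok": np.random.default_rng(0).normal(0, 1, 50),
                          "flat": np.ones(50)})
        with pytest.raises(ValueError, match="flat"):
            cs.parallel_analysis(x, n_iterations=10, seed=0)


class TestVarimaxPCA:
    def _two_block(self, seed=0, n=1500):
        rng = np.random.default_rng(seed)
        f1, f2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        load1 = [0.95, 0.85, 0.75, 0.9, 0.8]
        load2 = [0.7, 0.9, 0.8, 0.95, 0.6]
        x = np.empty((n, 10))
        for j in range(5):
            x[:, j] = load1[j] * f1 + 0.3 * rng.normal(0, 1, n)
            x[:, j + 5] = load2[j] * f2 + 0.3 * rng.normal(0, 1, n)
        return pd.DataFrame(x), f1, f2

    def test_single_component_rotation_is_identity(self):
        x, _, _ = self._two_block()
        m = cs.pca_varimax(x, 1)
        assert np.allclose(m.rotation_, [[1.0]])

    def test_two_block_structure_recovered(self):
        x, f1, f2 = self._two_block()
        m = cs.pca_varimax(x, 2)
        load = np.abs(m.loadings_)
        b1 = 0 if load[:5, 0].mean() > load[:5, 1].mean() else 1
        assert max(load[:5, 1 - b1].max(), load[5:, b1].max()) < 0.1
        scores = m.transform(x)
        assert abs(np.corrcoef(scores[:, b1], f1)[0, 1]) > 0.95
        assert abs(np.corrcoef(scores[:, 1 - b1], f2)[0, 1]) > 0.95

    def test_communalities_invariant_under_rotation(self):
        x, _, _ = self._two_block()
        m = cs.pca_varimax(x, 2)
        corr = np.corrcoef(x.to_numpy(), rowvar=False)
        val, vec = np.linalg.eigh(corr)
        order = np.argsort(val)[::-1][:2]
        unrotated = vec[:, order] * np.sqrt(val[order])
        assert np.allclose((unrotated ** 2).sum(axis=1), m.communalities_,
                           atol=1e-8)

    def test_variance_proportions_sum_below_one(self):
        x, _, _ = self._two_block()
        m = cs.pca_varimax(x, 3)
        assert m.variance_proportion_.sum() <= 1.0 + 1e-12
        assert (m.variance_proportion_ > 0).all()

    def test_rotation_preserves_total_retained_variance(self):
        x, _, _ = self._two_block()
        rotated = cs.pca_varimax(x, 2)
        plain = cs.VarimaxPCA(n_components=2, rotate=False).fit(x)
        assert rotated.variance_proportion_.sum() == pytest.approx(
            plain.variance_proportion_.sum(), abs=1e-10)

    def test_singular_correlation_rejected(self):
        z = np.random.default_rng(0).normal(0, 1, 200)
        x = pd.DataFrame({"a": z, "b": 2 * z + 1, "c": z - 3,
                          "d": np.random.default_rng(1).normal(0, 1, 200)})
        with pytest.raises(ValueError, match="singular|collinear"):
            cs.pca_varimax(x, 2)


class TestEstimateVCE:
    def test_oneway_parameter_recovery(self):
        rng = np.random.default_rng(0)
        y, groups = one_way_scores(rng, n_groups=20, n_per_group=50,
                                   sb=1.0, sw=1.0)
        vce = cs.estimate_vce(y, pd.DataFrame({"individual": groups}),
                              ["individual"])
        # approximate SE of S_B^2 for a balanced one-way design
        se = np.sqrt(2 / 19) * (1.0 + 1.0 / 50)
        assert vce.between["individual"][0] == pytest.approx(1.0, abs=3 * se)
        assert vce.within[0] == pytest.approx(1.0, abs=0.15)

    def test_null_case_truncates_to_zero(self):
        rng = np.random.default_rng(1)
        groups = np.repeat(np.arange(10), 40)
        y = rng.normal(0, 1, 400)
        y -= pd.Series(y).groupby(groups).transform("mean").to_numpy()
        vce = cs.estimate_vce(y, pd.DataFrame({"individual": groups}),
                              ["individual"])
        assert vce.between["individual"][0] == 0.0
        assert vce.within[0] == pytest.approx(1.0, abs=0.2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_balanced_reml_equals_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y, groups = one_way_scores(rng, n_groups=20, n_per_group=30,
                                   sb=0.7, sw=1.2)
        sb2, sw2 = _oneway_reml(y, groups)
        sb2_o, sw2_o = brute_force_anova_components(y, groups)
        if sb2_o >= 0:
            assert abs(sb2 - sb2_o) < 1e-6
            assert abs(sw2 - sw2_o) < 1e-6

    def test_nested_factors_recovered(self):
        rng = np.random.default_rng(5)
        labels = pd.DataFrame({
            "colony": np.repeat([f"c{i}" for i in range(12)], 80),
            "individual": np.repeat([f"i{i}" for i in range(48)], 20)})
        y = (np.repeat(rng.normal(0, np.sqrt(2.0), 12), 80)
             + np.repeat(rng.normal(0, 1.0, 48), 20)
             + rng.normal(0, 1, 960))
        vce = cs.estimate_vce(y, labels, ["colony", "individual"])
        assert vce.between["colony"][0] == pytest.approx(2.0, abs=1.5)
        assert vce.between["individual"][0] == pytest.approx(1.0, abs=0.5)
        assert vce.within[0] == pytest.approx(1.0, abs=0.15)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="level"):
            cs.estimate_vce(np.arange(10.0),
                            pd.DataFrame({"individual": ["a"] * 10}),
                            ["individual"])


def make_vce(sb_list, sw_list, factor="individual"):
    return VarianceComponents(
        factors=[factor],
        between=pd.DataFrame({factor: np.asarray(sb_list, dtype=float)}),
        within=np.asarray(sw_list, dtype=float))


class TestSignatureInformation:
    def test_closed_form_single_component(self):
        sig = cs.signature_information(make_vce([3.0], [1.0]))
        assert sig.h_bits[0] == pytest.approx(1.0)
        assert sig.repeatability[0] == pytest.approx(0.75)

    def test_zero_between_variance(self):
        sig = cs.signature_information(make_vce([0.0], [1.0]))
        assert sig.h_bits[0] == 0.0
        assert sig.repeatability[0] == 0.0

    def test_three_equal_components_sum(self):
        sig = cs.signature_information(make_vce([1.0] * 3, [1.0] * 3))
        assert sig.total_bits == pytest.approx(1.5)
        assert sig.total_bits == pytest.approx(sig.h_bits.sum())

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ValueError, match="S_w|within|positive"):
            cs.signature_information(make_vce([1.0], [0.0]))

    @given(sb=st.floats(0.01, 50), sw=st.floats(0.01, 50),
           c=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, sb, sw, c):
        """Multiplying all scores of a component by c scales both
        variance components by c^2 and leaves H_i and r_i unchanged."""
        base = cs.signature_information(make_vce([sb], [sw]))
        scaled = cs.signature_information(make_vce([sb * c ** 2],
                                                   [sw * c ** 2]))
        assert base.h_bits[0] == pytest.approx(scaled.h_bits[0], rel=1e-9)
        assert base.repeatability[0] == pytest.approx(
            scaled.repeatability[0], rel=1e-9)

    @given(sb=st.floats(0.01, 20), sw=st.floats(0.01, 20),
           delta=st.floats(0.01, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_between_variance(self, sb, sw, delta):
        lo = cs.signature_information(make_vce([sb], [sw]))
        hi = cs.signature_information(make_vce([sb + delta], [sw]))
        assert hi.h_bits[0] > lo.h_bits[0]
        assert hi.repeatability[0] > lo.repeatability[0]

    def test_signature_factors_sum_colony_and_individual(self):
        vce = VarianceComponents(
            factors=["species", "colony", "individual"],
            between=pd.DataFrame({"species": [5.0], "colony": [1.0],
                                  "individual": [2.0]}),
            within=np.array([1.0]))
        sig = cs.signature_information(vce)
        # default signature variance excludes species: S_B^2 = 3
        assert sig.signature_factors == ["colony", "individual"]
        assert sig.h_bits[0] == pytest.approx(1.0)


class TestWeightedVarianceAttribution:
    def _model_with_varprops(self, props):
        m = cs.VarimaxPCA(n_components=len(props))
        m.variance_proportion_ = np.asarray(props, dtype=float)
        return m

    def test_single_component_even_split(self):
        out = cs.weighted_variance_attribution(
            make_vce([1.0], [1.0]), self._model_with_varprops([0.5]))
        assert out["individual"] == pytest.approx(50.0)
        assert out["residual"] == pytest.approx(50.0)

    def test_no_factor_variance_gives_full_residual(self):
        out = cs.weighted_variance_attribution(
            make_vce([0.0, 0.0], [1.0, 2.0]),
            self._model_with_varprops([0.4, 0.3]))
        assert out["individual"] == 0.0
        assert out["residual"] == pytest.approx(100.0)

    def test_shares_sum_to_100(self):
        vce = VarianceComponents(
            factors=["species", "colony", "individual"],
            between=pd.DataFrame({"species": [2.0, 0.5],
                                  "colony": [0.3, 0.1],
                                  "individual": [1.0, 2.0]}),
            within=np.array([1.0, 0.7]))
        out = cs.weighted_variance_attribution(
            vce, self._model_with_varprops([0.45, 0.25]))
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-6)
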