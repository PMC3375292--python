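"""Conventional DFA, permuted DFA, and the summary statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import callsig as cs
from callsig.dfa import LinearDFA, PermutedDFA


def gaussian_classes(rng, n_classes=4, n_per_class=50, n_vars=5,
                     separation=0.0):
    y = np.repeat(np.arange(n_classes), n_per_class)
    x = rng.normal(0, 1, (n_classes * n_per_class, n_vars))
    x[:, 0] += separation * y
    return x, y


class TestLinearDFA:
    def test_null_loo_rate_near_chance(self):
        rng = np.random.default_rng(1)
        x, y = gaussian_classes(rng, 4, 100, 5)
        m = LinearDFA().fit(x, y)
        half = 2.576 * np.sqrt(25 * 75 / 400)
        assert 25 - half <= m.cv_rate_ <= 25 + half

    def test_separated_classes_fully_recovered(self):
        rng = np.random.default_rng(2)
        x, y = gaussian_classes(rng, 4, 50, 5, separation=10.0)
        m = LinearDFA().fit(x, y)
        assert m.cv_rate_ == 100.0
        assert m.training_rate_ == 100.0

    def test_wilks_is_one_for_equal_class_means(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, (60, 4))
        x = np.vstack([base, base])
        y = np.repeat([0, 1], 60)
        m = LinearDFA().fit(x, y)
        assert m.wilks_lambda_ == pytest.approx(1.0, abs=1e-12)
        assert m.chi2_ == pytest.approx(0.0, abs=1e-9)

    def test_bartlett_chi2_matches_formula(self):
        rng = np.random.default_rng(4)
        x, y = gaussian_classes(rng, 3, 40, 6, separation=1.0)
        m = LinearDFA().fit(x, y)
        n, p, g = 120, 6, 3
        expected = -(n - 1 - (p + g) / 2) * np.log(m.wilks_lambda_)
        assert m.chi2_ == pytest.approx(expected)
        assert m.df_ == p * (g - 1)
        assert m.p_value_ == pytest.approx(stats.chi2.sf(expected, m.df_))

    def test_loo_not_better_than_training_on_average(self):
        """Resubstitution optimism: over null datasets the LOO rate
        stays below the training rate in expectation."""
        diffs = []
        for seed in range(15):
            rng = np.random.default_rng(200 + seed)
            x, y = gaussian_classes(rng, 3, 25, 6)
            m = LinearDFA().fit(x, y)
            diffs.append(m.training_rate_ - m.cv_rate_)
        assert np.mean(diffs) > 0

    def test_structure_matrix_planted_variable(self):
        rng = np.random.default_rng(5)
        x, y = gaussian_classes(rng, 3, 100, 6)
        x[:, 3] += 2.0 * y
        m = LinearDFA().fit(pd.DataFrame(
            x, columns=[f"v{i}" for i in range(6)]), y)
        assert m.structure_matrix_["DF1"].abs().idxmax() == "v3"
        assert (m.structure_matrix_.abs() <= 1.0 + 1e-12).all().all()

    def test_predict_and_transform_shapes(self):
        rng = np.random.default_rng(6)
        x, y = gaussian_classes(rng, 3, 30, 4, separation=3.0)
        m = LinearDFA().fit(x, y)
        assert m.predict(x[:7]).shape == (7,)
        assert m.transform(x[:7]).shape == (7, 2)
        # sklearn-style parameter interface
        assert m.get_params() == {"compute_loo": True}

    def test_class_with_one_note_rejected(self):
        x = np.random.default_rng(0).normal(0, 1, (21, 3))
        y = np.array([0] * 10 + [1] * 10 + [2])
        with pytest.raises(ValueError, match="fewer than 2"):
            LinearDFA().fit(x, y)

    def test_too_many_variables_advises_reduction(self):
        x = np.random.default_rng(0).normal(0, 1, (20, 30))
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match="[Rr]educe dimension"):
            LinearDFA().fit(x, y)

    def test_singular_covariance_names_variables(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (40, 3))
        x = np.column_stack([x, x[:, 0]])
        y = np.repeat([0, 1], 20)
        with pytest.raises(ValueError, match="singular"):
            LinearDFA().fit(pd.DataFrame(
                x, columns=["a", "b", "c", "dup"]), y)


def nested_subjects(rng, n_per_level=4, n_levels=2, notes=20, n_vars=6,
                    subject_sd=0.8, effect=0.0):
    n_sub = n_per_level * n_levels
    subj = np.repeat(np.arange(n_sub), notes)
    level = np.repeat(np.arange(n_levels), n_per_level)
    x = rng.normal(0, 1, (n_sub * notes, n_vars))
    x += rng.normal(0, subject_sd, (n_sub, n_vars))[subj]
    x[:, 0] += effect * level[subj]
    return x, level[subj], subj


class TestPermutedDFA:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        x, y, g = nested_subjects(rng)
        r1 = cs.pdfa(x, y, g, n_dfa_reps=3, n_permutations=20,
                     random_state=1)
        r2 = cs.pdfa(x, y, g, n_dfa_reps=3, n_permutations=20,
                     random_state=1)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_rates, r2.null_rates)

    def test_note_order_invariance(self):
        """Shuffling note rows does not change the analysis design."""
        rng = np.random.default_rng(1)
        x, y, g = nested_subjects(rng, effect=2.0)
        perm = np.random.default_rng(9).permutation(len(y))
        r1 = cs.pdfa(x, y, g, n_dfa_reps=3, n_permutations=30,
                     random_state=2)
        r2 = cs.pdfa(x[perm], y[perm], g[perm], n_dfa_reps=3,
                     n_permutations=30, random_state=2)
        assert r1.observed_cv_rate == pytest.approx(r2.observed_cv_rate,
                                                    abs=3.0)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(2)
        x, y, g = nested_subjects(rng, n_per_level=6, n_levels=3,
                                  effect=5.0)
        res = cs.pdfa(x, y, g, n_dfa_reps=5, n_permutations=100,
                      random_state=3)
        assert res.p_value == 0.0
        assert res.observed_cv_rate > 90.0

    def test_two_subject_degenerate_permutations_give_p_one(self):
        """With one subject per level every permutation reproduces the
        observed partition, so the null ties the observed rate."""
        rng = np.random.default_rng(3)
        x, y, g = nested_subjects(rng, n_per_level=1, n_levels=2,
                                  notes=30, effect=4.0)
        res = cs.pdfa(x, y, g, n_dfa_reps=3, n_permutations=1,
                      random_state=4)
        assert res.p_value == 1.0

    def test_auto_training_count(self):
        rng = np.random.default_rng(4)
        x, y, g = nested_subjects(rng, notes=21)
        res = cs.pdfa(x, y, g, n_dfa_reps=2, n_permutations=2,
                      random_state=0)
        assert res.n_train_per_subject == 14

    def test_subject_without_test_notes_rejected(self):
        rng = np.random.default_rng(5)
        x, y, g = nested_subjects(rng, notes=5)
        with pytest.raises(ValueError, match="no test notes"):
            PermutedDFA(n_train_per_subject=5).fit(x, y, groups=g)

    def test_non_nested_control_rejected(self):
        rng = np.random.default_rng(6)
        x, y, g = nested_subjects(rng)
        y = y.copy()
        y[0] = 1 - y[0]  # subject 0 now carries two test labels
        with pytest.raises(ValueError, match="not nested"):
            PermutedDFA().fit(x, y, groups=g)


class TestSummaryStats:
    def test_group_rate_comparison_worked_example(self):
        """Testing-note rates of four wild vs four captive bats give the
        published pooled t of 2.987 with df 6 and p 0.024."""
        rc = cs.compare_group_rates([88, 98, 94, 84], [63, 82, 65, 37])
        assert rc.t == pytest.approx(2.987, abs=5e-4)
        assert rc.df == 6
        assert rc.p_value == pytest.approx(0.024, abs=5e-4)

    def test_identical_groups_give_t_zero_p_one(self):
        rc = cs.compare_group_rates([60, 70, 80], [60, 70, 80])
        assert rc.t == 0.0
        assert rc.p_value == pytest.approx(1.0)

    def test_swapping_groups_negates_t(self):
        a, b = [60, 70, 90, 50], [80, 85, 95, 75]
        r1 = cs.compare_group_rates(a, b)
        r2 = cs.compare_group_rates(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cs.compare_group_rates([50, 50], [70, 70])

    def test_chance_rates(self):
        assert cs.chance_rate(4) == 25.0
        assert round(cs.chance_rate(18)) == 6

    def test_outlier_at_mean_gives_zero(self):
        x2, p = cs.outlier_chisq([10.0, 30.0, 20.0, 20.0], 20.0)
        assert x2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_outlier_two_sd_gives_four(self):
        others = [10.0, 20.0, 30.0]
        mean, sd = np.mean(others), np.std(others, ddof=1)
        candidate = mean + 2 * sd
        x2, p = cs.outlier_chisq(others + [candidate], candidate)
        assert x2 == pytest.approx(4.0)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1))

    def test_outlier_symmetric_case_matches_brute_force(self):
        a = 7.0
        rates = [-a, 0.0, a]

        def brute(rates, cand):
            rest = [r for r in rates if r != cand]
            m = sum(rest) / len(rest)
            v = sum((r - m) ** 2 for r in rest) / (len(rest) - 1)
            return (cand - m) ** 2 / v

        x2, _ = cs.outlier_chisq(rates, a)
        assert x2 == pytest.approx(brute(rates, a))

    def test_holm_single_test_uncorrected(self):
        out = cs.holm_correction([0.03], alpha=0.05)
        assert bool(out["reject"][0])
        assert out["threshold"][0] == pytest.approx(0.05)

    def test_holm_ladder_hand_computation(self):
        out = cs.holm_correction([0.001, 0.04], alpha=0.05)
        assert out["threshold"].tolist() == [0.025, 0.05]
        assert out["reject"].tolist() == [True, True]

    def test_holm_stops_at_first_failure(self):
        out = cs.holm_correction([0.001, 0.03, 0.04], alpha=0.05)
        # 0.03 > 0.05/2 fails, so 0.04 cannot be rejected either
        assert out["reject"].tolist() == [True, False, False]

    def test_holm_all_ones_no_rejections(self):
        assert not cs.holm_correction([1.0, 1.0, 1.0])["reject"].any()

    def test_holm_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            cs.holm_correction([0.5, 1.5])
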