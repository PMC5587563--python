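from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from connectopy import (
    Connectome,
    default_parcellation,
    hedges_g,
    ks_two_sample,
    quartile_table,
    rm_anova_2xk,
    strength_quartiles,
    tmax_permutation_test,
)
from connectopy.group_stats import (
    group_averaged_distribution,
    simple_effects,
    two_sample_t,
)

from conftest import random_symmetric


class TestStrengthQuartiles:
    def test_hand_computed_quartiles(self):
        # left-hemisphere block holds weights {1..5}; linear interpolation
        # gives (2, 3, 4)
        p = default_parcellation()
        w = np.zeros((72, 72))
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        for k, (i, j) in enumerate([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)]):
            w[i, j] = w[j, i] = vals[k]
        q = strength_quartiles(Connectome(w, p, "s")).set_index("region_set")
        assert tuple(q.loc["left", ["q25", "q50", "q75"]]) == (2.0, 3.0, 4.0)
        # right hemisphere has no edges -> missing
        assert q.loc["right"].isna().all()

    def test_constant_and_single_edge_degenerate_cases(self):
        p = default_parcellation()
        w = np.zeros((72, 72))
        w[36, 37] = w[37, 36] = 2.5  # one right-hemisphere edge
        q = strength_quartiles(Connectome(w, p, "s")).set_index("region_set")
        assert tuple(q.loc["right", ["q25", "q50", "q75"]]) == (2.5, 2.5, 2.5)

    def test_quartiles_ordered_on_random_data(self):
        p = default_parcellation()
        c = Connectome(random_symmetric(72, seed=1), p, "s")
        q = strength_quartiles(c)
        assert (q["q25"] <= q["q50"]).all() and (q["q50"] <= q["q75"]).all()


class TestTmaxPermutation:
    def test_identical_groups_give_p_one(self):
        base = np.arange(6, dtype=float).reshape(3, 2)
        values = np.vstack([base, base])  # same three subjects in each group
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = tmax_permutation_test(values, groups, exact=True)
        assert (res["p_adjusted"] == 1.0).all()

    def test_exact_matches_independent_enumeration_3v3(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(6, 4))
        values[:3] += 1.5
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = tmax_permutation_test(values, groups, exact=True)

        # independent oracle: enumerate all C(6,3) assignments with scipy
        def max_abs_t(idx):
            sel = np.zeros(6, dtype=bool)
            sel[list(idx)] = True
            t = stats.ttest_ind(values[sel], values[~sel], axis=0).statistic
            return np.max(np.abs(t))

        maxima = [max_abs_t(idx) for idx in combinations(range(6), 3)]
        obs_t = stats.ttest_ind(values[:3], values[3:], axis=0).statistic
        for j in range(4):
            p_oracle = np.mean(
                [m >= abs(obs_t[j]) - 1e-12 for m in maxima]
            )
            assert res["p_adjusted"].iloc[j] == pytest.approx(p_oracle)

    def test_adjusted_p_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(20, 9))
        values[:10, 0] += 2.0
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = tmax_permutation_test(values, groups, n_perm=2000, seed=3)
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-12).all()
        ordered = res.sort_values("t", key=np.abs, ascending=False)
        assert ordered["p_adjusted"].is_monotonic_increasing

    def test_familywise_error_near_nominal_under_null(self):
        # 300 null replicates of a 9-statistic family
        rng = np.random.default_rng(2)
        groups = np.array(["a"] * 10 + ["b"] * 10)
        rejections = 0
        for _ in range(300):
            values = rng.normal(size=(20, 9))
            res = tmax_permutation_test(
                values, groups, n_perm=200, seed=int(rng.integers(2**31))
            )
            rejections += (res["p_adjusted"] <= 0.05).any()
        assert 0.02 <= rejections / 300 <= 0.09

    def test_sign_convention_control_minus_patient(self):
        values = np.array([[2.0], [2.1], [1.9], [1.0], [1.1], [0.9]])
        groups = np.array(["control"] * 3 + ["patient"] * 3)
        res = tmax_permutation_test(values, groups, exact=True, control="control")
        assert res["t"].iloc[0] > 0


class TestKS:
    def test_identical_samples_d_zero(self):
        x = np.arange(10.0)
        d, p = ks_two_sample(x, x)
        assert d == 0.0

    def test_disjoint_supports_d_one(self):
        d, _ = ks_two_sample(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert d == 1.0

    def test_matches_ecdf_scan_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=40), rng.normal(0.5, 1.2, size=55)
        d, _ = ks_two_sample(x, y)
        grid = np.sort(np.concatenate([x, y]))
        ecdf = lambda s, g: np.searchsorted(np.sort(s), g, side="right") / len(s)
        d_oracle = np.max(np.abs(ecdf(x, grid) - ecdf(y, grid)))
        assert d == pytest.approx(d_oracle)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample(np.array([]), np.array([1.0]))


class TestRmAnova:
    @staticmethod
    def _long(y, groups):
        n, b = y.shape
        rows = []
        for i in range(n):
            for j in range(b):
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "group": groups[i],
                        "region_set": f"lvl{j}",
                        "value": y[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def test_hand_computed_decomposition_4_subjects(self):
        y = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 5.0], [5.0, 7.0]])
        table = rm_anova_2xk(self._long(y, ["g1", "g1", "g2", "g2"]))
        assert table.loc["group", "SS"] == pytest.approx(15.125)
        assert table.loc["within", "SS"] == pytest.approx(6.125)
        assert table.loc["interaction", "SS"] == pytest.approx(0.125)
        assert table.attrs["SS_subjects_within"] == pytest.approx(6.25)
        assert table.attrs["SS_error_within"] == pytest.approx(0.25)
        assert table.loc["group", "F"] == pytest.approx(4.84)
        assert table.loc["within", "F"] == pytest.approx(49.0)
        assert table.loc["interaction", "F"] == pytest.approx(1.0)
        assert table.loc["group", "partial_eta_sq"] == pytest.approx(15.125 / 21.375)

    def test_ss_decomposition_sums_to_total(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(12, 3))
        table = rm_anova_2xk(self._long(y, ["g1"] * 5 + ["g2"] * 7))
        total = (
            table["SS"].sum()
            + table.attrs["SS_subjects_within"]
            + table.attrs["SS_error_within"]
        )
        assert total == pytest.approx(table.attrs["SS_total"], abs=1e-8)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        y = rng.normal(size=(14, 3))
        y[:7] += np.array([0.5, 0.0, -0.5])
        long = self._long(y, ["g1"] * 7 + ["g2"] * 7)
        ours = rm_anova_2xk(long)
        theirs = pg.mixed_anova(
            data=long, dv="value", within="region_set",
            subject="subject_id", between="group",
        ).set_index("Source")
        assert ours.loc["group", "F"] == pytest.approx(theirs.loc["group", "F"])
        assert ours.loc["within", "F"] == pytest.approx(theirs.loc["region_set", "F"])
        assert ours.loc["interaction", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"]
        )
        assert ours.loc["group", "partial_eta_sq"] == pytest.approx(
            theirs.loc["group", "np2"]
        )

    def test_constant_within_profile_kills_interaction(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=12)
        y = np.tile(base[:, None], (1, 3))  # no within variation per subject
        table = rm_anova_2xk(self._long(y, ["g1"] * 6 + ["g2"] * 6))
        assert table.loc["interaction", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_unbalanced_design_rejected(self):
        long = self._long(np.ones((4, 2)), ["g1", "g1", "g2", "g2"])
        with pytest.raises(ValueError):
            rm_anova_2xk(long.iloc[:-1])


class TestEffectSizes:
    def test_identical_means_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert hedges_g(x, x + 0.0) == 0.0

    def test_closed_form_small_sample_correction(self):
        # mean difference 1, pooled sd 1, n = 13+13: g = 1 - 3/95
        pattern = np.array([1.0] * 6 + [-1.0] * 6 + [0.0])
        x, y = 1.0 + pattern, pattern
        assert hedges_g(x, y) == pytest.approx(1 - 3 / 95)

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(1, 1, 10), rng.normal(0, 1, 12)
        assert hedges_g(x, y) == pytest.approx(-hedges_g(y, x))

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            hedges_g(np.ones(5), np.ones(5) * 2)


class TestCohortHelpers:
    def test_quartile_table_has_nine_statistics(self, small_cohort):
        cohort, table, _ = small_cohort
        qt = quartile_table(cohort)
        assert qt.shape == (10, 9)
        assert set(c.rsplit("_", 1)[0] for c in qt.columns) == {
            "left", "right", "interhemispheric",
        }

    def test_group_averaged_distribution_shapes(self, small_cohort):
        cohort, table, _ = small_cohort
        dists = group_averaged_distribution(
            cohort, table["group"].to_numpy(), "right"
        )
        n = cohort[0].parcellation.size // 2
        assert all(v.size == n * (n - 1) // 2 for v in dists.values())

    def test_simple_effects_match_scipy_t(self, small_cohort):
        cohort, table, _ = small_cohort
        qt = quartile_table(cohort)
        long = qt.reset_index().melt(
            id_vars="subject_id",
            value_vars=["left_q50", "right_q50"],
            var_name="region_set", value_name="value",
        ).merge(table[["subject_id", "group"]], on="subject_id")
        se = simple_effects(long, control="control")
        x = qt["right_q50"].to_numpy()[(table["group"] == "control").to_numpy()]
        y = qt["right_q50"].to_numpy()[(table["group"] == "patient").to_numpy()]
        expect = stats.ttest_ind(x, y)
        assert se.loc["right_q50", "t"] == pytest.approx(expect.statistic)
        assert se.loc["right_q50", "p"] == pytest.approx(expect.pvalue)

    def test_two_sample_t_matches_scipy(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=9), rng.normal(size=11)
        assert two_sample_t(x, y) == pytest.approx(
            stats.ttest_ind(x, y).statistic
        )
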