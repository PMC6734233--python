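import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migconn import (
    adjusted_group_effect,
    bh_fdr,
    correlate_clinical,
    interaction_effect,
    permutation_group_test,
)


def enumeration_oracle(dc, mask_b):
    """Exact permutation p by direct enumeration (independent of the
    implementation's exhaustive path)."""
    n = len(dc)
    nb = int(mask_b.sum())
    obs = dc[mask_b].mean() - dc[~mask_b].mean()
    stats = []
    for idx in itertools.combinations(range(n), nb):
        m = np.zeros(n, bool)
        m[list(idx)] = True
        stats.append(dc[m].mean() - dc[~m].mean())
    stats = np.array(stats)
    return (np.abs(stats) >= abs(obs) - 1e-12).mean()


class TestPermutationTest:
    def test_exhaustive_equals_enumeration_oracle(self, rng):
        dc = rng.standard_normal((8, 3))
        groups = np.array(["EM"] * 4 + ["CM"] * 4)
        res = permutation_group_test(dc, groups, exhaustive=True)
        assert res.n_permutations == 70
        for k in range(3):
            mask = groups == "CM"
            assert res.pvalues[k] == pytest.approx(
                enumeration_oracle(dc[:, k], mask)
            )

    def test_sampled_converges_to_exact(self, rng):
        dc = rng.standard_normal((10, 2))
        groups = np.array(["EM"] * 5 + ["CM"] * 5)
        exact = permutation_group_test(dc, groups, exhaustive=True).pvalues
        B = 20_000
        sampled = permutation_group_test(
            dc, groups, n_permutations=B, seed=0
        ).pvalues
        se = np.sqrt(exact * (1 - exact) / B)
        assert np.all(np.abs(sampled - exact) < 2 * se + 1 / B)

    def test_extreme_statistic_floor(self, rng):
        # observed statistic beyond every sampled null value -> add-one floor
        dc = rng.standard_normal((20, 1))
        dc[10:] += 100.0
        groups = np.array(["EM"] * 10 + ["CM"] * 10)
        res = permutation_group_test(dc, groups, n_permutations=500, seed=1)
        assert res.pvalues[0] == pytest.approx(1 / 501)

    def test_statistic_direction_cm_minus_em(self):
        dc = np.r_[np.zeros(4), np.ones(4)][:, None]
        groups = np.array(["EM"] * 4 + ["CM"] * 4)
        res = permutation_group_test(dc, groups, n_permutations=99, seed=0)
        assert res.observed[0] == pytest.approx(1.0)
        assert res.groups == ("EM", "CM")

    def test_deterministic_given_seed(self, rng):
        dc = rng.standard_normal((12, 4))
        groups = np.array(["EM"] * 7 + ["CM"] * 5)
        a = permutation_group_test(dc, groups, n_permutations=300, seed=9)
        b = permutation_group_test(dc, groups, n_permutations=300, seed=9)
        assert np.array_equal(a.pvalues, b.pvalues)
        assert np.array_equal(a.null, b.null)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_group_test(np.zeros((4, 1)), ["EM"] * 4)

    def test_null_rejection_rate_calibrated(self, rng):
        # identically distributed groups: uncorrected rejections at
        # alpha = 0.05 should occur at about the nominal rate
        hits, trials = 0, 0
        for _ in range(200):
            dc = rng.standard_normal((20, 1))
            groups = np.array(["EM"] * 12 + ["CM"] * 8)
            res = permutation_group_test(dc, groups, n_permutations=199,
                                         seed=int(rng.integers(2**31)))
            hits += (res.pvalues <= 0.05).sum()
            trials += 1
        rate = hits / trials
        assert 0.02 < rate < 0.08  # binomial 95% CI around 0.05 at n=200


class TestBhFdr:
    def test_headline_worked_example(self):
        # m = 7, smallest p = 0.0066, the rest >= 0.30
        p = [0.0066, 0.30, 0.41, 0.52, 0.63, 0.74, 0.85]
        adj, reject = bh_fdr(p, q=0.05)
        assert adj[0] == pytest.approx(0.0462)
        assert reject[0] and not reject[1:].any()

    def test_all_equal_pvalues_unchanged(self):
        adj, _ = bh_fdr([0.2] * 5)
        assert np.allclose(adj, 0.2)

    def test_single_test_identity(self):
        adj, _ = bh_fdr([0.031])
        assert adj[0] == pytest.approx(0.031)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(1e-6, 1, 20)
        adj, _ = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_never_rejects_more_than_unadjusted(self, seed):
        p = np.random.default_rng(seed).uniform(1e-6, 1, 15)
        _, reject = bh_fdr(p, q=0.05)
        assert reject.sum() <= (p <= 0.05).sum()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestAdjustedGroupEffect:
    def make_cohort(self, rng, n=120, effect=1.0, confounded=False):
        group = np.array(["EM"] * (n // 2) + ["CM"] * (n // 2))
        g = (group == "CM").astype(float)
        conf = rng.standard_normal(n) + (2.0 * g if confounded else 0.0)
        dc = (
            (0.0 if confounded else effect) * g
            + (2.0 * conf if confounded else 0.0)
            + rng.standard_normal(n)
        )
        cov = pd.DataFrame(
            {
                "group": group,
                "age": rng.normal(40, 10, n),
                "conf": conf,
            }
        )
        return dc, cov

    def test_independent_covariates_leave_effect(self, rng):
        dc, cov = self.make_cohort(rng, effect=1.5)
        res = adjusted_group_effect(dc, cov, [[], ["age"]])
        p_unadj = res[res.covariate_set == "(unadjusted)"].p.iloc[0]
        p_adj = res[res.covariate_set == "age"].p.iloc[0]
        assert p_unadj < 0.01 and p_adj < 0.01

    def test_confounder_explains_group_difference(self, rng):
        dc, cov = self.make_cohort(rng, confounded=True)
        res = adjusted_group_effect(dc, cov, [[], ["conf"]])
        assert res[res.covariate_set == "(unadjusted)"].p.iloc[0] < 0.01
        assert res[res.covariate_set == "conf"].p.iloc[0] > 0.05

    def test_constant_group_rejected(self, rng):
        cov = pd.DataFrame({"group": ["EM"] * 10, "age": rng.normal(40, 5, 10)})
        with pytest.raises(ValueError):
            adjusted_group_effect(rng.standard_normal(10), cov, [["age"]])

    def test_collinear_design_names_columns(self, rng):
        n = 30
        cov = pd.DataFrame(
            {
                "group": ["EM"] * 15 + ["CM"] * 15,
                "a": rng.standard_normal(n),
            }
        )
        cov["b"] = 2.0 * cov["a"]
        with pytest.raises(ValueError, match="b"):
            adjusted_group_effect(rng.standard_normal(n), cov, [["a", "b"]])

    def test_fdr_across_node_family(self, rng):
        dc = rng.standard_normal((60, 3))
        cov = pd.DataFrame({"group": ["EM"] * 30 + ["CM"] * 30})
        res = adjusted_group_effect(dc, cov, [[]])
        assert len(res) == 3
        assert np.all(res.p_fdr >= res.p - 1e-15)


class TestCorrelateClinical:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = correlate_clinical(x, x)
        assert r == pytest.approx(1.0)

    def test_printed_pair_consistency(self, rng):
        # sample correlation planted exactly at 0.0444 with n = 62
        n, target = 62, 0.0444
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        xs = (x - x.mean()) / x.std()
        ec = e - e.mean()
        ec = ec - (ec @ xs / n) * xs  # orthogonal to x, zero mean
        y = target * xs + np.sqrt(1 - target**2) * ec / ec.std()
        r, p = correlate_clinical(x, y)
        assert r == pytest.approx(target, abs=1e-12)
        assert p == pytest.approx(0.7321, abs=5e-4)

    def test_null_pvalues_uniform(self, rng):
        from scipy.stats import kstest

        ps = [
            correlate_clinical(rng.standard_normal(62), rng.standard_normal(62))[1]
            for _ in range(300)
        ]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_clinical(np.ones(10), np.arange(10.0))


class TestInteraction:
    def test_null_interaction_rate(self, rng):
        hits = 0
        for _ in range(100):
            g = np.array(["EM"] * 30 + ["CM"] * 30)
            m = rng.integers(0, 2, 60).astype(float)
            if len(np.unique(m)) < 2 or any(
                not np.any(((g == "CM") == gv) & (m == mv))
                for gv in (True, False) for mv in (0, 1)
            ):
                continue
            y = (g == "CM") * 0.5 + m * 0.3 + rng.standard_normal(60)
            hits += interaction_effect(y, g, m)["p_interaction"] <= 0.05
        assert hits <= 12  # ~alpha of 100 null fits

    def test_crossover_interaction_detected(self, rng):
        n = 200
        g = np.array(["EM"] * 100 + ["CM"] * 100)
        m = np.tile([0.0, 1.0], 100)
        gi = (g == "CM").astype(float)
        y = gi * (2 * m - 1) + 0.5 * rng.standard_normal(n)  # pure crossover
        assert interaction_effect(y, g, m)["p_interaction"] < 0.01

    def test_constant_moderator_rejected(self, rng):
        g = np.array(["EM"] * 5 + ["CM"] * 5)
        with pytest.raises(ValueError):
            interaction_effect(rng.standard_normal(10), g, np.zeros(10))

    def test_empty_cell_rejected(self, rng):
        g = np.array(["EM"] * 5 + ["CM"] * 5)
        m = np.r_[np.ones(5), np.zeros(5)]  # no EM/moderator=0 cell
        with pytest.raises(ValueError, match="empty cell"):
            interaction_effect(rng.standard_normal(10), g, m)
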