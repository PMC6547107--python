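import numpy as np
import pandas as pd
import pytest
from scipy import stats

from precisionrct import bh_adjust, omnibus_test, pairwise_tests
from precisionrct.profiles import Variable, _categorical_test, summarize_by_group


def make_labels(n_int, n_mut, n_ctl):
    return np.array(
        ["intervention"] * n_int + ["muted"] * n_mut + ["control"] * n_ctl
    )


class TestSummaries:
    def test_continuous_mean_sd(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out = summarize_by_group(df, make_labels(3, 0, 0), [Variable("x", "continuous")])
        assert out.loc[0, "intervention"] == "2.00 (1.00)"

    def test_categorical_percentages(self):
        df = pd.DataFrame({"g": [1.0, 1.0, 1.0, 0.0]})
        out = summarize_by_group(
            df, make_labels(4, 0, 0), [Variable("g", "categorical", (0.0, 1.0))]
        )
        assert out.loc[0, "intervention"] == "1 (25.0%)"
        assert out.loc[1, "intervention"] == "3 (75.0%)"

    def test_skewed_median_iqr(self):
        df = pd.DataFrame({"h": [0.0, 1.0, 2.0, 6.0, 50.0]})
        out = summarize_by_group(df, make_labels(5, 0, 0), [Variable("h", "skewed")])
        assert out.loc[0, "intervention"] == "2 (1-6)"

    def test_empty_group_gives_na(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        out = summarize_by_group(df, make_labels(2, 0, 0), [Variable("x", "continuous")])
        assert out.loc[0, "muted"] == "NA"


class TestOmnibus:
    def test_printed_weight_category_table(self):
        # 3x3 weight-category x assigned-group contingency table
        tab = np.array([[24, 95, 11], [12, 30, 12], [8, 11, 13]], dtype=float)
        res = _categorical_test(tab)
        assert res.test == "chi-square"
        assert res.statistic == pytest.approx(24.67, abs=0.005)
        assert res.df == 4

    def test_chi2_equals_squared_two_proportion_z_on_2x2(self, rng):
        for _ in range(50):
            tab = rng.integers(5, 60, size=(2, 2)).astype(float)
            res = _categorical_test(tab)
            n1, n2 = tab[:, 0].sum(), tab[:, 1].sum()
            p1, p2 = tab[0, 0] / n1, tab[0, 1] / n2
            pool = tab[0].sum() / tab.sum()
            z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
            if res.test == "chi-square":
                assert res.statistic == pytest.approx(z * z, abs=1e-10)

    def test_low_expected_count_switches_to_fisher(self):
        tab = np.array([[2.0, 10.0], [3.0, 30.0]])  # expected[0,0] = 1.33
        res = _categorical_test(tab)
        assert res.test == "fisher-exact"
        _, p = stats.fisher_exact(tab.astype(int))
        assert res.p_raw == pytest.approx(p)

    def test_low_expected_count_rxc_uses_monte_carlo(self):
        tab = np.array([[2.0, 8.0, 1.0], [10.0, 3.0, 9.0], [1.0, 2.0, 12.0]])
        res = _categorical_test(tab, rng=np.random.default_rng(0))
        assert res.test == "fisher-mc"
        assert 0 < res.p_raw <= 1

    def test_anova_type_one_error_calibrated(self):
        # three identical Gaussian groups; rejection rate should be ~alpha
        rng = np.random.default_rng(0)
        reps = 10_000
        a = rng.normal(size=(reps, 30))
        b = rng.normal(size=(reps, 30))
        c = rng.normal(size=(reps, 30))
        _, p = stats.f_oneway(a, b, c, axis=1)
        assert 0.04 <= np.mean(p < 0.05) <= 0.06

    def test_kruskal_for_skewed_variable(self, rng):
        vals = np.concatenate([rng.exponential(1, 40), rng.exponential(3, 40)])
        labels = make_labels(40, 40, 0)
        res = omnibus_test(vals, labels, "skewed")
        assert res.test == "kruskal"
        assert res.p_raw < 0.05

    def test_identical_values_p_one(self):
        res = omnibus_test(np.ones(20), make_labels(10, 10, 0), "continuous")
        assert res.p_raw == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two non-empty"):
            omnibus_test(np.arange(5.0), make_labels(5, 0, 0), "continuous")


class TestPairwise:
    def test_identical_groups_t_statistic_zero(self):
        vals = np.concatenate([np.arange(10.0), np.arange(10.0)])
        res = pairwise_tests(vals, make_labels(10, 10, 0), "continuous")
        assert len(res) == 1
        assert res[0].statistic == pytest.approx(0.0)
        assert res[0].p_raw == pytest.approx(1.0)

    def test_separated_groups_detected(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = np.concatenate([rng.normal(0, 1, 200), rng.normal(1, 1, 200)])
            res = pairwise_tests(vals, make_labels(200, 0, 200), "continuous")
            hits += res[0].p_raw < 0.05
        assert hits >= 99

    def test_three_groups_give_two_comparisons_vs_intervention(self, rng):
        vals = rng.normal(size=60)
        res = pairwise_tests(vals, make_labels(20, 20, 20), "continuous")
        assert sorted(r.comparison for r in res) == [
            "control vs intervention",
            "muted vs intervention",
        ]


def bh_bruteforce(p, alpha):
    """Step-up threshold scan: reject the i smallest p-values where
    p_(i) <= i * alpha / m for the largest such i."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestBH:
    def test_all_rejected_example(self):
        adj, rej = bh_adjust([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert rej.all()
        np.testing.assert_allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        adj, rej = bh_adjust([0.03])
        assert adj[0] == 0.03 and rej[0]

    def test_constant_p_unchanged(self):
        adj, rej = bh_adjust([0.5, 0.5, 0.5])
        np.testing.assert_allclose(adj, 0.5)
        assert not rej.any()

    def test_empty_input(self):
        adj, rej = bh_adjust([])
        assert adj.size == 0 and rej.size == 0

    def test_against_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = int(rng.integers(1, 51))
            p = rng.uniform(size=m)
            if rng.uniform() < 0.3:
                p = np.round(p, 1)  # exercise ties
            adj, rej = bh_adjust(p, alpha=0.05)
            np.testing.assert_array_equal(rej, bh_bruteforce(p, 0.05))
            assert np.all(adj >= p - 1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(2, 30)))
            adj, rej = bh_adjust(p, alpha=0.05)
            sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(adj, sm_adj)
            np.testing.assert_array_equal(rej, sm_rej)

    def test_rejection_monotone_in_p(self, rng):
        p = rng.uniform(size=12)
        _, rej = bh_adjust(p, alpha=0.05)
        p2 = p.copy()
        p2[3] = p2[3] / 2
        _, rej2 = bh_adjust(p2, alpha=0.05)
        assert np.all(rej2 | ~rej)  # lowering a p never removes a rejection

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
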