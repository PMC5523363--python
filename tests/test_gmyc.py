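import math

import numpy as np
import pytest
from scipy.integrate import quad

from gmycdelim import (
    chi2_survival,
    extract_clusters,
    fit_gmyc,
    fit_null,
    interval_loglik,
    parse_newick,
    waiting_intervals,
)
from gmycdelim.gmyc import WaitingIntervalSeries, _fit_single_coalescent
from gmycdelim.synthetic import simulate_coalescent_tree

BALANCED = "((A:1,B:1):2,(C:1,D:1):2);"


class TestWaitingIntervals:
    def test_balanced_tree_with_threshold(self):
        t = parse_newick(BALANCED)
        s = waiting_intervals(t, threshold=2.0)
        # first interval: duration 2, two speciation lineages, no groups
        assert s.x[0] == pytest.approx(2.0, rel=1e-6)
        assert s.n_s[0] == 2
        assert not (s.group_idx == 0).any()
        # the last interval sees two coalescent groups of 2 lineages each
        last = s.n_intervals - 1
        vals = s.group_vals[s.group_idx == last]
        assert sorted(vals) == [2.0, 2.0]

    def test_balanced_tree_null(self):
        t = parse_newick(BALANCED)
        s = waiting_intervals(t, threshold=None)
        assert s.n_intervals == 3
        # root -> tips: durations ~(2, 0, 1), lineages 2, 3, 4
        assert s.x[0] == pytest.approx(2.0, rel=1e-6)
        assert s.x[1] == pytest.approx(0.0, abs=1e-6)
        assert s.x[2] == pytest.approx(1.0, rel=1e-6)
        assert [v * (v - 1) for v in (2, 3, 4)] == list(s.group_vals)
        assert (s.n_s == 0).all()

    def test_caterpillar_lineage_counts(self):
        t = parse_newick("(((A:1,B:1):1,C:2):1,D:3);")
        s = waiting_intervals(t, threshold=None)
        assert list(s.group_vals) == [2.0, 6.0, 12.0]

    def test_too_few_tips_rejected(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="3 tips"):
            waiting_intervals(t)


class TestIntervalLoglik:
    def test_two_lineage_coalescent_closed_form(self):
        # single interval of duration x with 2 lineages: logL = ln(l) - l*x,
        # maximized at l = 1/x giving -ln(x) - 1
        for x, expected in [(1.0, -1.0), (math.e, -2.0)]:
            series = WaitingIntervalSeries(
                x=np.array([x]), n_s=np.array([0.0]),
                group_vals=np.array([2.0]), group_idx=np.array([0]),
            )
            fit = _fit_single_coalescent(series)
            assert fit.loglik == pytest.approx(expected, abs=1e-6)
            # rate b * 2**p = 1/x at the optimum
            assert fit.b * 2 ** fit.p == pytest.approx(1 / x, rel=1e-4)

    def test_loglik_matches_direct_formula(self):
        series = WaitingIntervalSeries(
            x=np.array([0.5, 0.3]), n_s=np.array([0.0, 0.0]),
            group_vals=np.array([6.0, 2.0]), group_idx=np.array([0, 1]),
        )
        b, p = 0.7, 1.2
        rho = b * np.array([6.0, 2.0]) ** p
        expected = float(np.sum(np.log(rho) - rho * np.array([0.5, 0.3])))
        assert interval_loglik(series, b2=b, p2=p) == pytest.approx(expected)

    def test_density_integrates_to_one(self):
        # as a function of the first waiting time, exp(logL) is the
        # exponential density of the first event
        b, p = 0.9, 1.3
        rho = b * 6.0 ** p

        def dens(x):
            series = WaitingIntervalSeries(
                x=np.array([x]), n_s=np.array([0.0]),
                group_vals=np.array([6.0]), group_idx=np.array([0]),
            )
            return math.exp(interval_loglik(series, b2=b, p2=p))

        total, err = quad(dens, 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_non_positive_rate_rejected(self):
        series = WaitingIntervalSeries(
            x=np.array([1.0]), n_s=np.array([0.0]),
            group_vals=np.array([2.0]), group_idx=np.array([0]),
        )
        with pytest.raises(ValueError):
            interval_loglik(series, b2=0.0)


class TestChi2Survival:
    def test_zero_statistic(self):
        assert chi2_survival(0.0, 3) == 1.0

    def test_printed_p_value_at_df3(self):
        assert f"{chi2_survival(12.4592, 3):.3g}" == "0.00596"

    def test_df2_closed_form(self):
        # df=2 survival is exp(-x/2)
        assert chi2_survival(1.386294, 2) == pytest.approx(0.5, abs=1e-6)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            chi2_survival(1.0, 0)


class TestExtractClusters:
    def test_balanced_tree_two_clusters(self):
        t = parse_newick(BALANCED)
        res = extract_clusters(t, 2.0)
        assert res.n_clusters == 2
        assert res.n_singletons == 0
        assert res.partition["A"] == res.partition["B"]
        assert res.partition["A"] != res.partition["C"]

    def test_threshold_above_root_single_cluster(self):
        t = parse_newick(BALANCED)
        res = extract_clusters(t, 10.0)
        assert res.n_entities == 1
        assert res.n_clusters == 1
        assert len(set(res.partition.values())) == 1

    def test_threshold_below_all_nodes_all_singletons(self):
        t = parse_newick(BALANCED)
        res = extract_clusters(t, 0.5)
        assert res.n_singletons == 4
        assert res.n_clusters == 0

    def test_cluster_count_non_increasing_in_threshold(self):
        tree = simulate_coalescent_tree(15, seed=3)
        heights = sorted(n.height for n in tree.internal_nodes())
        entities = [
            extract_clusters(tree, t).n_entities
            for t in np.linspace(1e-6, tree.height * 1.1, 50)
        ]
        assert all(a >= b for a, b in zip(entities, entities[1:]))


class TestFitNull:
    def test_loglik_consistent_with_interval_loglik(self):
        tree = simulate_coalescent_tree(12, seed=1)
        fit = fit_null(tree)
        series = waiting_intervals(tree, None)
        assert interval_loglik(series, b2=fit.b, p2=fit.p) == pytest.approx(
            fit.loglik
        )

    def test_height_rescaling_shifts_loglik_by_known_constant(self):
        tree = simulate_coalescent_tree(12, seed=2)
        c = 3.7
        f1 = fit_null(tree)
        f2 = fit_null(tree.scaled(c))
        m = waiting_intervals(tree, None).n_intervals
        assert f2.loglik == pytest.approx(f1.loglik - m * math.log(c), rel=1e-6)
        assert f2.b * 2 ** f2.p == pytest.approx(
            (f1.b * 2 ** f1.p) / c, rel=1e-2
        )


class TestFitGMYC:
    def test_nesting_alt_at_least_null(self):
        for seed in range(4):
            tree = simulate_coalescent_tree(10, seed=seed)
            fit = fit_gmyc(tree)
            assert fit.loglik_alt >= fit.loglik_null
            assert fit.lr >= 0

    def test_lr_invariant_under_rescaling(self):
        tree = simulate_coalescent_tree(10, seed=7)
        f1 = fit_gmyc(tree)
        f2 = fit_gmyc(tree.scaled(10.0))
        assert f2.lr == pytest.approx(f1.lr, abs=0.05)

    def test_fixture_recovers_three_clusters(self, fixture_tree):
        fit = fit_gmyc(fixture_tree)
        assert fit.clusters.n_clusters == 3
        assert fit.p_value < 0.05
        # every well-supported solution keeps the three species separate
        assert min(c.n_clusters for c in fit.confidence_set) >= 3

    def test_summary_keys(self, fixture_tree):
        s = fit_gmyc(fixture_tree).summary()
        for key in ("loglik_null", "loglik_alt", "lr", "p_value",
                    "threshold", "n_clusters"):
            assert key in s
        assert s["lr"] == pytest.approx(
            2 * (s["loglik_alt"] - s["loglik_null"])
        )
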