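import random

import numpy as np
import pytest

from astomecoev.reconcile import (
    CostScheme,
    EventCounts,
    SolverConfig,
    Tanglegram,
    cost_scheme_presets,
    random_binary_topology,
    random_tree_test,
    reconcile_exact,
    reconcile_search,
    reconciliation_cost,
)
from astomecoev.simulate import SimConfig, simulate_cophylogeny, simulate_host_tree
from conftest import tree


JANE = cost_scheme_presets()["jane_default"]


def simulated_tanglegrams(n, tip_range=(4, 7), seed0=0, max_symb=8):
    """Deterministic stream of small simulated tanglegrams."""
    out = []
    seed = seed0
    while len(out) < n:
        rng = random.Random(seed)
        n_tips = rng.randint(*tip_range)
        cfg = SimConfig(n_host_tips=n_tips, cospeciation_prob=0.6, loss_prob=0.3,
                        ftd_prob=0.1, duplication_rate=0.5, switch_rate=0.5,
                        seed=seed)
        sim = simulate_cophylogeny(cfg)
        if sim.tanglegram.n_symbiont_tips <= max_symb:
            out.append(sim)
        seed += 1
    return out


class TestCostSchemes:
    def test_all_ten_presets_with_exact_vectors(self):
        presets = cost_scheme_presets()
        expected = {
            "jane_default": (0, 1, 2, 1, 1),
            "treemap_default": (0, 1, 1, 1, 1),
            "treefitter_default": (0, 0, 2, 1, 1),
            "codivergence_adjusted": (1, 0, 1, 1, 1),
            "host_switch_adjusted": (0, 0, 1, 1, 1),
            "cospeciation_prohibited": (10, 1, 1, 1, 1),
            "host_switch_prohibited": (1, 1, 10, 1, 1),
            "sorting_prohibited": (1, 1, 1, 10, 1),
            "ftd_prohibitive": (1, 1, 1, 1, 10),
            "equal_weights": (1, 1, 1, 1, 1),
        }
        assert set(presets) == set(expected)
        for name, vec in expected.items():
            assert presets[name].as_tuple() == vec

    def test_cost_is_dot_product(self):
        counts = EventCounts(5, 8, 7, 1, 3)
        assert reconciliation_cost(counts, JANE) == 26
        assert reconciliation_cost(
            counts, cost_scheme_presets()["host_switch_adjusted"]) == 11

    def test_negative_costs_rejected(self):
        with pytest.raises(ValueError):
            CostScheme(-1, 0, 0, 0, 0)


class TestTanglegram:
    def test_unlinked_tip_rejected(self):
        with pytest.raises(ValueError, match="links"):
            Tanglegram(host=tree("(a:1,b:1);"), symbiont=tree("(x:1,y:1);"),
                       links={"x": {"a"}})

    def test_unknown_host_rejected(self):
        with pytest.raises(ValueError, match="unknown host"):
            Tanglegram(host=tree("(a:1,b:1);"), symbiont=tree("(x:1,y:1);"),
                       links={"x": {"a"}, "y": {"zzz"}})


class TestExactSolver:
    def test_perfect_cherry(self, perfect_cherry_tanglegram):
        s = reconcile_exact(perfect_cherry_tanglegram, JANE)
        assert s.best_cost == 0
        assert s.counts_set == [EventCounts(1, 0, 0, 0, 0)]

    def test_perfect_three_tips(self, perfect_three_tanglegram):
        s = reconcile_exact(perfect_three_tanglegram, JANE)
        assert s.best_cost == 0
        assert s.counts_set == [EventCounts(2, 0, 0, 0, 0)]

    def test_multihost_tip_forces_one_ftd(self, host_cherry):
        tg = Tanglegram(host=host_cherry, symbiont=tree("t;"),
                        links={"t": {"a", "b"}})
        s = reconcile_exact(tg, JANE)
        assert s.best_cost == 1
        assert s.counts_set == [EventCounts(0, 0, 0, 0, 1)]

    def test_oversize_instance_directed_to_heuristic(self):
        sim = simulated_tanglegrams(1, tip_range=(9, 9), max_symb=30)[0]
        with pytest.raises(ValueError, match="heuristic"):
            reconcile_exact(sim.tanglegram, JANE)

    def test_internal_node_conservation_and_cost_rederivation(self):
        for sim in simulated_tanglegrams(20):
            s = reconcile_exact(sim.tanglegram, JANE)
            n_internal = sum(
                1 for nd in sim.tanglegram.symbiont.preorder_node_iter()
                if not nd.is_leaf())
            for counts in s.counts_set:
                assert (counts.n_cospeciation + counts.n_duplication
                        + counts.n_switch) == n_internal
                assert reconciliation_cost(counts, JANE) == pytest.approx(
                    s.best_cost)
            rep = s.representative
            assert rep.total_cost == pytest.approx(s.best_cost)
            assert reconciliation_cost(rep.counts, JANE) == rep.total_cost

    def test_true_history_is_feasible_upper_bound(self):
        for sim in simulated_tanglegrams(25):
            opt = reconcile_exact(sim.tanglegram, JANE,
                                  enumerate_counts=False).best_cost
            assert opt <= reconciliation_cost(sim.true_events, JANE) + 1e-9


class TestHeuristicSearch:
    def test_agrees_with_exact_on_small_instances(self):
        for k, sim in enumerate(simulated_tanglegrams(30)):
            exact = reconcile_exact(sim.tanglegram, JANE,
                                    enumerate_counts=False).best_cost
            cfg = SolverConfig(generations=40, population_size=24, seed=k)
            found = reconcile_search(sim.tanglegram, JANE, cfg,
                                     enumerate_counts=False).best_cost
            assert found == pytest.approx(exact)

    def test_cospeciation_only_costs_zero(self):
        cfg = SimConfig(n_host_tips=7, cospeciation_prob=1.0, loss_prob=0.0,
                        ftd_prob=0.0, duplication_rate=0.0, switch_rate=0.0,
                        seed=5)
        sim = simulate_cophylogeny(cfg)
        s = reconcile_search(sim.tanglegram, JANE,
                             SolverConfig(generations=20, population_size=16,
                                          seed=1), enumerate_counts=False)
        assert s.best_cost == 0

    def test_seed_reproducibility(self):
        sim = simulated_tanglegrams(1, seed0=3)[0]
        cfg = SolverConfig(generations=30, population_size=16, seed=9)
        a = reconcile_search(sim.tanglegram, JANE, cfg)
        b = reconcile_search(sim.tanglegram, JANE, cfg)
        assert a.best_cost == b.best_cost
        assert a.counts_set == b.counts_set

    def test_raising_switch_cost_never_lowers_optimum(self):
        base = CostScheme(0, 1, 1, 1, 1)
        raised = CostScheme(0, 1, 3, 1, 1)
        for sim in simulated_tanglegrams(30):
            c_base = reconcile_exact(sim.tanglegram, base,
                                     enumerate_counts=False).best_cost
            c_raised = reconcile_exact(sim.tanglegram, raised,
                                       enumerate_counts=False).best_cost
            assert c_raised >= c_base - 1e-9

    def test_prohibitive_switch_cost_yields_switch_free_solutions(self):
        scheme = cost_scheme_presets()["host_switch_prohibited"]
        for sim in simulated_tanglegrams(10):
            s = reconcile_exact(sim.tanglegram, scheme)
            assert all(c.n_switch == 0 for c in s.counts_set)


class TestRandomTreeTest:
    def test_p_value_formula_bounds(self, perfect_three_tanglegram):
        res = random_tree_test(perfect_three_tanglegram, JANE, n_samples=20,
                               config=SolverConfig(seed=0))
        k = sum(1 for c in res.null_costs if c <= res.observed_cost)
        assert res.p_value == pytest.approx((1 + k) / 21)
        assert 0 < res.p_value <= 1

    def test_strong_codivergence_is_significant(self):
        cfg = SimConfig(n_host_tips=8, cospeciation_prob=1.0, loss_prob=0.0,
                        ftd_prob=0.0, duplication_rate=0.0, switch_rate=0.0,
                        seed=2)
        sim = simulate_cophylogeny(cfg)
        res = random_tree_test(sim.tanglegram, JANE, n_samples=99,
                               config=SolverConfig(seed=0))
        assert res.observed_cost == 0
        assert res.p_value < 0.05

    def test_null_calibration_is_valid_and_conservative(self):
        # the cost statistic is coarse on small instances, so ties make the
        # (k+1)/(N+1) p conservative: the test should rarely reject its own null
        rng = random.Random(0)
        ps = []
        for rep in range(30):
            host = simulate_host_tree(6, seed=rep)
            labels = [f"S{i}" for i in range(1, 7)]
            symb = random_binary_topology(labels, random.Random(1000 + rep))
            links = {s: {rng.choice([f"H{i}" for i in range(1, 7)])}
                     for s in labels}
            tg = Tanglegram(host=host, symbiont=symb, links=links)
            res = random_tree_test(tg, JANE, n_samples=49,
                                   config=SolverConfig(seed=rep))
            ps.append(res.p_value)
        assert sum(1 for p in ps if p <= 0.05) <= 3
        assert 0.4 < np.mean(ps) < 0.9

    def test_shuffle_null_and_invalid_sample_count(self, perfect_three_tanglegram):
        res = random_tree_test(perfect_three_tanglegram, JANE, n_samples=10,
                               config=SolverConfig(seed=1), null="shuffle")
        assert len(res.null_costs) == 10
        with pytest.raises(ValueError):
            random_tree_test(perfect_three_tanglegram, JANE, n_samples=0)


class TestRandomTopology:
    def test_uniform_generator_over_three_tip_trees(self):
        # a rooted 3-leaf topology is identified by its cherry pair; the
        # uniform model gives each of the 3 topologies probability 1/3
        rng = random.Random(0)
        counts = {}
        for _ in range(300):
            t = random_binary_topology(["a", "b", "c"], rng)
            for nd in t.preorder_node_iter():
                kids = nd.child_nodes()
                if len(kids) == 2 and all(k.is_leaf() for k in kids):
                    cherry = frozenset(k.taxon.label for k in kids)
                    counts[cherry] = counts.get(cherry, 0) + 1
                    break
        assert len(counts) == 3
        assert all(c > 60 for c in counts.values())  # ~100 each expected
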