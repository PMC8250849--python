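import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from astomecoev.parafit import (
    LinkMatrix,
    parafit_global,
    parafit_links,
    pcoa_lingoes,
)
from astomecoev.seqio import DistanceMatrix, p_distance_matrix
from conftest import random_symmetric_distances


def dm(labels, values):
    return DistanceMatrix(labels=list(labels), values=np.asarray(values, float))


class TestPcoaLingoes:
    def test_collinear_points_recovered(self):
        # points at 0, 1, 2 on a line: one positive eigenvalue 2, axis
        # coordinates (+-1, 0) up to sign
        r = pcoa_lingoes(dm("abc", [[0, 1, 2], [1, 0, 1], [2, 1, 0]]))
        assert r.lingoes_constant == 0.0
        assert r.eigenvalues == pytest.approx([2.0])
        axis = r.coordinates[:, 0]
        assert sorted(axis) == pytest.approx([-1.0, 0.0, 1.0], abs=1e-9)

    def test_euclidean_distances_need_no_correction(self):
        pts = np.random.default_rng(0).random((6, 3))
        r = pcoa_lingoes(dm("abcdef", squareform(pdist(pts))))
        assert r.lingoes_constant == 0.0

    def test_non_euclidean_triple_corrected(self):
        r = pcoa_lingoes(dm("abc", [[0, 1, 3], [1, 0, 1], [3, 1, 0]]))
        assert r.lingoes_constant > 0
        assert (r.eigenvalues >= -1e-10).all()

    def test_coordinates_reconstruct_corrected_distances(self):
        d = dm("abc", [[0, 1, 3], [1, 0, 1], [3, 1, 0]])
        r = pcoa_lingoes(d)
        # corrected squared distances: d^2 + 2c off-diagonal
        d_sq = d.values ** 2 + 2 * r.lingoes_constant
        np.fill_diagonal(d_sq, 0.0)
        rec = squareform(pdist(r.coordinates)) ** 2
        assert np.allclose(rec, d_sq, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        bad = dm("ab", [[0, 1], [1, 0]])
        bad.values = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa_lingoes(bad)


def small_system(seed=0, n_hosts=4, n_symb=3):
    rng = np.random.default_rng(seed)
    d_host = random_symmetric_distances(rng, [f"h{i}" for i in range(n_hosts)])
    d_symb = random_symmetric_distances(rng, [f"s{i}" for i in range(n_symb)])
    a = np.zeros((n_hosts, n_symb))
    for j in range(n_symb):
        a[rng.integers(0, n_hosts), j] = 1.0
    links = LinkMatrix(hosts=d_host.labels, symbionts=d_symb.labels, values=a)
    return d_host, d_symb, links


class TestParafitGlobal:
    def test_statistic_nonnegative_and_relabel_invariant(self):
        d_host, d_symb, links = small_system(1)
        res = parafit_global(d_host, d_symb, links, n_permutations=9, seed=0)
        assert res.global_statistic >= 0
        # consistently permuting host rows of the distance matrix and links
        # leaves the statistic unchanged
        perm = [2, 0, 3, 1]
        d_host2 = DistanceMatrix(
            labels=[d_host.labels[i] for i in perm],
            values=d_host.values[np.ix_(perm, perm)])
        links2 = LinkMatrix(hosts=d_host2.labels, symbionts=links.symbionts,
                            values=links.values[perm, :])
        res2 = parafit_global(d_host2, d_symb, links2, n_permutations=9, seed=0)
        assert res2.global_statistic == pytest.approx(res.global_statistic)

    def test_two_by_two_matches_exhaustive_enumeration(self):
        # with 2 hosts there are 2 permutations per symbiont column, 4 in all;
        # the sampled p must approach the exhaustively enumerated p
        rng = np.random.default_rng(3)
        d_host = random_symmetric_distances(rng, ["h0", "h1"])
        d_symb = random_symmetric_distances(rng, ["s0", "s1"])
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        links = LinkMatrix(hosts=d_host.labels, symbionts=d_symb.labels, values=a)
        res = parafit_global(d_host, d_symb, links, n_permutations=999, seed=0)

        from astomecoev.parafit import _coords_for, _global_stat
        h = _coords_for(d_host, links.hosts)
        p = _coords_for(d_symb, links.symbionts)
        null = []
        for p0, p1 in itertools.product([(0, 1), (1, 0)], repeat=2):
            a_perm = np.column_stack([a[list(p0), 0], a[list(p1), 1]])
            null.append(_global_stat(h, p, a_perm))
        obs = _global_stat(h, p, a)
        p_exact = (1 + sum(1 for s in null if s >= obs - 1e-12)) / (len(null) + 1)
        assert abs(res.p_global - p_exact) < 0.12

    def test_empty_and_zero_link_matrices_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            LinkMatrix(hosts=["h0"], symbionts=["s0"], values=np.zeros((1, 1)))
        with pytest.raises(ValueError, match="no links"):
            LinkMatrix(hosts=["h0", "h1"], symbionts=["s0", "s1"],
                       values=np.array([[1.0, 0.0], [1.0, 0.0]]))

    def test_seed_reproducibility(self):
        d_host, d_symb, links = small_system(5)
        r1 = parafit_global(d_host, d_symb, links, n_permutations=49, seed=3)
        r2 = parafit_global(d_host, d_symb, links, n_permutations=49, seed=3)
        assert r1.p_global == r2.p_global

    def test_codivergence_positive_control(self):
        # cospeciation-only tanglegrams with sequence-derived distances are
        # recognised as congruent in most replicates
        from astomecoev.simulate import (SimConfig, simulate_alignment,
                                         simulate_cophylogeny)
        hits = 0
        for seed in range(20):
            cfg = SimConfig(n_host_tips=16, cospeciation_prob=1.0,
                            loss_prob=0.0, ftd_prob=0.0, duplication_rate=0.0,
                            switch_rate=0.0, subst_scale=0.2, seed=seed)
            tg = simulate_cophylogeny(cfg).tanglegram
            d_host = p_distance_matrix(
                simulate_alignment(tg.host, 2000, seed=seed + 500))
            d_symb = p_distance_matrix(
                simulate_alignment(tg.symbiont, 2000, seed=seed + 900))
            hosts, symbs = d_host.labels, d_symb.labels
            a = np.zeros((len(hosts), len(symbs)))
            for j, s in enumerate(symbs):
                (h,) = tg.links[s]
                a[hosts.index(h), j] = 1.0
            links = LinkMatrix(hosts=hosts, symbionts=symbs, values=a)
            res = parafit_global(d_host, d_symb, links, n_permutations=999,
                                 seed=seed)
            hits += res.p_global <= 0.05
        assert hits > 10  # majority of replicates reject independence


class TestParafitLinks:
    def test_single_link_statistic_equals_global(self):
        rng = np.random.default_rng(7)
        d_host = random_symmetric_distances(rng, ["h0", "h1", "h2"])
        d_symb = random_symmetric_distances(rng, ["s0"])
        a = np.array([[1.0], [0.0], [0.0]])
        links = LinkMatrix(hosts=d_host.labels, symbionts=d_symb.labels, values=a)
        res = parafit_links(d_host, d_symb, links, n_permutations=19, seed=0)
        (_, _, stat, _) = res.per_link[0]
        assert stat == pytest.approx(res.global_statistic)

    def test_link_statistics_match_explicit_removal_oracle(self):
        d_host, d_symb, links = small_system(9, n_hosts=3, n_symb=3)
        res = parafit_links(d_host, d_symb, links, n_permutations=19, seed=0)
        from astomecoev.parafit import _coords_for, _global_stat
        h = _coords_for(d_host, links.hosts)
        p = _coords_for(d_symb, links.symbionts)
        for host, symb, stat, _p in res.per_link:
            i, j = links.hosts.index(host), links.symbionts.index(symb)
            a_red = links.values.copy()
            a_red[i, j] = 0.0
            expected = (_global_stat(h, p, links.values)
                        - _global_stat(h, p, a_red))
            assert stat == pytest.approx(expected, abs=1e-12)

    def test_duplicated_links_get_equal_statistics(self):
        rng = np.random.default_rng(11)
        d_host = random_symmetric_distances(rng, ["h0", "h1"])
        d_symb = DistanceMatrix(labels=["s0", "s1"],
                                values=np.zeros((2, 2)))  # identical symbionts
        a = np.array([[1.0, 1.0], [0.0, 0.0]])
        links = LinkMatrix(hosts=d_host.labels, symbionts=d_symb.labels, values=a)
        res = parafit_links(d_host, d_symb, links, n_permutations=19, seed=0)
        stats = [s for _, _, s, _ in res.per_link]
        assert stats[0] == pytest.approx(stats[1], abs=1e-12)


class TestCalibration:
    def test_type_one_error_p_values_approximately_uniform(self):
        # links independent of both trees: p should be near-uniform
        from scipy.stats import kstest
        ps = []
        for seed in range(200):
            d_host, d_symb, links = small_system(seed, n_hosts=6, n_symb=5)
            res = parafit_global(d_host, d_symb, links, n_permutations=99,
                                 seed=seed + 10000)
            ps.append(res.p_global)
        stat = kstest(ps, "uniform").statistic
        assert stat < 0.12
        assert sum(1 for p in ps if p <= 0.05) <= 0.10 * len(ps)
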