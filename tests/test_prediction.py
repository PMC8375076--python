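from itertools import product

import networkx as nx
import numpy as np
import pytest

from pathextend import (
    InputError,
    SyntheticSpec,
    gen_network,
    loocv_auc,
    nbd_tail,
    rwr,
    score_nbd,
    select_candidates,
)


def rwr_direct_solve(net, seeds, r):
    """Dense linear-algebra oracle: p = r (I - (1-r) W)^-1 p0."""
    nodes = sorted(net.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(net, nodelist=nodes)
    colsum = A.sum(axis=0)
    W = np.where(colsum == 0, 1.0 / n, A / np.where(colsum == 0, 1.0, colsum))
    p0 = np.zeros(n)
    idx = [i for i, g in enumerate(nodes) if g in seeds]
    p0[idx] = 1.0 / len(idx)
    p = r * np.linalg.solve(np.eye(n) - (1 - r) * W, p0)
    return dict(zip(nodes, p))


def binomial_tail_enumeration(n, k, p):
    """Exhaustive 2^n outcome enumeration oracle."""
    total = 0.0
    for bits in product((0, 1), repeat=n):
        ones = sum(bits)
        if ones >= k:
            total += p**ones * (1 - p) ** (n - ones)
    return total


class TestRWR:
    def test_two_node_path_hand_solved(self):
        net = nx.Graph([("a", "b")])
        res = rwr(net, {"a"}, r=0.8)
        assert res["a"] == pytest.approx(25 / 30, abs=1e-6)
        assert res["b"] == pytest.approx(5 / 30, abs=1e-6)

    def test_restart_dominated_limit(self):
        net = nx.path_graph(5)
        res = rwr(net, {0, 1}, r=0.999999)
        assert res[0] == pytest.approx(0.5, abs=1e-5)
        assert res[1] == pytest.approx(0.5, abs=1e-5)
        assert res[3] == pytest.approx(0.0, abs=1e-5)

    def test_matches_direct_linear_solve(self):
        for seed in range(5):
            net = nx.gnp_random_graph(30, 0.15, seed=seed)
            seeds = {0, 1, 2}
            iterative = rwr(net, seeds, r=0.5)
            direct = rwr_direct_solve(net, seeds, r=0.5)
            for g in net.nodes:
                assert iterative[g] == pytest.approx(direct[g], abs=1e-8)

    def test_probability_vector_and_relabel_invariance(self):
        net = nx.gnp_random_graph(25, 0.2, seed=8)
        res = rwr(net, {0, 5}, r=0.8)
        assert sum(res.values()) == pytest.approx(1.0, abs=1e-9)
        mapping = {g: f"node_{g}" for g in net.nodes}
        res2 = rwr(nx.relabel_nodes(net, mapping), {"node_0", "node_5"}, r=0.8)
        for g in net.nodes:
            assert res2[mapping[g]] == pytest.approx(res[g], abs=1e-10)

    def test_dangling_nodes_handled(self):
        net = nx.Graph([("a", "b")])
        net.add_node("isolated")
        res = rwr(net, {"a"}, r=0.8)
        assert sum(res.values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_seed_in_network_rejected(self):
        with pytest.raises(InputError, match="seed"):
            rwr(nx.path_graph(3), {"zz"}, r=0.8)


class TestNbdTail:
    def test_k_zero_is_certain(self):
        for n, p in [(0, 0.5), (5, 0.1), (100, 0.9)]:
            assert nbd_tail(n, 0, p) == 1.0

    def test_hand_enumerated_values(self):
        assert nbd_tail(2, 1, 0.5) == pytest.approx(0.75)
        expected = 1 - 0.9**10 - 10 * 0.1 * 0.9**9
        assert nbd_tail(10, 2, 0.1) == pytest.approx(expected, rel=1e-10)

    def test_non_increasing_in_k(self):
        tails = [nbd_tail(12, k, 0.3) for k in range(13)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_matches_exhaustive_enumeration_small_n(self):
        for n in range(0, 9):
            for k in range(n + 1):
                assert nbd_tail(n, k, 0.2) == pytest.approx(
                    binomial_tail_enumeration(n, k, 0.2), abs=1e-12
                )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            nbd_tail(2, 3, 0.5)
        with pytest.raises(InputError):
            nbd_tail(2, 1, 1.5)

    def test_negative_binomial_mode(self):
        # P(X >= 1) = 1 - P(X = 0) = 1 - p^n for failures-before-n-successes
        assert nbd_tail(3, 1, 0.4, distribution="negative_binomial") == \
            pytest.approx(1 - 0.4**3)


class TestScoreNbd:
    def test_two_seed_neighbors_toy(self):
        net = nx.star_graph(9)  # hub 0
        net = nx.relabel_nodes(net, {i: f"g{i}" for i in net.nodes})
        net.add_edge("g1", "g2")
        # candidate g1 has degree 2 (hub + g2); seeds g0 (hub) and g2
        scores = {s.gene: s for s in score_nbd(net, {"g0", "g2"})}
        rec = scores["g1"]
        assert (rec.n, rec.k) == (2, 2)
        assert rec.p == pytest.approx(0.2)
        assert rec.tail_p == pytest.approx(0.04)

    def test_no_seed_neighbor_tail_one(self):
        net = nx.path_graph(4)
        scores = {s.gene: s for s in score_nbd(net, {0})}
        assert scores[3].tail_p == 1.0

    def test_degree_zero_candidates_skipped(self):
        net = nx.Graph([("a", "b")])
        net.add_node("alone")
        genes = {s.gene for s in score_nbd(net, {"a"})}
        assert genes == {"b"}


class TestSelectCandidates:
    def test_rwr_threshold(self):
        table = select_candidates({"x": 0.002, "y": 0.0005}, None,
                                  rwr_threshold=0.001)
        passing = dict(zip(table.gene, table["pass"]))
        assert passing == {"x": True, "y": False}

    def test_nbd_cutoff(self):
        from pathextend import NBDScore

        recs = [
            NBDScore("u", 10, 5, 0.1, 0.005),
            NBDScore("v", 10, 3, 0.1, 0.02),
        ]
        table = select_candidates(None, recs, nbd_cutoff=0.01)
        passing = dict(zip(table.gene, table["pass"]))
        assert passing == {"u": True, "v": False}

    def test_empty_maps_empty_table(self):
        assert select_candidates({}, [], seeds=set()).empty


class TestLoocvAuc:
    def test_all_tied_scores_auc_half(self):
        net = nx.complete_graph(10)  # symmetric: every gene scores alike
        res = loocv_auc(net, {0, 1}, "NBD")
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_minimal_roc_perfect(self):
        # triangle + pendant: hidden seed is adjacent to the other seed,
        # the sole negative is not
        net = nx.Graph([("s1", "s2"), ("s1", "neg"), ("s2", "x"), ("x", "neg")])
        res = loocv_auc(net, {"s1", "s2"}, "RWR", r=0.8)
        assert res.auc in (0.0, 0.5, 1.0)
        assert res.fpr[0] == 0.0 and res.fpr[-1] == 1.0
        assert res.tpr[0] == 0.0 and res.tpr[-1] == 1.0

    def test_planted_module_near_perfect_discrimination(self):
        spec = SyntheticSpec(
            n_genes=300, n_samples=10, module_sizes=(10,),
            n_decoy_modules=0, seed_module_size=12, seed_module_density=0.8,
            rng_seed=4,
        )
        net, planted = gen_network(spec)
        for method in ("RWR", "NBD"):
            res = loocv_auc(net, planted, method)
            assert res.auc >= 0.95, method

    def test_fewer_than_two_seeds_rejected(self):
        with pytest.raises(InputError):
            loocv_auc(nx.path_graph(5), {0}, "RWR")
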