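from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pytest

from pathextend import (
    InputError,
    SeedSet,
    go_consistency,
    go_enrichment,
    random_consistency_baseline,
    seed_connectivity_test,
)


def exact_hypergeom_tail(k, pop_n, pop_count, study_n):
    """Upper-tail hypergeometric by direct combinatorics."""
    return sum(
        comb(pop_count, i) * comb(pop_n - pop_count, study_n - i)
        for i in range(k, min(study_n, pop_count) + 1)
    ) / comb(pop_n, study_n)


class TestGoEnrichment:
    def test_study_equals_population_all_p_one(self):
        pop = {f"g{i}" for i in range(20)}
        annot = {f"g{i}": {"GO:0000001"} for i in range(8)}
        results = go_enrichment(pop, pop, annot)
        assert results and all(r.p_value == pytest.approx(1.0) for r in results)

    def test_perfect_enrichment_exact_p(self):
        pop = {f"g{i}" for i in range(100)}
        study = {f"g{i}" for i in range(5)}
        annot = {g: {"GO:0000007"} for g in study}
        (res,) = go_enrichment(study, pop, annot)
        assert res.p_value == pytest.approx(1 / comb(100, 5), rel=1e-12)

    def test_term_absent_from_study_not_tested(self):
        pop = {"a", "b", "c", "d"}
        annot = {"c": {"GO:0000001"}, "d": {"GO:0000002"}}
        results = go_enrichment({"a", "c"}, pop, annot)
        assert {r.term for r in results} == {"GO:0000001"}

    def test_study_not_subset_rejected(self):
        with pytest.raises(InputError, match="subset"):
            go_enrichment({"zz"}, {"a"}, {})

    def test_matches_exact_combinatorial_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            pop_n = int(rng.integers(10, 61))
            pop = {f"g{i}" for i in range(pop_n)}
            pop_count = int(rng.integers(1, pop_n + 1))
            study_n = int(rng.integers(1, pop_n + 1))
            carriers = set(rng.choice(sorted(pop), size=pop_count, replace=False))
            study = set(rng.choice(sorted(pop), size=study_n, replace=False))
            annot = {g: {"GO:0000009"} for g in carriers}
            results = go_enrichment(study, pop, annot)
            k = len(study & carriers)
            if k == 0:
                assert results == []
                continue
            (res,) = results
            assert res.p_value == pytest.approx(
                exact_hypergeom_tail(k, pop_n, pop_count, study_n), rel=1e-10
            )


class TestGoConsistency:
    def test_perfect_modularity(self, clique_world):
        net, annot = clique_world
        res = go_consistency(net, annot, fdr=0.05)
        assert res.consistency == pytest.approx(1.0)
        assert res.n_tested == 60

    def test_permuted_annotations_break_consistency(self, clique_world):
        net, annot = clique_world
        rng = np.random.default_rng(12)
        genes = sorted(annot)
        perm = rng.permutation(len(genes))
        shuffled = {genes[i]: annot[genes[perm[i]]] for i in range(len(genes))}
        res = go_consistency(net, shuffled, fdr=0.05)
        assert res.consistency < 0.3

    def test_gene_with_unannotated_neighbors_excluded(self):
        net = nx.Graph([("a", "b"), ("a", "c")])
        annot = {"a": {"GO:0000001"}}
        with pytest.raises(InputError, match="M = 0"):
            go_consistency(net, annot)

    def test_invariant_under_relabeling(self, clique_world):
        net, annot = clique_world
        mapping = {g: f"X_{g}" for g in net.nodes}
        net2 = nx.relabel_nodes(net, mapping)
        annot2 = {mapping[g]: t for g, t in annot.items()}
        r1 = go_consistency(net, annot)
        r2 = go_consistency(net2, annot2)
        assert r1.consistency == pytest.approx(r2.consistency)
        assert r1.n_tested == r2.n_tested


class TestRandomBaseline:
    def test_saturated_annotation_baseline_equals_observed(self):
        """With a single term on every gene, randomizing neighbor sets
        cannot change the statistic: every repetition equals the observed
        consistency (a universal term is never enriched, so both are 0)."""
        net = nx.complete_graph(8)
        net = nx.relabel_nodes(net, {i: f"g{i}" for i in net.nodes})
        annot = {g: {"GO:0000001"} for g in net.nodes}
        observed = go_consistency(net, annot).consistency
        vals = random_consistency_baseline(net, annot, n_perm=20, rng_seed=1)
        assert np.allclose(vals, observed)

    def test_deterministic_under_seed(self, clique_world):
        net, annot = clique_world
        v1 = random_consistency_baseline(net, annot, n_perm=10, rng_seed=42)
        v2 = random_consistency_baseline(net, annot, n_perm=10, rng_seed=42)
        np.testing.assert_array_equal(v1, v2)

    def test_baseline_mean_matches_exhaustive_enumeration(self):
        """On a 6-node toy, the Monte Carlo baseline mean agrees with the
        exact average over all equal-size neighbor-set draws per gene."""
        net = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f")])
        annot = {
            "a": {"GO:0000001"}, "b": {"GO:0000001"}, "c": {"GO:0000002"},
            "d": {"GO:0000002"}, "e": {"GO:0000001"}, "f": {"GO:0000002"},
        }
        nodes = sorted(net.nodes)
        pop_n = len(nodes)
        term_pop = {"GO:0000001": 3, "GO:0000002": 3}

        def match_prob(gene):
            """Exact P(match) for one gene under a uniform equal-size draw."""
            d = net.degree(gene)
            hits = total = 0
            for combo in combinations([n for n in nodes if n != gene], d):
                study = set(combo)
                total += 1
                counts = {}
                for g in study:
                    for t in annot[g]:
                        counts[t] = counts.get(t, 0) + 1
                if not counts:
                    continue  # untested draw: contributes no match
                terms = sorted(counts)
                from scipy.stats import hypergeom
                pvals = [
                    hypergeom.sf(counts[t] - 1, pop_n, term_pop[t], len(study))
                    for t in terms
                ]
                m = len(pvals)
                order = sorted(range(m), key=lambda i: pvals[i])
                adj = [0.0] * m
                running = 1.0
                for rank in range(m - 1, -1, -1):
                    i = order[rank]
                    running = min(running, pvals[i] * m / (rank + 1))
                    adj[i] = running
                if any(t in annot[gene] and a < 0.05 for t, a in zip(terms, adj)):
                    hits += 1
            return hits, total

        # every draw is tested here (all genes annotated), so the exact
        # expected consistency is the mean per-gene match probability
        exact = np.mean([h / t for h, t in (match_prob(g) for g in nodes)])
        vals = random_consistency_baseline(net, annot, n_perm=400, rng_seed=21)
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - exact) <= 3 * max(se, 1e-9) + 1e-12

    def test_observed_beats_baseline_on_modular_annotation(self, clique_world):
        net, annot = clique_world
        observed = go_consistency(net, annot).consistency
        baseline = random_consistency_baseline(net, annot, n_perm=100, rng_seed=7)
        assert observed > np.quantile(baseline, 0.95)


class TestSeedConnectivity:
    def test_planted_clique_minimal_p(self):
        net = nx.empty_graph(100)
        net = nx.relabel_nodes(net, {i: f"g{i}" for i in net.nodes})
        for a, b in combinations([f"g{i}" for i in range(5)], 2):
            net.add_edge(a, b)
        res = seed_connectivity_test(
            net, {f"g{i}" for i in range(5)}, n_perm=99, rng_seed=0
        )
        assert res.observed_edges == 10
        assert res.empirical_p == pytest.approx(1 / 100)

    def test_all_nodes_seeds_p_one(self):
        net = nx.gnp_random_graph(10, 0.4, seed=1)
        res = seed_connectivity_test(net, set(net.nodes), n_perm=50, rng_seed=0)
        assert res.empirical_p == pytest.approx(1.0)

    def test_sampled_p_matches_exhaustive_enumeration(self):
        net = nx.gnp_random_graph(8, 0.4, seed=9)
        net = nx.relabel_nodes(net, {i: f"g{i}" for i in net.nodes})
        seeds = {"g0", "g1", "g2"}
        exact = seed_connectivity_test(net, seeds, exhaustive=True)
        assert exact.n_permutations == comb(8, 3)
        sampled = seed_connectivity_test(net, seeds, n_perm=20000, rng_seed=3)
        assert sampled.empirical_p == pytest.approx(exact.empirical_p, abs=0.02)

    def test_missing_seeds_dropped_then_error(self):
        net = nx.Graph([("a", "b")])
        with pytest.raises(InputError, match="fewer than 2"):
            seed_connectivity_test(net, {"a", "zz", "qq"}, n_perm=10)
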