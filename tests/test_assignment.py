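import numpy as np
import pandas as pd
import pytest

from pathextend import (
    InputError,
    SeedSet,
    euclidean_distance,
    gen_stage_profiles,
    hierarchical_cluster,
    knn_assign,
    zscore_profiles,
)

TWO_LABELS = ("fatty_acid_synthesis", "triacylglycerol_biosynthesis")


def profiles(rows: dict) -> pd.DataFrame:
    n = len(next(iter(rows.values())))
    return pd.DataFrame(rows, index=[f"stage{i}" for i in range(n)]).T


class TestEuclideanDistance:
    def test_identity(self):
        assert euclidean_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_three_four_five(self):
        assert euclidean_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)

    def test_hand_sum_of_squares(self):
        assert euclidean_distance([1, 2, 3], [2, 4, 6]) == pytest.approx(
            np.sqrt(14.0)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            euclidean_distance([1.0], [1.0, 2.0])


class TestZscoreProfiles:
    def test_hand_computed_population_sd(self):
        out = zscore_profiles(profiles({"g": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(
            out.loc["g"], [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_constant_profile_flagged_zero(self, caplog):
        with caplog.at_level("WARNING", logger="pathextend"):
            out = zscore_profiles(profiles({"g": [5.0, 5.0, 5.0]}))
        assert (out.loc["g"] == 0.0).all()
        assert "constant" in caplog.text

    def test_output_standardized(self):
        rng = np.random.default_rng(2)
        prof = profiles({f"g{i}": rng.gamma(2, 1, 7) for i in range(5)})
        out = zscore_profiles(prof)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.to_numpy().std(axis=1), 1.0, atol=1e-12)


class TestKnnAssign:
    def _seeds(self, mapping):
        return SeedSet(subpathway=mapping, labels=TWO_LABELS)

    def test_unanimous_vote(self):
        seed_prof = profiles({
            "s1": [1, 0, 0], "s2": [0.9, 0.1, 0], "s3": [1.1, 0, 0.1],
            "s4": [1, 0.05, 0], "s5": [0.95, 0, 0],
            "t1": [0, 0, 5], "t2": [0, 0.1, 5],
        })
        seeds = self._seeds({
            "s1": TWO_LABELS[0], "s2": TWO_LABELS[0], "s3": TWO_LABELS[0],
            "s4": TWO_LABELS[0], "s5": TWO_LABELS[0],
            "t1": TWO_LABELS[1], "t2": TWO_LABELS[1],
        })
        cand = profiles({"c": [1, 0, 0]})
        (a,) = knn_assign(cand, seed_prof, seeds, k=5)
        assert a.label == TWO_LABELS[0]
        assert a.votes == {TWO_LABELS[0]: 5}

    def test_tie_broken_by_summed_distance(self):
        seed_prof = profiles({
            "a1": [0.0, 0.0], "a2": [0.1, 0.0],
            "b1": [1.0, 1.0], "b2": [1.1, 1.0],
        })
        seeds = self._seeds({
            "a1": TWO_LABELS[0], "a2": TWO_LABELS[0],
            "b1": TWO_LABELS[1], "b2": TWO_LABELS[1],
        })
        cand = profiles({"c": [0.4, 0.4]})  # nearer the 'a' pair
        (a,) = knn_assign(cand, seed_prof, seeds, k=4, zscore=False)
        assert sorted(a.votes.values()) == [2, 2]
        assert a.label == TWO_LABELS[0]

    def test_neighbors_match_brute_force_sort(self):
        rng = np.random.default_rng(6)
        seed_prof = profiles({f"s{i}": rng.normal(size=4) for i in range(8)})
        labels = {f"s{i}": TWO_LABELS[i % 2] for i in range(8)}
        cand = profiles({"c": rng.normal(size=4)})
        (a,) = knn_assign(cand, seed_prof, self._seeds(labels), k=3,
                          zscore=False)
        dists = {
            g: float(np.sqrt(((seed_prof.loc[g] - cand.loc["c"]) ** 2).sum()))
            for g in seed_prof.index
        }
        expected = sorted(dists, key=lambda g: (dists[g], g))[:3]
        assert a.neighbors == expected

    def test_invariant_under_common_stage_permutation(self):
        rng = np.random.default_rng(9)
        seed_prof = profiles({f"s{i}": rng.normal(size=5) for i in range(6)})
        labels = {f"s{i}": TWO_LABELS[i % 2] for i in range(6)}
        cand = profiles({"c": rng.normal(size=5)})
        perm = [3, 0, 4, 1, 2]
        (a1,) = knn_assign(cand, seed_prof, self._seeds(labels), k=3)
        (a2,) = knn_assign(
            cand.iloc[:, perm], seed_prof.iloc[:, perm], self._seeds(labels), k=3
        )
        assert a1.label == a2.label and a1.neighbors == a2.neighbors

    def test_assigned_label_attains_max_votes(self):
        seed_prof, seeds, cand_prof, _ = gen_stage_profiles(
            n_seeds_per_class=4, n_candidates=20, rng_seed=3
        )
        for a in knn_assign(cand_prof, seed_prof, seeds, k=5):
            assert a.votes[a.label] == max(a.votes.values())

    def test_k_exceeding_seed_count_rejected(self):
        seed_prof = profiles({"s1": [0.0, 1.0]})
        seeds = self._seeds({"s1": TWO_LABELS[0]})
        with pytest.raises(InputError):
            knn_assign(profiles({"c": [0.0, 1.0]}), seed_prof, seeds, k=5)


class TestHierarchicalCluster:
    def test_separable_groups_split(self):
        prof = profiles({
            "a1": [0.0, 0.0, 0.1], "a2": [0.1, 0.0, 0.0], "a3": [0.0, 0.1, 0.0],
            "b1": [9.0, 9.0, 9.1], "b2": [9.1, 9.0, 9.0],
        })
        clusters = hierarchical_cluster(prof, n_clusters=2)
        assert clusters["a1"] == clusters["a2"] == clusters["a3"]
        assert clusters["b1"] == clusters["b2"]
        assert clusters["a1"] != clusters["b1"]

    def test_singleton_cut(self):
        prof = profiles({"a": [0.0, 1.0], "b": [5.0, 2.0], "c": [9.0, 9.0]})
        clusters = hierarchical_cluster(prof, n_clusters=3)
        assert len(set(clusters.values())) == 3

    def test_average_linkage_merge_order(self):
        """Six 1-d profiles whose average-linkage agglomeration is hand-run:
        {0,1} merge first (d=1), then {10,12}, then {30}, giving the 3-cut
        partition {0,1},{10,12},{30,40}? -- no: 30 and 40 are 10 apart,
        {10,12} to 30 averages 19; the 3-cluster cut is {0,1},{10,12},{30,40}."""
        prof = profiles({
            "p": [0.0, 0.0], "q": [1.0, 0.0],
            "r": [10.0, 0.0], "s": [12.0, 0.0],
            "t": [30.0, 0.0], "u": [40.0, 0.0],
        })
        clusters = hierarchical_cluster(prof, n_clusters=3)
        groups = {}
        for g, c in clusters.items():
            groups.setdefault(c, set()).add(g)
        assert {frozenset(v) for v in groups.values()} == {
            frozenset({"p", "q"}), frozenset({"r", "s"}), frozenset({"t", "u"})
        }

    def test_invalid_cluster_count_rejected(self):
        prof = profiles({"a": [0.0, 1.0]})
        with pytest.raises(InputError):
            hierarchical_cluster(prof, n_clusters=0)
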