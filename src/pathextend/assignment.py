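"""Sub-pathway assignment of candidates by KNN voting on developmental
expression profiles, and hierarchical clustering of z-scored profiles.

Stage profiles are rows of a genes x stages DataFrame sharing one ordered
stage axis (e.g. days after pollination). A candidate inherits the
sub-pathway voted for by its k nearest seed genes under Euclidean distance
(k = 5 by default); distances are computed on z-scored profiles unless
``zscore=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .core import InputError, SeedSet, logger


@dataclass
class Assignment:
    gene: str
    label: str
    neighbors: list[str]
    distances: list[float]
    votes: dict[str, int]


def euclidean_distance(x, y) -> float:
    """Euclidean distance between two equally long stage profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"profile length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(((x - y) ** 2).sum()))


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene's profile over stages (population 1/n variance).

    Constant profiles become all-zero vectors (flagged in the log).
    """
    if profiles.shape[1] < 2:
        raise InputError("z-scoring requires at least 2 stages")
    values = profiles.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population (1/n) sd
    constant = sd.ravel() == 0
    if constant.any():
        logger.warning(
            "%d constant profile(s) z-scored to all-zero: %s",
            int(constant.sum()),
            list(profiles.index[constant][:5]),
        )
    out = np.where(sd == 0, 0.0, (values - mean) / np.where(sd == 0, 1.0, sd))
    return pd.DataFrame(out, index=profiles.index, columns=profiles.columns)


def knn_assign(
    candidate_profiles: pd.DataFrame,
    seed_profiles: pd.DataFrame,
    seeds: SeedSet,
    k: int = 5,
    zscore: bool = True,
) -> list[Assignment]:
    """Assign each candidate to the sub-pathway of its k nearest seeds.

    Ties in the plurality vote are broken by the smaller summed neighbor
    distance among tied labels, then lexicographically. Candidates lacking
    a profile are skipped with a warning; every seed must have one.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    seed_genes = sorted(seeds.genes)
    missing = [g for g in seed_genes if g not in seed_profiles.index]
    if missing:
        raise InputError(f"seed gene(s) without a stage profile: {missing[:5]}")
    if k > len(seed_genes):
        raise InputError(f"k ({k}) exceeds number of seeds ({len(seed_genes)})")
    if list(candidate_profiles.columns) != list(seed_profiles.columns):
        raise InputError("candidate and seed profiles must share the stage axis")
    if zscore:
        combined = pd.concat([seed_profiles.loc[seed_genes], candidate_profiles])
        combined = zscore_profiles(combined)
        seed_mat = combined.iloc[: len(seed_genes)].to_numpy()
        cand_frame = combined.iloc[len(seed_genes):]
    else:
        seed_mat = seed_profiles.loc[seed_genes].to_numpy(dtype=float)
        cand_frame = candidate_profiles.astype(float)

    assignments = []
    for gene, row in zip(cand_frame.index, cand_frame.to_numpy()):
        if not np.isfinite(row).all():
            logger.warning("candidate %r has a non-finite profile: skipped", gene)
            continue
        dists = np.sqrt(((seed_mat - row) ** 2).sum(axis=1))
        # stable nearest-k with gene-ID tiebreak on equal distances
        order = sorted(range(len(seed_genes)), key=lambda i: (dists[i], seed_genes[i]))
        nearest = order[:k]
        votes: dict[str, int] = {}
        dist_sum: dict[str, float] = {}
        for i in nearest:
            lbl = seeds.subpathway[seed_genes[i]]
            votes[lbl] = votes.get(lbl, 0) + 1
            dist_sum[lbl] = dist_sum.get(lbl, 0.0) + float(dists[i])
        best = max(votes.values())
        tied = [l for l, v in votes.items() if v == best]
        label = min(tied, key=lambda l: (dist_sum[l], l))
        assignments.append(
            Assignment(
                gene=gene,
                label=label,
                neighbors=[seed_genes[i] for i in nearest],
                distances=[float(dists[i]) for i in nearest],
                votes=votes,
            )
        )
    return assignments


def hierarchical_cluster(
    profiles: pd.DataFrame, n_clusters: int = 5
) -> dict[str, int]:
    """Average-linkage agglomerative clustering on Euclidean distances.

    The dendrogram is cut into ``n_clusters`` flat clusters; cluster IDs are
    1-based and deterministic given the input row order.
    """
    if n_clusters < 1:
        raise InputError("n_clusters must be >= 1")
    if n_clusters > len(profiles):
        raise InputError(
            f"n_clusters ({n_clusters}) exceeds number of genes ({len(profiles)})"
        )
    if len(profiles) == 1:
        return {profiles.index[0]: 1}
    dists = pdist(profiles.to_numpy(dtype=float), metric="euclidean")
    tree = linkage(dists, method="average")
    labels = fcluster(tree, t=n_clusters, criterion="maxclust")
    return {gene: int(lbl) for gene, lbl in zip(profiles.index, labels)}
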