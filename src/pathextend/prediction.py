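"""Candidate-gene prioritization and its leave-one-out evaluation.

Two scorers are provided, matching the two network types they were designed
for:

* :func:`rwr` — random walk with restart on the interaction network. The
  walker iterates ``P[t+1] = (1 - r) W P[t] + r P0`` with restart
  probability ``r`` (0.8 by default), ``W`` the column-normalized adjacency
  matrix and ``P0`` uniform over the seed genes; the stationary probability
  ranks every gene by network proximity to the seeds.
* :func:`score_nbd` — neighbor-overlap tail probability on the
  co-expression network: the probability that a gene of degree ``n`` has
  ``k`` or more seed neighbors when each link hits a seed independently
  with background probability ``p`` = (#seeds in network)/(#genes in
  network), i.e. the binomial upper tail P(X >= k).

:func:`loocv_auc` evaluates either scorer by leave-one-out
cross-validation: each seed in turn is hidden, re-scored as an unknown, and
the ROC is built over hidden-seed scores (positives) versus never-seed
genes (negatives, averaged across folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.metrics import roc_curve

from .core import ConvergenceError, InputError, logger
from .io import CANDIDATE_COLUMNS


@dataclass
class NBDScore:
    gene: str
    n: int
    k: int
    p: float
    tail_p: float


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    fold_ranks: dict[str, float] = field(default_factory=dict)


def rwr(
    net: nx.Graph,
    seeds,
    r: float = 0.8,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Random walk with restart; returns gene -> steady-state probability.

    Converges to the fixed point of ``P = (1-r) W P + r P0`` with W the
    column-normalized adjacency (degree-0 columns redistribute uniformly so
    W stays stochastic) and P0 uniform over the seeds present in the
    network. The result sums to 1.
    """
    if not (0.0 < r < 1.0):
        raise InputError(f"restart probability must lie in (0, 1), got {r}")
    nodes = sorted(net.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    present = sorted(set(seeds) & set(nodes))
    if not present:
        raise InputError("no seed gene present in the network")
    n = len(nodes)
    adj = nx.to_scipy_sparse_array(net, nodelist=nodes, format="csc", dtype=float)
    colsum = np.asarray(adj.sum(axis=0)).ravel()
    dangling = colsum == 0
    inv = np.where(dangling, 1.0, 1.0 / np.where(dangling, 1.0, colsum))
    W = adj @ sparse.diags(inv)
    p0 = np.zeros(n)
    p0[[index[g] for g in present]] = 1.0 / len(present)
    p = p0.copy()
    for _ in range(max_iter):
        spread = W @ p
        if dangling.any():
            spread = spread + p[dangling].sum() / n
        p_next = (1.0 - r) * spread + r * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"RWR did not converge in {max_iter} iterations (residual {delta:.3g})"
        )
    return {g: float(p[index[g]]) for g in nodes}


def nbd_tail(n: int, k: int, p: float, distribution: str = "binomial") -> float:
    """Upper-tail probability of seeing ``k`` or more seed links out of ``n``.

    Default model: X ~ Binomial(n, p), returns P(X >= k) (computed with the
    regularized incomplete beta function, stable for large n). A literal
    negative-binomial reading (X ~ NegBinomial(n, p), the count of failures
    before the n-th success) is available via
    ``distribution='negative_binomial'``.
    """
    if not (0.0 < p < 1.0):
        raise InputError(f"background probability must lie in (0, 1), got {p}")
    if k < 0 or n < 0:
        raise InputError("n and k must be non-negative")
    if distribution == "binomial":
        if k > n:
            raise InputError(f"k ({k}) cannot exceed n ({n})")
        if k == 0:
            return 1.0
        return float(stats.binom.sf(k - 1, n, p))
    if distribution == "negative_binomial":
        if n < 1:
            raise InputError("negative-binomial mode requires n >= 1")
        if k == 0:
            return 1.0
        return float(stats.nbinom.sf(k - 1, n, p))
    raise InputError(f"unknown distribution {distribution!r}")


def score_nbd(
    net: nx.Graph, seeds, distribution: str = "binomial"
) -> list[NBDScore]:
    """Neighbor-overlap tail probability for every non-seed node of degree >= 1.

    The background probability is the seed fraction of the network,
    p = (#seeds in network) / (#genes in network).
    """
    seed_set = set(seeds) & set(net.nodes)
    if not seed_set:
        raise InputError("no seed gene present in the network")
    n_nodes = net.number_of_nodes()
    p = len(seed_set) / n_nodes
    if p >= 1.0:
        raise InputError("all network genes are seeds: nothing to score")
    scores = []
    n_skipped = 0
    for gene in sorted(net.nodes):
        if gene in seed_set:
            continue
        deg = net.degree(gene)
        if deg == 0:
            n_skipped += 1
            continue
        k = sum(1 for nb in net.neighbors(gene) if nb in seed_set)
        scores.append(
            NBDScore(gene=gene, n=deg, k=k, p=p,
                     tail_p=nbd_tail(deg, k, p, distribution=distribution))
        )
    if n_skipped:
        logger.info("skipped %d degree-0 gene(s) in NBD scoring", n_skipped)
    return scores


def select_candidates(
    rwr_scores: dict[str, float] | None,
    nbd_scores: list[NBDScore] | None,
    rwr_threshold: float = 0.001,
    nbd_cutoff: float = 0.01,
    seeds=(),
) -> pd.DataFrame:
    """Union candidate table from the two scorers with threshold decisions.

    RWR rows pass when the steady-state probability exceeds
    ``rwr_threshold``; NBD rows pass when the tail probability falls below
    ``nbd_cutoff``. Seed genes are excluded. A gene may appear once per
    method.
    """
    seed_set = set(seeds)
    rows = []
    if rwr_scores:
        for gene in sorted(rwr_scores):
            if gene in seed_set:
                continue
            s = rwr_scores[gene]
            rows.append((gene, "RWR", float(s), np.nan, np.nan, s > rwr_threshold))
    if nbd_scores:
        for rec in nbd_scores:
            if rec.gene in seed_set:
                continue
            rows.append(
                (rec.gene, "NBD", float(rec.tail_p), rec.n, rec.k,
                 rec.tail_p < nbd_cutoff)
            )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def _fold_scores(net, train_seeds, method, params) -> dict[str, float]:
    """Score every non-train-seed gene; higher = more pathway-like."""
    if method == "RWR":
        probs = rwr(
            net,
            train_seeds,
            r=params.get("r", 0.8),
            tol=params.get("tol", 1e-10),
            max_iter=params.get("max_iter", 10_000),
        )
        return {g: s for g, s in probs.items() if g not in train_seeds}
    if method == "NBD":
        n_nodes = net.number_of_nodes()
        p = len(train_seeds) / n_nodes
        out = {}
        for gene in net.nodes:
            if gene in train_seeds:
                continue
            deg = net.degree(gene)
            if deg == 0:
                out[gene] = -1.0  # tail_p = 1 for isolated genes
                continue
            k = sum(1 for nb in net.neighbors(gene) if nb in train_seeds)
            out[gene] = -nbd_tail(
                deg, k, p, distribution=params.get("distribution", "binomial")
            )
        return out
    raise InputError(f"unknown method {method!r} (expected 'RWR' or 'NBD')")


def loocv_auc(net: nx.Graph, seeds, method: str, **params) -> ROCResult:
    """Leave-one-out ROC/AUC of a scorer's ability to recover hidden seeds.

    Each seed in turn is removed from the seed set and re-scored as an
    unknown; positives are the hidden seeds' fold scores, negatives are the
    never-seed genes with their scores averaged across folds. AUC is the
    trapezoidal area under the ROC; tied scores earn half credit.
    """
    seed_list = sorted(set(seeds) & set(net.nodes))
    if len(seed_list) < 2:
        raise InputError("LOOCV requires at least 2 seeds present in the network")
    negatives = sorted(set(net.nodes) - set(seed_list))
    neg_sums = np.zeros(len(negatives))
    pos_scores = {}
    fold_ranks = {}
    for s in seed_list:
        train = set(seed_list) - {s}
        scores = _fold_scores(net, train, method, params)
        pos = scores[s]
        pos_scores[s] = pos
        neg = np.array([scores[g] for g in negatives])
        neg_sums += neg
        fold_ranks[s] = float(1 + (neg > pos).sum() + 0.5 * (neg == pos).sum())
    neg_avg = neg_sums / len(seed_list)
    y = np.concatenate([np.ones(len(seed_list)), np.zeros(len(negatives))])
    x = np.concatenate([np.array([pos_scores[s] for s in seed_list]), neg_avg])
    fpr, tpr, _ = roc_curve(y, x, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr, fold_ranks=fold_ranks)
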