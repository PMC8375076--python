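"""Expression normalization, variance filtering and the thresholded
Spearman co-expression network.

The network rule follows the published protocol: an edge connects a gene
pair when its Spearman correlation exceeds the SCC cutoff (0.6 by default,
signed) and its Benjamini–Hochberg adjusted p-value falls below the
adjusted-p cutoff (0.01 by default). P-values use the large-sample
t-approximation for Spearman's rho; the adjustment is performed over all
tested pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

import networkx as nx

from .core import InputError, logger, validate_expression

RECORD_COLUMNS = ["geneA", "geneB", "scc", "p", "adj_p"]


def upper_quartile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile normalization of a genes x samples matrix.

    Each sample is divided by the 75th percentile of its nonzero values and
    rescaled by the mean of those percentiles across samples, so the overall
    scale of the matrix is preserved and zeros stay zero.
    """
    expr = validate_expression(expr)
    if expr.shape[1] < 1:
        raise InputError("at least one sample required")
    uq = np.empty(expr.shape[1])
    values = expr.to_numpy()
    for j, sample in enumerate(expr.columns):
        nz = values[:, j][values[:, j] > 0]
        if nz.size == 0:
            raise InputError(f"sample {sample!r} is all-zero")
        uq[j] = np.percentile(nz, 75)
    scaled = values / uq * uq.mean()
    return pd.DataFrame(scaled, index=expr.index, columns=expr.columns)


def variance_filter(expr: pd.DataFrame, keep_fraction: float = 0.75) -> pd.DataFrame:
    """Retain the genes whose expression variance ranks in the top
    ``keep_fraction``; ties at the boundary are all retained."""
    if not (0.0 < keep_fraction <= 1.0):
        raise InputError(f"keep_fraction must lie in (0, 1], got {keep_fraction}")
    if expr.shape[1] < 2:
        raise InputError("variance undefined with fewer than 2 samples")
    variances = expr.var(axis=1, ddof=1)
    n_keep = int(np.ceil(keep_fraction * len(variances)))
    cutoff = np.sort(variances.to_numpy())[::-1][n_keep - 1]
    keep = variances >= cutoff
    logger.info(
        "variance filter kept %d/%d genes (keep_fraction=%.3g)",
        int(keep.sum()), len(variances), keep_fraction,
    )
    return expr.loc[keep]


def spearman_matrix(expr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and two-sided t-approximation p-values.

    Returns (rho, p) square arrays aligned with ``expr.index``; entries
    involving constant genes are NaN.
    """
    n = expr.shape[1]
    if n < 3:
        raise InputError("at least 3 samples required for correlation p-values")
    values = expr.to_numpy()
    ranks = stats.rankdata(values, axis=1)  # midranks for ties
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant gene(s) skipped in correlation", int(constant.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0  # |rho| == 1
    return rho, p


def build_coexpression_network(
    expr: pd.DataFrame,
    scc_cutoff: float = 0.6,
    adj_p_cutoff: float = 0.01,
    absolute: bool = False,
    record_all: bool = False,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Build the thresholded Spearman co-expression network.

    An edge is added for every unordered gene pair with (signed, or absolute
    when ``absolute=True``) Spearman rho above ``scc_cutoff`` and BH-adjusted
    p-value below ``adj_p_cutoff``; the edge weight is the correlation. The
    BH adjustment always spans all tested pairs. The returned record table
    covers pairs exceeding the SCC cutoff, or every tested pair when
    ``record_all=True``.
    """
    if not (0.0 < scc_cutoff <= 1.0):
        raise InputError(f"scc_cutoff must lie in (0, 1], got {scc_cutoff}")
    if not (0.0 < adj_p_cutoff < 1.0):
        raise InputError(f"adj_p_cutoff must lie in (0, 1), got {adj_p_cutoff}")
    rho, p = spearman_matrix(expr)
    genes = np.asarray(expr.index)
    iu, ju = np.triu_indices(len(genes), k=1)
    rho_f = rho[iu, ju]
    p_f = p[iu, ju]
    tested = ~np.isnan(rho_f)
    adj = np.full_like(p_f, np.nan)
    if tested.any():
        adj[tested] = multipletests(p_f[tested], method="fdr_bh")[1]
    strength = np.abs(rho_f) if absolute else rho_f
    with np.errstate(invalid="ignore"):
        is_edge = tested & (strength > scc_cutoff) & (adj < adj_p_cutoff)
    keep = tested if record_all else (tested & (strength > scc_cutoff))
    records = pd.DataFrame(
        {
            "geneA": genes[iu[keep]],
            "geneB": genes[ju[keep]],
            "scc": rho_f[keep],
            "p": p_f[keep],
            "adj_p": adj[keep],
        },
        columns=RECORD_COLUMNS,
    )
    net = nx.Graph()
    for i, j, r in zip(iu[is_edge], ju[is_edge], rho_f[is_edge]):
        net.add_edge(genes[i], genes[j], weight=float(r))
    logger.info(
        "co-expression network: %d nodes, %d edges (scc>%.3g, adj_p<%.3g)",
        net.number_of_nodes(), net.number_of_edges(), scc_cutoff, adj_p_cutoff,
    )
    return net, records
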