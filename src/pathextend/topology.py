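"""Network topology report and scale-free (power-law) degree-distribution fit.

The scale-free fit is an ordinary least-squares regression of log10 P(k) on
log10 k over the observed degrees with nonzero probability — the classic
log-log line fit, not a maximum-likelihood tail fit. Gamma is the negated
slope; R^2 is the coefficient of determination of the regression.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
from scipy import stats

from .core import InputError


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    n_connected_components: int
    giant_component_size: int
    density: float
    mean_degree: float
    degree_centrality: float
    heterogeneity: float
    clustering_coefficient: float
    scale_free_r2: float
    scale_free_gamma: float

    def to_dict(self) -> dict:
        return asdict(self)


def degree_distribution(net: nx.Graph) -> dict[int, float]:
    """Fraction of nodes at each observed degree; values sum to 1."""
    if net.number_of_nodes() == 0:
        raise InputError("empty network")
    degrees = [d for _, d in net.degree()]
    n = len(degrees)
    counts: dict[int, int] = {}
    for d in degrees:
        counts[d] = counts.get(d, 0) + 1
    return {k: counts[k] / n for k in sorted(counts)}


def fit_power_law(
    dist: dict[int, float], log_binning: bool = False
) -> tuple[float, float]:
    """Fit log10 P(k) ~ -gamma * log10 k by OLS; returns (gamma, r2).

    Degree 0 (log undefined) and zero-probability degrees are excluded.
    ``log_binning=True`` first pools degrees into logarithmic bins for
    robustness on heavy-tailed empirical distributions.
    """
    ks = np.array([k for k, p in dist.items() if k > 0 and p > 0], dtype=float)
    ps = np.array([p for k, p in dist.items() if k > 0 and p > 0], dtype=float)
    if log_binning and len(ks) >= 3:
        edges = np.logspace(0, np.log10(ks.max() + 1), num=min(len(ks), 20))
        idx = np.digitize(ks, edges)
        kb, pb = [], []
        for b in np.unique(idx):
            sel = idx == b
            kb.append(np.exp(np.mean(np.log(ks[sel]))))
            pb.append(ps[sel].mean())
        ks, ps = np.array(kb), np.array(pb)
    if len(ks) < 3:
        raise InputError("insufficient degree support (need >= 3 distinct degrees)")
    x = np.log10(ks)
    y = np.log10(ps)
    fit = stats.linregress(x, y)
    return float(-fit.slope), float(fit.rvalue**2)


def _freeman_centralization(net: nx.Graph) -> float:
    """Freeman degree-centralization index in [0, 1]."""
    n = net.number_of_nodes()
    if n < 3:
        return 0.0
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    dmax = degrees.max()
    return float((dmax - degrees).sum() / ((n - 1) * (n - 2)))


def topology_report(net: nx.Graph, log_binning: bool = False) -> TopologyReport:
    """Compute the standard topology summary of an undirected network.

    density = 2E / (N(N-1)); heterogeneity = sd(degree)/mean(degree);
    clustering coefficient = mean local clustering over nodes of degree >= 2;
    degree centrality = Freeman centralization. The scale-free fields are NaN
    when the degree support is too small to fit.
    """
    if net.number_of_nodes() == 0:
        raise InputError("empty network")
    n = net.number_of_nodes()
    e = net.number_of_edges()
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    components = list(nx.connected_components(net))
    mean_deg = float(degrees.mean())
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else float("nan")
    clust = nx.clustering(net)
    eligible = [v for node, v in clust.items() if net.degree(node) >= 2]
    clustering = float(np.mean(eligible)) if eligible else float("nan")
    try:
        gamma, r2 = fit_power_law(degree_distribution(net), log_binning=log_binning)
    except InputError:
        gamma, r2 = float("nan"), float("nan")
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        n_connected_components=len(components),
        giant_component_size=max(len(c) for c in components),
        density=float(2 * e / (n * (n - 1))) if n > 1 else 0.0,
        mean_degree=mean_deg,
        degree_centrality=_freeman_centralization(net),
        heterogeneity=heterogeneity,
        clustering_coefficient=clustering,
        scale_free_r2=r2,
        scale_free_gamma=gamma,
    )
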