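"""Seeded generators for every input the pipeline consumes.

Each generator plants known structure so downstream stages have a ground
truth to be scored against:

* :func:`gen_expression` — log-normal expression with planted co-expressed
  modules. Module genes share a latent per-sample signal with loading
  chosen so the expected pairwise Spearman correlation equals the requested
  rho (via the bivariate-normal identity rho_S = (6/pi) asin(r_P / 2)).
* :func:`gen_network` — preferential-attachment (Barabási–Albert) backbone
  with a planted seed-gene module wired to a given internal edge density.
* :func:`gen_annotations` — one GO term per module, sprinkled on a fraction
  of its genes, plus decoy terms on background genes.
* :func:`gen_ortholog_fixture` — a reference-species network and ortholog
  groups such that migration reproduces the input network when the group
  expansion is 1.
* :func:`gen_stage_profiles` — per-sub-pathway stage-profile archetypes
  plus noisy seed and candidate profiles for the KNN benchmark.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    DEFAULT_SUBPATHWAYS,
    InputError,
    OrthologGroup,
    OrthologGroupMap,
    SeedSet,
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions (demo-scale defaults)."""

    n_genes: int = 2000
    n_samples: int = 60
    module_sizes: tuple[int, ...] = (30, 30, 30, 30, 30)
    module_rho: float = 0.8
    module_amplitude: float = 1.5
    n_decoy_modules: int = 20
    decoy_module_size: int = 15
    ba_m: int = 3
    seed_module_size: int = 40
    seed_module_density: float = 0.3
    annotation_density: float = 0.9
    decoy_fraction: float = 0.3
    n_decoy_terms: int = 25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.module_sizes) + self.n_decoy_modules * self.decoy_module_size
        if total > self.n_genes:
            raise InputError("module sizes (incl. decoy modules) exceed n_genes")
        if not (0.0 < self.module_rho < 1.0):
            raise InputError(
                f"module_rho must lie in (0, 1), got {self.module_rho}"
            )
        if not (0.0 < self.seed_module_density <= 1.0):
            raise InputError("seed_module_density must lie in (0, 1]")
        if not (0.0 < self.annotation_density <= 1.0):
            raise InputError("annotation_density must lie in (0, 1]")
        if self.seed_module_size > self.n_genes:
            raise InputError("seed_module_size exceeds n_genes")
        if self.ba_m < 1:
            raise InputError("ba_m must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        return d

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]


def spearman_loading(rho: float) -> float:
    """Shared-latent loading giving expected pairwise Spearman ``rho``.

    For bivariate normal variables with Pearson correlation r, the Spearman
    correlation is (6/pi) asin(r/2); sharing a latent with loading sqrt(a)
    gives pairwise Pearson a, so a = 2 sin(pi rho / 6).
    """
    a = 2.0 * np.sin(np.pi * rho / 6.0)
    if not (0.0 < a < 1.0):
        raise InputError(f"infeasible module correlation rho={rho}")
    return float(a)


def gen_expression(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Generate a genes x samples matrix with planted co-expressed modules.

    Returns (expression, module map). Module genes occupy consecutive ID
    blocks at the head of the gene list; values are log-normal (the latent
    Gaussian is exponentiated), so they are non-negative with RNA-seq-like
    skewed marginals, and Spearman correlations are unchanged by the
    monotone transform.

    The map holds the pathway modules (``module1`` ...) followed by
    ``n_decoy_modules`` decoy modules (``decoy01`` ...) of the same
    within-module correlation: co-expression programs unrelated to the
    pathway, as a real transcriptome would contain. Module genes are scaled
    by ``module_amplitude``, emulating the high expression dynamics of
    developmentally regulated genes relative to the background (so a
    variance filter retains them).
    """
    rng = np.random.default_rng(spec.rng_seed)
    genes = spec.gene_ids()
    latent = np.sqrt(spearman_loading(spec.module_rho))
    noise = np.sqrt(1.0 - latent**2)
    values = np.empty((spec.n_genes, spec.n_samples))
    modules: dict[str, list[str]] = {}
    offset = 0
    block_plan = [(f"module{i + 1}", size)
                  for i, size in enumerate(spec.module_sizes)]
    block_plan += [(f"decoy{i + 1:02d}", spec.decoy_module_size)
                   for i in range(spec.n_decoy_modules)]
    for name, size in block_plan:
        signal = rng.standard_normal(spec.n_samples)
        block = latent * signal + noise * rng.standard_normal((size, spec.n_samples))
        values[offset: offset + size] = spec.module_amplitude * block
        modules[name] = genes[offset: offset + size]
        offset += size
    values[offset:] = rng.standard_normal((spec.n_genes - offset, spec.n_samples))
    expr = pd.DataFrame(np.exp(values), index=genes, columns=[
        f"s{j + 1:03d}" for j in range(spec.n_samples)
    ])
    return expr, modules


def gen_network(
    spec: SyntheticSpec, seed_genes: list[str] | None = None
) -> tuple[nx.Graph, set[str]]:
    """Generate a scale-free network with a planted dense seed module.

    The backbone is a Barabási–Albert graph (``ba_m`` edges per new node);
    the planted module (``seed_genes`` if given, else a uniform sample of
    ``seed_module_size`` genes) is additionally wired internally so each
    pair is connected with probability ``seed_module_density``. Returns
    (network, planted seed set).
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    genes = spec.gene_ids()
    backbone = nx.barabasi_albert_graph(
        spec.n_genes, spec.ba_m, seed=int(spec.rng_seed % 2**31)
    )
    net = nx.relabel_nodes(backbone, dict(enumerate(genes)))
    if seed_genes is None:
        pick = rng.choice(spec.n_genes, size=spec.seed_module_size, replace=False)
        planted = sorted(genes[i] for i in pick)
    else:
        unknown = set(seed_genes) - set(genes)
        if unknown:
            raise InputError(f"planted genes not in gene universe: {sorted(unknown)[:5]}")
        planted = sorted(seed_genes)
    for i, a in enumerate(planted):
        for b in planted[i + 1:]:
            if spec.seed_module_density >= 1.0 or rng.random() < spec.seed_module_density:
                net.add_edge(a, b)
    return net, set(planted)


def gen_annotations(
    net: nx.Graph,
    modules: dict[str, list[str]],
    density: float,
    rng_seed: int = 0,
    n_decoy_terms: int = 25,
    decoy_fraction: float = 0.3,
) -> dict[str, set[str]]:
    """Annotate each module with its own GO term on a ``density`` fraction
    of its genes; background genes get uniformly random decoy terms."""
    if not (0.0 < density <= 1.0):
        raise InputError(f"annotation density must lie in (0, 1], got {density}")
    rng = np.random.default_rng(rng_seed)
    annot: dict[str, set[str]] = {}
    module_genes: set[str] = set()
    for mi, (name, genes) in enumerate(sorted(modules.items())):
        term = f"GO:{mi + 1:07d}"
        genes = sorted(genes)
        n_annot = len(genes) if density >= 1.0 else max(1, round(density * len(genes)))
        pick = rng.choice(len(genes), size=n_annot, replace=False)
        for i in sorted(pick):
            annot.setdefault(genes[i], set()).add(term)
        module_genes.update(genes)
    decoys = [f"GO:{9000000 + t:07d}" for t in range(n_decoy_terms)]
    for gene in sorted(set(net.nodes) - module_genes):
        if decoys and rng.random() < decoy_fraction:
            annot.setdefault(gene, set()).add(decoys[int(rng.integers(len(decoys)))])
    return annot


def gen_ortholog_fixture(
    net: nx.Graph, expansion: int = 1, rng_seed: int = 0
) -> tuple[nx.Graph, OrthologGroupMap]:
    """Build a reference network and groups whose migration reproduces ``net``.

    Each target gene g gets one reference gene REF_g and one group; with
    ``expansion`` > 1 the group additionally carries expansion-1 cloned
    target genes, so each migrated reference edge yields up to expansion^2
    target edges. With expansion = 1 the migration round-trip is exact.
    """
    if expansion < 1:
        raise InputError("expansion must be >= 1")
    groups = []
    for i, g in enumerate(sorted(net.nodes)):
        targets = {g} | {f"{g}__h{j + 2}" for j in range(expansion - 1)}
        groups.append(
            OrthologGroup(f"OG{i + 1:05d}", frozenset({f"REF_{g}"}), frozenset(targets))
        )
    ref_net = nx.Graph()
    ref_net.add_nodes_from(f"REF_{g}" for g in net.nodes)
    ref_net.add_edges_from((f"REF_{a}", f"REF_{b}") for a, b in net.edges)
    return ref_net, OrthologGroupMap(groups=groups, provenance="synthetic-fixture")


def archetype_profiles(
    n_stages: int = 7, labels: tuple[str, ...] = DEFAULT_SUBPATHWAYS
) -> pd.DataFrame:
    """One smooth stage-profile archetype per sub-pathway.

    Gaussian bumps of unit amplitude whose peaks are spread across the
    stage axis, emulating sub-pathways that fire at different developmental
    windows.
    """
    t = np.arange(n_stages, dtype=float)
    centers = np.linspace(0, n_stages - 1, len(labels))
    rows = [np.exp(-((t - c) ** 2) / (2 * (n_stages / 6) ** 2)) for c in centers]
    return pd.DataFrame(
        rows, index=list(labels), columns=[f"stage{i + 1}" for i in range(n_stages)]
    )


def gen_stage_profiles(
    n_seeds_per_class: int = 8,
    n_candidates: int = 100,
    n_stages: int = 7,
    noise_sd: float = 0.2,
    labels: tuple[str, ...] = DEFAULT_SUBPATHWAYS,
    rng_seed: int = 0,
):
    """Noisy stage profiles for the KNN sub-pathway benchmark.

    Every seed and candidate profile is its class archetype (unit signal
    amplitude) plus independent Gaussian noise of sd ``noise_sd``. Returns
    (seed_profiles, SeedSet, candidate_profiles, candidate -> true label).
    """
    rng = np.random.default_rng(rng_seed)
    arch = archetype_profiles(n_stages=n_stages, labels=labels)
    seed_rows, seed_ids, seed_labels = [], [], {}
    for label in labels:
        base = arch.loc[label].to_numpy()
        for i in range(n_seeds_per_class):
            gid = f"seed_{label}_{i + 1:02d}"
            seed_ids.append(gid)
            seed_labels[gid] = label
            seed_rows.append(base + noise_sd * rng.standard_normal(n_stages))
    cand_rows, cand_ids, truth = [], [], {}
    for i in range(n_candidates):
        label = labels[int(rng.integers(len(labels)))]
        gid = f"cand_{i + 1:03d}"
        cand_ids.append(gid)
        truth[gid] = label
        cand_rows.append(
            arch.loc[label].to_numpy() + noise_sd * rng.standard_normal(n_stages)
        )
    seed_profiles = pd.DataFrame(seed_rows, index=seed_ids, columns=arch.columns)
    cand_profiles = pd.DataFrame(cand_rows, index=cand_ids, columns=arch.columns)
    return seed_profiles, SeedSet(subpathway=seed_labels, labels=labels), \
        cand_profiles, truth
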