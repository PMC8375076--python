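"""End-to-end orchestration: normalize -> networks -> validation ->
prediction -> candidate union -> sub-pathway assignment, with a manifest
that fully determines a rerun.

The demo configuration (:func:`demo_inputs`) wires every synthetic
generator together coherently: the known seeds are drawn from the planted
co-expressed modules (8 per module, labelled by module), the same genes
form the planted dense module of the interaction network, and the ortholog
fixture reproduces that network through migration — so every stage of the
pipeline has a ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .assignment import hierarchical_cluster, knn_assign, zscore_profiles
from .coexpression import (
    build_coexpression_network,
    upper_quartile_normalize,
    variance_filter,
)
from .core import (
    DEFAULT_SUBPATHWAYS,
    InputError,
    OrthologGroupMap,
    PipelineConfig,
    SeedSet,
    format_score,
    logger,
)
from .homology import migrate_network
from .io import (
    write_annotations,
    write_candidates,
    write_edge_list,
    write_expression,
    write_report,
    write_seeds,
)
from .prediction import loocv_auc, rwr, score_nbd, select_candidates
from .synthetic import (
    SyntheticSpec,
    gen_annotations,
    gen_expression,
    gen_network,
    gen_ortholog_fixture,
)
from .topology import topology_report
from .validation import (
    go_consistency,
    go_enrichment,
    random_consistency_baseline,
    seed_connectivity_test,
)


@dataclass
class PipelineInputs:
    expression: pd.DataFrame
    seeds: SeedSet
    annotations: dict
    ref_net: nx.Graph | None = None
    groups: OrthologGroupMap | None = None
    ppi: nx.Graph | None = None
    stage_profiles: pd.DataFrame | None = None


@dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: dict
    outputs: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "input_checksums": self.input_checksums,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _checksums(inputs: PipelineInputs) -> dict:
    sums = {
        "expression": _sha256(inputs.expression.to_csv(sep="\t")),
        "seeds": _sha256(json.dumps(inputs.seeds.subpathway, sort_keys=True)),
        "annotations": _sha256(
            json.dumps({g: sorted(t) for g, t in inputs.annotations.items()},
                       sort_keys=True)
        ),
    }
    for name, net in (("ref_net", inputs.ref_net), ("ppi", inputs.ppi)):
        if net is not None:
            sums[name] = _sha256(
                json.dumps(sorted(tuple(sorted(e)) for e in net.edges))
            )
    if inputs.groups is not None:
        sums["groups"] = _sha256(
            json.dumps(
                [
                    [g.group_id, sorted(g.reference_genes), sorted(g.target_genes)]
                    for g in inputs.groups.groups
                ]
            )
        )
    return sums


def demo_inputs(
    spec: SyntheticSpec | None = None, n_seeds_per_module: int = 8
) -> tuple[PipelineInputs, dict]:
    """Build coherent synthetic inputs for the full pipeline.

    Returns (inputs, ground_truth) where ground_truth records the planted
    expression modules, the seed genes, and each module gene's sub-pathway.
    """
    spec = spec or SyntheticSpec()
    expr, modules = gen_expression(spec)
    module_names = sorted(m for m in modules if m.startswith("module"))
    if len(module_names) > len(DEFAULT_SUBPATHWAYS):
        raise InputError("demo supports at most 5 planted pathway modules")
    seed_map = {}
    gene_subpathway = {}
    for name, label in zip(module_names, DEFAULT_SUBPATHWAYS):
        for g in modules[name]:
            gene_subpathway[g] = label
        for g in modules[name][:n_seeds_per_module]:
            seed_map[g] = label
    seeds = SeedSet(subpathway=seed_map)
    net, planted = gen_network(spec, seed_genes=sorted(seed_map))
    ref_net, groups = gen_ortholog_fixture(net, expansion=1,
                                           rng_seed=spec.rng_seed + 2)
    annot = gen_annotations(
        net,
        modules={**modules, "seed_module": sorted(planted)},
        density=spec.annotation_density,
        rng_seed=spec.rng_seed + 3,
        n_decoy_terms=spec.n_decoy_terms,
        decoy_fraction=spec.decoy_fraction,
    )
    inputs = PipelineInputs(
        expression=expr, seeds=seeds, annotations=annot,
        ref_net=ref_net, groups=groups,
    )
    truth = {
        "modules": modules,
        "planted_seed_module": sorted(planted),
        "gene_subpathway": gene_subpathway,
    }
    return inputs, truth


def _write_scores_tsv(scores: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tscore\n")
        for g in sorted(scores, key=lambda g: (-scores[g], g)):
            fh.write(f"{g}\t{format_score(scores[g])}\n")


def _write_roc_tsv(roc, path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for f, t in zip(roc.fpr, roc.tpr):
            fh.write(f"{format_score(float(f))}\t{format_score(float(t))}\n")


def run_all(
    config: PipelineConfig, inputs: PipelineInputs, outdir
) -> RunManifest:
    """Execute the full extended-mining pipeline and write all outputs.

    Stages: upper-quartile normalization -> variance filter -> co-expression
    network; PPI migration (or a directly supplied PPI network); topology
    and GO-consistency/connectivity validation of both networks; RWR and
    NBD prediction with LOOCV; candidate union; GO enrichment of
    candidates; KNN sub-pathway assignment and hierarchical clustering of
    candidate profiles. Deterministic given the config seed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__, config=config.to_dict(),
        input_checksums=_checksums(inputs),
    )

    def emit(name: str, filename: str):
        manifest.outputs[name] = filename
        return outdir / filename

    # --- expression -> co-expression network
    expr = upper_quartile_normalize(inputs.expression)
    expr = variance_filter(expr, config.variance_keep_fraction)
    coexpr, records = build_coexpression_network(
        expr,
        scc_cutoff=config.scc_cutoff,
        adj_p_cutoff=config.adj_p_cutoff,
        absolute=config.absolute_scc,
    )
    write_expression(expr, emit("normalized_expression", "normalized_expression.tsv"))
    records = records.sort_values(["geneA", "geneB"])
    with open(emit("coexpression_records", "coexpression_records.tsv"), "w") as fh:
        fh.write("geneA\tgeneB\tscc\tp\tadj_p\n")
        for row in records.itertuples(index=False):
            fh.write(
                f"{row.geneA}\t{row.geneB}\t{format_score(row.scc)}"
                f"\t{format_score(row.p)}\t{format_score(row.adj_p)}\n"
            )
    write_edge_list(coexpr, emit("coexpression_edges", "coexpression_edges.tsv"))

    # --- interaction network
    if inputs.ppi is not None:
        ppi = inputs.ppi
    elif inputs.ref_net is not None and inputs.groups is not None:
        ppi = migrate_network(
            inputs.ref_net, inputs.groups,
            self_interaction_expansion=config.self_interaction_expansion,
        )
    else:
        raise InputError(
            "interaction stage requires either a PPI network or a reference "
            "network plus ortholog groups"
        )
    write_edge_list(ppi, emit("ppi_edges", "ppi_edges.tsv"))
    write_seeds(inputs.seeds, emit("seeds", "seeds.tsv"))
    write_annotations(inputs.annotations, emit("annotations", "annotations.tsv"))

    # --- topology and validation
    networks = {"ppi": ppi, "coexpression": coexpr}
    for name, net in networks.items():
        if net.number_of_nodes() == 0:
            logger.warning("%s network empty: validation skipped", name)
            continue
        write_report(
            topology_report(net).to_dict(), emit(f"topology_{name}",
                                                 f"topology_{name}.tsv")
        )
        try:
            cons = go_consistency(net, inputs.annotations,
                                  fdr=config.consistency_fdr)
            baseline = random_consistency_baseline(
                net, inputs.annotations, n_perm=config.n_permutations,
                rng_seed=config.rng_seed + 11, fdr=config.consistency_fdr,
            )
            write_report(
                {
                    "observed_consistency": cons.consistency,
                    "n_matches": cons.n_matches,
                    "n_tested": cons.n_tested,
                    "baseline_mean": float(baseline.mean()),
                    "baseline_sd": float(baseline.std()),
                    "baseline_p95": float(np.quantile(baseline, 0.95)),
                    "n_permutations": len(baseline),
                },
                emit(f"consistency_{name}", f"consistency_{name}.tsv"),
            )
        except InputError as exc:
            logger.warning("consistency on %s skipped: %s", name, exc)
        try:
            conn = seed_connectivity_test(
                net, inputs.seeds, n_perm=config.n_permutations,
                rng_seed=config.rng_seed + 13,
            )
            write_report(
                {
                    "observed_edges": conn.observed_edges,
                    "null_mean": conn.null_mean,
                    "null_sd": conn.null_sd,
                    "empirical_p": conn.empirical_p,
                    "n_permutations": conn.n_permutations,
                },
                emit(f"connectivity_{name}", f"connectivity_{name}.tsv"),
            )
        except InputError as exc:
            logger.warning("connectivity test on %s skipped: %s", name, exc)

    # --- prediction
    seed_genes = inputs.seeds.genes
    rwr_scores = {
        g: s for g, s in rwr(ppi, seed_genes, r=config.rwr_restart).items()
        if g not in seed_genes
    }
    nbd_scores = score_nbd(coexpr, seed_genes)
    _write_scores_tsv(rwr_scores, emit("rwr_scores", "rwr_scores.tsv"))
    with open(emit("nbd_scores", "nbd_scores.tsv"), "w") as fh:
        fh.write("gene\tn\tk\tp\ttail_p\n")
        for rec in sorted(nbd_scores, key=lambda r: (r.tail_p, r.gene)):
            fh.write(
                f"{rec.gene}\t{rec.n}\t{rec.k}\t{format_score(rec.p)}"
                f"\t{format_score(rec.tail_p)}\n"
            )
    evaluation = {}
    roc_rwr = loocv_auc(ppi, seed_genes, "RWR", r=config.rwr_restart)
    evaluation["rwr_loocv_auc"] = roc_rwr.auc
    _write_roc_tsv(roc_rwr, emit("roc_rwr", "roc_rwr.tsv"))
    try:
        roc_nbd = loocv_auc(coexpr, seed_genes, "NBD")
        evaluation["nbd_loocv_auc"] = roc_nbd.auc
        _write_roc_tsv(roc_nbd, emit("roc_nbd", "roc_nbd.tsv"))
    except InputError as exc:
        logger.warning("NBD LOOCV skipped: %s", exc)
    write_report(evaluation, emit("evaluation", "evaluation.tsv"))

    candidates = select_candidates(
        rwr_scores, nbd_scores,
        rwr_threshold=config.rwr_threshold,
        nbd_cutoff=config.nbd_p_cutoff,
        seeds=seed_genes,
    )
    write_candidates(candidates, emit("candidates", "candidates.tsv"))

    # --- GO enrichment of the predicted set
    passing = sorted(set(candidates.loc[candidates["pass"], "gene"]))
    population = set(ppi.nodes) | set(coexpr.nodes)
    study = set(passing) & population
    enrichment = go_enrichment(study, population, inputs.annotations) if study else []
    with open(emit("enrichment", "candidate_enrichment.tsv"), "w") as fh:
        fh.write("term\tstudy_count\tstudy_n\tpop_count\tpop_n\tp\tadj_p\n")
        for r in sorted(enrichment, key=lambda r: (r.p_value, r.term)):
            fh.write(
                f"{r.term}\t{r.study_count}\t{r.study_n}\t{r.pop_count}"
                f"\t{r.pop_n}\t{format_score(r.p_value)}\t{format_score(r.adj_p)}\n"
            )

    # --- sub-pathway assignment + clustering of candidate profiles
    profiles = (
        inputs.stage_profiles if inputs.stage_profiles is not None
        else inputs.expression
    )
    with_profile = [g for g in passing if g in profiles.index]
    skipped = set(passing) - set(with_profile)
    if skipped:
        logger.warning(
            "%d candidate(s) lack stage profiles: %s",
            len(skipped), sorted(skipped)[:5],
        )
    seed_profiles = profiles.loc[[g for g in sorted(seed_genes)
                                  if g in profiles.index]]
    with open(emit("assignments", "assignments.tsv"), "w") as fh:
        fh.write("gene\tlabel\tneighbors\tdistances\tvotes\n")
        if with_profile:
            for a in knn_assign(
                profiles.loc[with_profile], seed_profiles, inputs.seeds,
                k=config.knn_k,
            ):
                votes = ";".join(f"{l}={v}" for l, v in sorted(a.votes.items()))
                fh.write(
                    f"{a.gene}\t{a.label}\t{','.join(a.neighbors)}\t"
                    f"{','.join(format_score(d) for d in a.distances)}\t{votes}\n"
                )
    with open(emit("clusters", "candidate_clusters.tsv"), "w") as fh:
        fh.write("gene\tcluster\n")
        if len(with_profile) >= 5:
            clusters = hierarchical_cluster(
                zscore_profiles(profiles.loc[with_profile]), n_clusters=5
            )
            for g in sorted(clusters):
                fh.write(f"{g}\t{clusters[g]}\n")

    manifest.write(outdir / "manifest.json")
    return manifest
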