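"""Readers and writers for the tabular formats the pipeline consumes.

All formats are plain TSV / whitespace-delimited text:

* expression matrix — first column gene IDs, header row sample IDs;
* edge list — two or three whitespace-separated columns
  (``geneA geneB [weight]``);
* ortholog groups — InParanoid-style table
  (``group_id  species  gene  confidence``);
* GO annotations — two-column TSV (``gene  term``) or a GAF dialect
  (gene in column 2, term in column 5);
* seeds — two-column TSV (``gene  subpathway``);
* candidates — fixed-column TSV written by :func:`write_candidates`.

Readers reject invariant violations instead of repairing them; the one
exception is self-loops in edge lists, which are dropped, counted and
logged.
"""

from __future__ import annotations

import re

import networkx as nx
import pandas as pd

from .core import (
    DEFAULT_SUBPATHWAYS,
    InputError,
    OrthologGroup,
    OrthologGroupMap,
    SeedSet,
    format_score,
    logger,
    validate_expression,
)

GO_TERM_RE = re.compile(r"^GO:\d{7}$")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV into a validated DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric expression value in {path}: {exc}") from exc
    return validate_expression(df)


def write_expression(expr: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(map(str, expr.columns)) + "\n")
        for gene, row in zip(expr.index, expr.to_numpy()):
            fh.write(str(gene) + "\t" + "\t".join(format_score(v) for v in row) + "\n")


def read_edge_list(path) -> nx.Graph:
    """Read a 2-3 column edge list into an undirected, deduplicated graph.

    Self-loops are dropped (counted and logged); reversed duplicates
    collapse onto one undirected edge.
    """
    net = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise InputError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            a, b = parts[0], parts[1]
            if a == b:
                n_loops += 1
                net.add_node(a)
                continue
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise InputError(
                        f"{path}:{lineno}: malformed weight {parts[2]!r}"
                    ) from exc
                net.add_edge(a, b, weight=w)
            else:
                net.add_edge(a, b)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return net


def write_edge_list(net: nx.Graph, path) -> None:
    """Write an edge list with deterministic (sorted) row order."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            data = net.edges[a, b]
            if "weight" in data:
                fh.write(f"{a}\t{b}\t{format_score(data['weight'])}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_inparanoid_groups(
    path,
    ref_species: str | None = None,
    target_species: str | None = None,
    confidence_cutoff: float = 0.05,
) -> OrthologGroupMap:
    """Read an InParanoid-style group table.

    Expected columns: ``group_id  species  gene  confidence``. Entries with
    bootstrap confidence below ``confidence_cutoff`` are excluded. Groups
    left with only one species are dropped with a warning. If the species
    names are not given, the species of the first row is taken as the
    reference and the other as the target.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise InputError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(parts)}"
                )
            gid, species, gene, conf = parts
            try:
                conf_f = float(conf)
            except ValueError as exc:
                raise InputError(
                    f"{path}:{lineno}: malformed confidence {conf!r}"
                ) from exc
            rows.append((gid, species, gene, conf_f))
    if not rows:
        logger.warning("%s: empty ortholog table", path)
        return OrthologGroupMap(groups=[], provenance=str(path))
    species_seen = []
    for _, sp, _, _ in rows:
        if sp not in species_seen:
            species_seen.append(sp)
    if ref_species is None:
        ref_species = species_seen[0]
    if target_species is None:
        others = [s for s in species_seen if s != ref_species]
        target_species = others[0] if others else None
    groups: dict[str, tuple[set, set]] = {}
    for gid, sp, gene, conf in rows:
        if conf < confidence_cutoff:
            logger.info("excluding %r (confidence %.3g < %.3g)", gene, conf,
                        confidence_cutoff)
            continue
        ref, tgt = groups.setdefault(gid, (set(), set()))
        if sp == ref_species:
            ref.add(gene)
        elif sp == target_species:
            tgt.add(gene)
        else:
            raise InputError(
                f"{path}: unexpected species {sp!r} (expected "
                f"{ref_species!r} or {target_species!r})"
            )
    kept = []
    for gid in sorted(groups):
        ref, tgt = groups[gid]
        if not ref or not tgt:
            logger.warning(
                "dropping group %r: only one species represented", gid
            )
            continue
        kept.append(OrthologGroup(gid, frozenset(ref), frozenset(tgt)))
    return OrthologGroupMap(groups=kept, provenance=str(path))


def read_annotations(path, gaf: bool = False) -> dict[str, set[str]]:
    """Read gene -> GO term annotations.

    Default format is a two-column TSV (gene, term). With ``gaf=True`` the
    gene is taken from column 2 and the term from column 5 (GAF dialect);
    comment lines starting with ``!`` are skipped.
    """
    annot: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("!"):
                continue
            parts = line.split("\t")
            if gaf:
                if len(parts) < 5:
                    raise InputError(
                        f"{path}:{lineno}: GAF line has fewer than 5 columns"
                    )
                gene, term = parts[1], parts[4]
            else:
                if len(parts) != 2:
                    raise InputError(
                        f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                    )
                gene, term = parts
            if not GO_TERM_RE.match(term):
                raise InputError(
                    f"{path}:{lineno}: invalid GO term identifier {term!r}"
                )
            annot.setdefault(gene, set()).add(term)
    return annot


def write_annotations(annot: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annot):
            for term in sorted(annot[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_seeds(path, labels: tuple[str, ...] = DEFAULT_SUBPATHWAYS) -> SeedSet:
    """Read a two-column TSV of (gene, sub-pathway label)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            gene, label = parts
            if gene in mapping and mapping[gene] != label:
                raise InputError(
                    f"{path}:{lineno}: gene {gene!r} listed with conflicting "
                    f"labels {mapping[gene]!r} and {label!r}"
                )
            mapping[gene] = label
    if not mapping:
        raise InputError(f"{path}: no seeds")
    return SeedSet(subpathway=mapping, labels=labels)


def write_seeds(seeds: SeedSet, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(seeds.subpathway):
            fh.write(f"{gene}\t{seeds.subpathway[gene]}\n")


CANDIDATE_COLUMNS = ["gene", "method", "score", "n", "k", "pass"]


def sort_candidates(table: pd.DataFrame) -> pd.DataFrame:
    """Deterministic candidate order: NBD p ascending, RWR probability
    descending, method then gene ID as tie-breaks."""
    if table.empty:
        return table.reindex(columns=CANDIDATE_COLUMNS)
    tbl = table.copy()
    # sort key: RWR scores negated so "better first" holds for both methods
    tbl["_key"] = tbl.apply(
        lambda r: r["score"] if r["method"] == "NBD" else -r["score"], axis=1
    )
    tbl = tbl.sort_values(["method", "_key", "gene"]).drop(columns="_key")
    return tbl.reset_index(drop=True).reindex(columns=CANDIDATE_COLUMNS)


def write_candidates(table: pd.DataFrame, path) -> None:
    """Write a candidate table as TSV with fixed column and row order."""
    tbl = sort_candidates(table)
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for _, row in tbl.iterrows():
            n = "" if pd.isna(row["n"]) else str(int(row["n"]))
            k = "" if pd.isna(row["k"]) else str(int(row["k"]))
            fh.write(
                f"{row['gene']}\t{row['method']}\t{format_score(row['score'])}"
                f"\t{n}\t{k}\t{bool(row['pass'])}\n"
            )


def write_report(metrics: dict, path) -> None:
    """Write a flat two-column (metric, value) TSV report."""
    with open(path, "w") as fh:
        for key, value in metrics.items():
            if isinstance(value, float):
                value = format_score(value)
            fh.write(f"{key}\t{value}\n")
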