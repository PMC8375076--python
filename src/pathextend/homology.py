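"""Ortholog groups and interolog-based network migration.

The primary route consumes an InParanoid-style group table
(:func:`pathextend.io.read_inparanoid_groups`). When only raw pairwise
similarities are available, :func:`build_groups_rbh` offers a simplified
group builder: reciprocal best hits (RBH) above a bit-score cutoff seed the
groups, and in-paralogs are attached to a seed pair when their
within-species similarity to the seed ortholog exceeds the seed pair's own
cross-species score.

:func:`migrate_network` implements the homolog-group product rule: if a
reference gene in group A interacts with a reference gene in group B, every
target-species gene of group A is connected to every target-species gene of
group B.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .core import InputError, OrthologGroup, OrthologGroupMap, logger

SIM_COLUMNS = ["query", "subject", "bitscore"]


def read_similarity_table(path, column_indices=(0, 1, 11)) -> pd.DataFrame:
    """Read a BLAST outfmt-6-like TSV into a (query, subject, bitscore) table.

    ``column_indices`` selects the query, subject and bit-score columns
    (defaults match tabular BLAST output). Duplicate (query, subject) pairs
    are reduced to their best (maximum) bit score.
    """
    qi, si, bi = column_indices
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) <= max(qi, si, bi):
                raise InputError(f"{path}:{lineno}: too few columns")
            try:
                score = float(parts[bi])
            except ValueError as exc:
                raise InputError(
                    f"{path}:{lineno}: malformed bit score {parts[bi]!r}"
                ) from exc
            if score < 0:
                raise InputError(f"{path}:{lineno}: negative bit score")
            rows.append((parts[qi], parts[si], score))
    df = pd.DataFrame(rows, columns=SIM_COLUMNS)
    if df.empty:
        return df
    return (
        df.groupby(["query", "subject"], as_index=False)["bitscore"].max()
    )


def _best_hits(sim: pd.DataFrame, queries: set, subjects: set) -> dict:
    """Best cross-species subject per query; ties break on subject ID."""
    best: dict[str, tuple[str, float]] = {}
    for q, s, b in sim.itertuples(index=False):
        if q not in queries or s not in subjects:
            continue
        cur = best.get(q)
        if cur is None or b > cur[1] or (b == cur[1] and s < cur[0]):
            best[q] = (s, b)
    return best


def build_groups_rbh(
    sim_ab: pd.DataFrame,
    sim_ba: pd.DataFrame,
    bit_cutoff: float = 40.0,
) -> OrthologGroupMap:
    """Build two-species ortholog groups from pairwise similarities.

    ``sim_ab`` holds hits queried from the reference species (A),
    ``sim_ba`` hits queried from the target species (B); either table may
    additionally contain within-species rows, which drive in-paralog
    attachment. Seed ortholog pairs are reciprocal best cross-species hits
    with both directional scores >= ``bit_cutoff``; an unassigned gene joins
    a seed pair's group when its within-species score to the seed ortholog
    strictly exceeds the pair's cross-species score (mean of the two
    directions).
    """
    if sim_ab.empty and sim_ba.empty:
        logger.warning("empty similarity tables: no ortholog groups built")
        return OrthologGroupMap(groups=[], provenance="rbh")
    # queries pin the species; subjects seen only as subjects fall to the
    # other species of their table (tables may contain within-species rows)
    species_a = set(sim_ab["query"])
    species_b = set(sim_ba["query"])
    both = species_a & species_b
    if both:
        raise InputError(f"genes queried from both species: {sorted(both)[:5]}")
    species_b |= {s for s in sim_ab["subject"]
                  if s not in species_a and s not in species_b}
    species_a |= {s for s in sim_ba["subject"]
                  if s not in species_a and s not in species_b}
    best_ab = _best_hits(sim_ab, species_a, species_b)
    best_ba = _best_hits(sim_ba, species_b, species_a)

    # within-species similarity, symmetrised to the max over directions
    within: dict[tuple[str, str], float] = {}
    for sim in (sim_ab, sim_ba):
        for q, s, b in sim.itertuples(index=False):
            if q == s:
                continue
            same = (q in species_a and s in species_a) or (
                q in species_b and s in species_b
            )
            if same:
                key = (q, s) if q < s else (s, q)
                within[key] = max(within.get(key, 0.0), b)

    seeds = []  # (ref_gene, tgt_gene, cross_score)
    for a in sorted(best_ab):
        b, s_ab = best_ab[a]
        back = best_ba.get(b)
        if back is None or back[0] != a:
            continue
        s_ba = back[1]
        if s_ab < bit_cutoff or s_ba < bit_cutoff:
            continue
        seeds.append((a, b, (s_ab + s_ba) / 2.0))
    assigned = {g for a, b, _ in seeds for g in (a, b)}

    members: dict[int, tuple[set, set]] = {
        i: ({a}, {b}) for i, (a, b, _) in enumerate(seeds)
    }
    for gene in sorted((species_a | species_b) - assigned):
        is_ref = gene in species_a
        best_group, best_score = None, None
        for i, (a, b, cross) in enumerate(seeds):
            anchor = a if is_ref else b
            key = (gene, anchor) if gene < anchor else (anchor, gene)
            w = within.get(key)
            if w is not None and w > cross:
                if best_score is None or w > best_score:
                    best_group, best_score = i, w
        if best_group is not None:
            members[best_group][0 if is_ref else 1].add(gene)

    groups = [
        OrthologGroup(f"OG{i + 1:04d}", frozenset(ref), frozenset(tgt))
        for i, (ref, tgt) in sorted(members.items())
    ]
    return OrthologGroupMap(groups=groups, provenance="rbh")


def migrate_network(
    ref_net: nx.Graph,
    groups: OrthologGroupMap,
    self_interaction_expansion: bool = True,
) -> nx.Graph:
    """Project a reference-species interaction network onto the target species.

    Every reference edge (a, b) with a in group GA and b in group GB expands
    to all target(GA) x target(GB) pairs; duplicates and self-pairs are
    dropped, and reference genes without a group contribute nothing.
    Reference self-interactions (a, a) expand to all unordered pairs within
    target(GA) when ``self_interaction_expansion`` is on.
    """
    ref2tgt = groups.reference_to_targets()
    out = nx.Graph()
    for node in ref_net.nodes:
        for t in ref2tgt.get(node, ()):  # mapped isolates stay isolated
            out.add_node(t)
    for a, b in ref_net.edges:
        ta = ref2tgt.get(a)
        tb = ref2tgt.get(b)
        if ta is None or tb is None:
            continue
        if a == b and not self_interaction_expansion:
            continue
        for t1 in ta:
            for t2 in tb:
                if t1 != t2:
                    out.add_edge(t1, t2)
    if out.number_of_edges() == 0:
        logger.warning("network migration produced no edges")
    return out
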