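"""Domain types and configuration shared by all pipeline stages.

Conventions used throughout the package:

* An *expression matrix* is a :class:`pandas.DataFrame` with gene IDs as the
  index and sample IDs as the columns; values are non-negative and finite.
  :func:`validate_expression` enforces the invariants.
* A *gene network* is an undirected :class:`networkx.Graph` without
  self-loops; co-expression edges carry a ``weight`` attribute holding the
  Spearman correlation, interaction edges are unweighted.
* Gene identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("pathextend")

#: The five functional categories of the oil-biosynthesis pathway used as
#: default sub-pathway labels for seed genes.
DEFAULT_SUBPATHWAYS = (
    "fatty_acid_synthesis",
    "fa_elongation_desaturation_export",
    "lipid_trafficking",
    "triacylglycerol_biosynthesis",
    "tag_fa_degradation",
)


class PathextendError(Exception):
    """Base class for all package errors."""


class InputError(PathextendError):
    """Invalid or inconsistent input data."""


class ConvergenceError(PathextendError):
    """An iterative solver failed to converge."""


def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an expression matrix (genes x samples).

    Raises :class:`InputError` on duplicate gene/sample IDs, negative or
    non-finite values. Returns the (float64) validated frame.
    """
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise InputError(f"duplicate gene IDs: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise InputError(f"duplicate sample IDs: {dups}")
    values = df.to_numpy(dtype=float, copy=False)
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise InputError(
            f"non-finite expression value at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )
    if (values < 0).any():
        bad = np.argwhere(values < 0)[0]
        raise InputError(
            f"negative expression value at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )
    return df.astype(float)


def validate_network(net: nx.Graph) -> nx.Graph:
    """Drop self-loops (logged) and assert the graph is undirected."""
    if net.is_directed():
        raise InputError("gene networks must be undirected")
    loops = list(nx.selfloop_edges(net))
    if loops:
        net.remove_edges_from(loops)
        logger.warning("dropped %d self-loop(s)", len(loops))
    return net


@dataclass(frozen=True)
class OrthologGroup:
    group_id: str
    reference_genes: frozenset[str]
    target_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.reference_genes or not self.target_genes:
            raise InputError(
                f"ortholog group {self.group_id!r} must contain at least one "
                "gene from each species"
            )


@dataclass
class OrthologGroupMap:
    """Two-species homolog groups (reference species -> target species)."""

    groups: list[OrthologGroup]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen_ref: dict[str, str] = {}
        seen_tgt: dict[str, str] = {}
        for g in self.groups:
            for r in g.reference_genes:
                if r in seen_ref and seen_ref[r] != g.group_id:
                    logger.warning(
                        "reference gene %r appears in groups %r and %r",
                        r, seen_ref[r], g.group_id,
                    )
                seen_ref[r] = g.group_id
            for t in g.target_genes:
                if t in seen_tgt and seen_tgt[t] != g.group_id:
                    logger.warning(
                        "target gene %r appears in groups %r and %r",
                        t, seen_tgt[t], g.group_id,
                    )
                seen_tgt[t] = g.group_id

    def reference_to_targets(self) -> dict[str, frozenset[str]]:
        """Map each reference gene to the target genes of its group."""
        out: dict[str, frozenset[str]] = {}
        for g in self.groups:
            for r in g.reference_genes:
                out[r] = g.target_genes
        return out

    def __len__(self) -> int:
        return len(self.groups)


@dataclass
class SeedSet:
    """Known pathway genes, each carrying one sub-pathway label."""

    subpathway: dict[str, str]
    labels: tuple[str, ...] = DEFAULT_SUBPATHWAYS

    def __post_init__(self) -> None:
        if not self.subpathway:
            raise InputError("no seeds")
        unknown = sorted(set(self.subpathway.values()) - set(self.labels))
        if unknown:
            raise InputError(f"unknown sub-pathway label(s): {unknown}")

    @property
    def genes(self) -> set[str]:
        return set(self.subpathway)

    def __len__(self) -> int:
        return len(self.subpathway)


AnnotationMap = dict  # gene -> set of GO term IDs


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline with the published defaults."""

    scc_cutoff: float = 0.6
    adj_p_cutoff: float = 0.01
    variance_keep_fraction: float = 0.75
    rwr_restart: float = 0.8
    rwr_threshold: float = 0.001
    nbd_p_cutoff: float = 0.01
    knn_k: int = 5
    n_permutations: int = 5000
    rng_seed: int = 0
    consistency_fdr: float = 0.05
    absolute_scc: bool = False
    self_interaction_expansion: bool = True

    def validate(self) -> "PipelineConfig":
        for name in ("adj_p_cutoff", "rwr_restart", "rwr_threshold",
                     "nbd_p_cutoff", "consistency_fdr"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InputError(f"{name} must lie in (0, 1), got {v}")
        if not (0.0 < self.scc_cutoff <= 1.0):
            raise InputError(f"scc_cutoff must lie in (0, 1], got {self.scc_cutoff}")
        if not (0.0 < self.variance_keep_fraction <= 1.0):
            raise InputError(
                f"variance_keep_fraction must lie in (0, 1], got "
                f"{self.variance_keep_fraction}"
            )
        if self.knn_k < 1:
            raise InputError(f"knn_k must be >= 1, got {self.knn_k}")
        if self.n_permutations < 1:
            raise InputError(
                f"n_permutations must be >= 1, got {self.n_permutations}"
            )
        return self

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in fields(cls):
            if f.name in d:
                raw = d[f.name]
                if f.type in ("int", int):
                    raw = int(raw)
                elif f.type in ("float", float):
                    raw = float(raw)
                elif f.type in ("bool", bool) and isinstance(raw, str):
                    raw = raw.strip().lower() in ("1", "true", "yes", "on")
                kwargs[f.name] = raw
        return cls(**kwargs).validate()


def format_score(x: float) -> str:
    """Render a score with 6 significant digits ('.' decimal separator)."""
    return f"{x:.6g}"
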