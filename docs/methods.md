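# Methods

This note documents the models and numerical choices behind `pathextend`,
what the synthetic generators do and do not emulate, and the design
decisions taken where the underlying procedure left them open.

## Co-expression network

Expression is upper-quartile normalized: each sample is divided by the
75th percentile of its *nonzero* values and rescaled by the mean of those
percentiles, so the matrix keeps its overall scale and zeros stay zero.
The variance filter retains the genes whose variance ranks in the top
`variance_keep_fraction` (default 0.75, i.e. the bottom quartile is
discarded); ties at the boundary are all retained, so the filter is a
deterministic function of the variance ranking.

Spearman's rho is computed on midranks (average ranks for ties — required
for RNA-seq zero inflation), with two-sided p-values from the large-sample
t-approximation `t = rho * sqrt((n-2)/(1-rho^2))`. With ~100+ samples the
approximation is standard; no claim of numeric identity with an exact
permutation p is made, and at least 3 samples are required. Constant
genes have undefined rank correlation and are skipped with a log message.
The Benjamini–Hochberg adjustment always spans **all** tested pairs, even
though by default the returned record stream is restricted to pairs above
the SCC cutoff (the full quadratic stream is available via
`record_all=True`). An edge requires signed rho > `scc_cutoff` (0.6) *and*
adjusted p < `adj_p_cutoff` (0.01); an absolute-value mode is available
(`absolute=True`) but negative correlation is excluded by default, reading
"correlation higher than the cutoff" literally. Raising either threshold
can only remove edges, which the tests assert.

## Interaction-network migration

Ortholog groups are consumed from an InParanoid-style table (entries below
bootstrap confidence 0.05 are excluded; groups with one species dropped).
When only raw similarities exist, `build_groups_rbh` is a documented
simplified fallback: reciprocal best cross-species hits above 40 bits seed
the groups and an unassigned gene joins a group when its within-species
score to the seed ortholog strictly exceeds the pair's cross-species score
(mean of the two directions). This is not a re-implementation of the
bootstrap clustering the original tool performs; downstream stages only
need the group structure.

Migration applies the group-product rule. Two deliberate readings:
reference self-interactions expand to all within-group target pairs
(toggleable via `self_interaction_expansion`), and within-group target
pairs are *never* added unless induced by a reference edge. Migrated
isolates are kept as nodes so that identity groups give an exact
round-trip.

## Topology and the scale-free fit

The degree distribution is fit by ordinary least squares on the raw
log-log points (`log10 P(k) ~ -gamma log10 k`), not by maximum-likelihood
tail fitting; logarithmic binning is available behind a flag for
heavy-tailed empirical data. Degree-0 nodes are excluded from the fit
(log undefined) but counted in the report. At least 3 distinct positive
degrees are required. Definitions fixed here because the field uses
several: density = 2E/(N(N-1)); heterogeneity = sd(degree)/mean(degree);
clustering coefficient = mean local clustering over nodes of degree >= 2;
"degree centrality" is reported as the Freeman centralization index in
[0, 1].

## GO consistency and the random baseline

For each gene that is annotated *and* has at least one annotated neighbor,
the gene's full neighbor set is enriched against the population of all
network genes (one-sided hypergeometric per term carried by the
neighborhood, BH across those terms). The gene is a match if any term at
adjusted p < 0.05 intersects its own annotation; consistency = N/M over
the tested genes. Unannotated genes (or genes with no annotated neighbor)
cannot match by construction and are excluded from M — including them
would only rescale the statistic. The enrichment background is the
network, not the genome, because the statistic measures within-network
coherence. GO terms are taken as annotated, with no DAG ancestor
propagation by default.

The random baseline replaces each tested gene's neighborhood with a
uniformly sampled gene set of equal size from the network, excluding the
gene itself (a gene is never its own neighbor), and recomputes the
statistic; a degree-preserving edge-rewiring baseline is available via
`mode="rewire"`. A boundary case worth noting: a term carried by *every*
network gene can never be enriched (its hypergeometric tail is exactly 1),
so on an annotation-saturated network both the observed consistency and
every baseline repetition are 0 and the two coincide.

The seed-connectivity test counts edges with both ends in the seed set
against equal-size uniform node sets, with the +1-corrected empirical
p-value `(1 + #{null >= obs}) / (1 + n_perm)` — never exactly 0 even when
no null draw reaches the observed count. An `exhaustive=True` mode
enumerates all equal-size subsets on tiny graphs and is used as a test
oracle.

## Scorers

**RWR.** `P(t+1) = (1-r) W P(t) + r P0`, W the column-normalized
adjacency; degree-0 columns redistribute uniformly so W stays stochastic
(the standard teleport convention; the source is silent on dangling
nodes). P0 is uniform over the seeds present in the network. Iteration
stops when the L1 change drops below `tol` (1e-10); since the update is a
contraction with factor (1-r), convergence is guaranteed for any r > 0 and
takes ~`log(tol)/log(1-r)` iterations. The iterative fixed point is
checked against the dense solve `r (I - (1-r)W)^{-1} P0` in the tests.

**Neighbor-overlap tail.** The printed form of this score in its source
mixes an integral, a binomial kernel and a 1/i! factor and is not a
probability as written; the implementation follows the verbal definition —
the probability that a gene with degree n has k *or more* seed neighbors
under independent background probability p = (#seeds in network)/(#genes
in network) — i.e. the binomial upper tail, computed through the
regularized incomplete beta function (stable for large n). A literal
negative-binomial variant is available via
`distribution="negative_binomial"` but is not the default. k = 0 gives
tail 1 by construction; degree-0 genes are skipped.

**LOOCV protocol.** Each seed in turn is hidden and re-scored as an
unknown; for the NBD scorer the hidden seed is removed from both the
background numerator and the neighbor counts (no information leak).
Positives are the hidden seeds' fold scores; negatives are the never-seed
genes, scored in every fold and averaged; remaining seeds are excluded
from the ranking. AUC is the trapezoid under the ROC with half credit for
ties, and gene IDs break residual ordering ties deterministically.

## KNN assignment and clustering

Distances are Euclidean on z-scored profiles by default (population 1/n
standard deviation, which makes the worked examples exact; constant
profiles become zero vectors and are flagged); a raw-value mode exists.
Vote ties are broken by the smaller summed neighbor distance among tied
labels, then lexicographically. Hierarchical clustering uses average
linkage on Euclidean distances with a maxclust cut (default 5 clusters);
the linkage choice is a package decision, as is the average-linkage
default — the procedure being reproduced names none.

## Synthetic data

`gen_expression` builds log-normal counts: module genes share a latent
per-sample Gaussian signal with loading `a = 2 sin(pi * rho / 6)`, the
bivariate-normal identity that makes the *Spearman* correlation of two
module genes equal rho; exponentiation gives non-negative, RNA-seq-like
skewed marginals without changing rank correlations. Two features go
beyond the minimal planted-module picture, both chosen on realism grounds:

* **Module amplitude** (default 1.5x): developmentally regulated pathway
  genes are more dynamic than background genes, so module genes get a
  larger latent scale and survive the top-75% variance filter. Without
  it, filtering would remove a random quarter of the module genes.
* **Decoy modules** (default twenty 15-gene modules at the same rho):
  co-expression programs unrelated to the pathway. Without them the
  co-expression network contains nothing but pathway modules, which
  degenerates the connectivity null (every random node set is as
  interconnected as the seeds) and inflates the NBD background
  probability to ~0.27.

`gen_network` overlays a dense planted module (pairwise wiring probability
`seed_module_density`, default 0.3) on a Barabási–Albert backbone (m = 3),
giving the power-law degree distribution of real interactomes.
`gen_annotations` puts one term per module on a `density` fraction of its
genes plus sparse decoy terms on background genes. `gen_ortholog_fixture`
builds one group per gene so migration is an exact round-trip at
expansion 1. All generators are pure functions of (parameters, seed).

The demo conditions (`SyntheticSpec()` defaults: 2000 genes, 60 samples,
five 30-gene pathway modules, a 40-gene seed module of 8 seeds per
module) run the full pipeline in ~20 s on one CPU; the validation-stage
Monte Carlo uses 200 repetitions at demo scale, while the library default
stays at 5000.

What passing on synthetic data does **not** show: real co-expression has
correlated noise, batch structure, and overlapping modules; real
interologs carry systematic false positives/negatives from incomplete
reference interactomes; real GO annotation is hierarchical and biased
toward well-studied genes. The generators plant clean structure to verify
that each algorithm recovers exactly what its model assumes — they are a
correctness harness, not a realism benchmark. One visible consequence:
the co-expression LOOCV AUC (~0.74 on the demo) is capped because the
planted modules contain unlabeled true members that legitimately outrank
held-out seeds.

## Degenerate inputs and determinism

Readers reject invariant violations (duplicate IDs, negative values,
malformed lines with line numbers) rather than repairing them; the single
exception is self-loops in edge lists, which are dropped, counted and
logged. All-zero samples, constant genes/profiles, empty networks, and
seed sets absent from a network produce named errors or logged skips as
documented per function. Every randomized routine takes an explicit seed;
there is no global RNG state. Output TSVs use fixed column orders, sorted
rows, "." decimals and 6 significant digits, so identically seeded reruns
are byte-identical (the run manifest snapshots config and input checksums
to make that checkable).
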