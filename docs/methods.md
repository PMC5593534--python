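# Methods

This note records the model behind each pipeline stage, the conventions and
numerical choices the implementation pins down, what the synthetic
generators do and do not emulate, and the known limitations.

## ADME triage

Each compound carries four predicted pharmacokinetic parameters: oral
bioavailability (OB, percent), drug-likeness (DL, unitless in [0, 1]),
Caco-2 monolayer permeability (a signed transport-rate score) and half-life
(HL, hours). A compound is retained when

    OB ≥ 30  and  DL ≥ 0.18  and  Caco-2 ≥ −0.4  and  HL ≥ 4,

all inequalities inclusive. Compounds named on a rescue list are retained
regardless of the rule — rescue models literature evidence of activity, so
it bypasses all four criteria rather than relaxing individual ones. A
missing or non-finite ADME value is a validation error, never an implicit
fail: silent coercion would corrupt the retained/rejected counts the rest
of the pipeline is built on.

Cross-herb identity is by case-folded compound *name* (ids stay herb-scoped),
because the interesting multiplicity is the same ingredient contributed by
several herbs of one formula. The duplicate count reported is the number of
*extra* occurrences (Σ over duplicated names of multiplicity − 1), so that
`retained = unique names + duplicates`; the unique-name count is reported
alongside so either bookkeeping convention can be read off.

## Differential expression

The expression matrix is declared log2-scale (a `linear` flag log2-transforms
first). Each gene gets a Welch two-sample t-test (unequal variances,
Satterthwaite degrees of freedom) between case and control columns; the
effect size is the difference of group means, i.e. the log2 fold change. A
gene is significant at

    P < 0.01  and  |log2FC| ≥ 1   (linear |FC| ≥ 2, inclusive),

with strictness of the fold-change comparison configurable. The raw-P
cutoff is the stage's contract; a Benjamini–Hochberg column is emitted for
information but never drives the verdict. Genes with zero variance in both
groups make the t-statistic undefined; they are assigned P = 1 when the
group means agree and P = 0 when they differ, which keeps constant genes
out of the DEG list without poisoning the table with NaNs. Groups need at
least two samples each.

A moderated/empirical-Bayes test would share variance information across
genes and behave better at very small n; the plain Welch test was chosen as
a transparent, dependency-light stage whose calibration is directly
checkable (on null data the P < 0.01 rate stays inside binomial bounds of
1%; see the tests). Results on any specific real dataset will therefore
differ in the tail from moderated-t pipelines.

## Networks

All protein nodes live in one upper-cased gene-symbol namespace. The
compound–target network is bipartite and undirected; duplicate links
collapse, links naming unknown compounds are dropped and counted, and
compounds with no surviving link are excluded by default (`keep_isolated`
flips this — whether published node counts include zero-link compounds is
rarely stated, so both readings are available).

The interactome loader drops self-loops (counted) and collapses duplicate
and reversed-duplicate rows. Seed expansion takes the seeds plus their
first neighbors and every interactome edge inside that node set; expansion
depth is configurable, with depth 0 giving the induced subgraph on the
seeds. Seeds absent from the interactome are kept as isolated nodes rather
than silently dropped. The drug-target and disease-target networks merge by
**intersection** (nodes ∩ nodes, edges ∩ edges) into the core PPI: the core
of interactions supported from both sides is necessarily no larger than
either input, which is the behavior a "core" merge should have; union is
available behind a flag.

## Centrality

Six measures, computed from scratch on undirected simple graphs:

- **DC(v)** — incident-edge count.
- **BC(v)** = Σ_{s≠v≠t} σ_st(v)/σ_st over unordered pairs {s, t}, where
  σ_st counts shortest s–t paths. Unnormalized, each pair counted once
  (Brandes accumulation halved); pairs with no path contribute 0.
- **CC(v)** = |R(v)| / Σ_{u∈R(v)} d(v, u) with R(v) the set reachable from
  v. On disconnected graphs this scores nodes within their components
  instead of zeroing whole components; isolated nodes get 0.
- **EC** — entrywise-nonnegative principal eigenvector of the adjacency
  matrix, Euclidean norm 1. Computed by shifted power iteration
  ((A + I)x, renormalize) from the uniform vector; the shift leaves the
  eigenvector unchanged while guaranteeing convergence on bipartite graphs,
  where plain power iteration can oscillate. L2 tolerance 1e-10, max 1000
  iterations, no randomness; non-convergence raises with the residual. A
  graph with no edges has no principal eigenvector: that is an error unless
  the caller opts into an EC = 0 fallback.
- **LAC(v)** — mean degree of v's neighbors inside the subgraph induced by
  N(v); 0 for isolated nodes.
- **NC(v)** = Σ_{u∈N(v)} ECC(v, u) with the edge clustering coefficient
  ECC(v, u) = |N(v) ∩ N(u)| / min(deg v − 1, deg u − 1); a zero or negative
  denominator (a degree-1 endpoint) defines ECC = 0.

The unnormalized-BC and reachable-set-CC conventions are what make
median-threshold screening over these values well defined and reproducible;
published screens built on Cytoscape plugins do not always document their
edge-case handling, so these choices are stated and tested here rather than
assumed. BC, CC, DC, LAC and NC are verified against brute-force oracles
exhaustively on every connected graph with ≤ 7 nodes and on seeded random
graphs up to n = 50; EC is checked against a dense eigendecomposition to
1e-8.

## Two-stage hub screen

Stage 1: hubs are nodes with DC strictly greater than 2 × median(DC) over
the whole network. Stage 2 (default scope) recomputes all six measures on
the subgraph induced by the hubs, takes each measure's median over those
nodes, and keeps the nodes strictly above **all six** medians. Strict ">"
in both stages means a measure that is constant across the screened nodes
passes nobody — vertex-transitive graphs yield empty screens by
construction, which the tests assert.

The median of an even-length sample is the mean of the two middle order
statistics. Whether stage-2 centralities should be recomputed on the hub
subnetwork or sliced from full-network values is genuinely ambiguous in
published screens of this style; recomputation on the extracted hub network
is the default here (the extraction step exists precisely to re-measure
topology in the reduced network), and `scope="full_graph"` implements the
other reading. The pipeline screens the largest connected component of the
core PPI, since intersection merges can leave small satellites whose
centralities are not comparable to the core's.

## Enrichment and term grouping

For a query of n genes in a universe of N, a term with K genes and overlap
x scores the upper-tail hypergeometric probability
p = Σ_{k=x}^{min(K,n)} C(K,k) C(N−K,n−k) / C(N,n), observed overlap
included; x = 0 gives p = 1. The universe defaults to the union of all term
genes (configurable); query genes outside it are dropped with a count.
Significance is raw p < 0.05 with BH reported, matching the stage's
contract of mirroring common over-representation practice. The tail is
evaluated with scipy's hypergeometric survival function and is tested
against exhaustive draw enumeration for N ≤ 12 and a closed-form
full-overlap case to 1e-12.

Significant terms are grouped by Cohen's kappa between term gene
memberships over the universe (2×2 agreement table; κ = (p_o − p_e)/(1 −
p_e); the degenerate p_e = 1 case is defined as κ = 1 for identical sets,
else 0). Terms with κ ≥ 0.4 (a conventional default for this style of
grouping, configurable) are linked, connected components become functional
groups, and each group is labeled by its most significant member term.
Components, not cliques: one strong chain of similarity merges groups, which
matches how grouped enrichment maps are usually drawn.

## Synthetic data

Generators are seeded (`default_rng([seed, stream])` with fixed per-stream
ids, so artifacts are independent of call order) and return ground truth
sufficient to score their downstream stage.

- **Compounds** (default n = 200, 80% passers over a ten-herb vocabulary):
  passers draw each ADME parameter uniformly above its threshold, failers
  fail a random nonempty subset of criteria; truth records pass ids and
  per-failer violated criteria. Real ADME predictions are correlated across
  parameters and clustered by chemistry; this generator is deliberately
  independent per parameter, so passing tests show rule correctness, not
  robustness to realistic parameter correlation.
- **Interactome** (default Barabási–Albert m = 3, n = 500, 10 boosted
  nodes with 60 extra random partners each): scale-free degree structure is
  the one property the hub screen's behavior depends on, and BA provides it;
  Erdős–Rényi is retained for null experiments. A heavy-tailed base graph
  has natural high-degree nodes, so boosting can never make the boosted set
  the *only* nodes above the 2×median cut; truth therefore records both the
  boosted ids and the full constructed hub set (computed from the
  generator's own degree array), and screen-recovery tests assert exact
  equality against the latter with the boosted ids always contained.
- **Expression** (default 2000 genes, 22 case / 26 control, mirroring a
  small case–control cohort; DE fraction 2.5%, |log2FC| = 2, noise sd 0.5):
  i.i.d. Gaussian log2 noise around per-gene baselines, shifts planted in
  cases with alternating sign. No gene–gene correlation, batch structure or
  heteroskedasticity — calibration results transfer to real arrays only to
  the extent those hold there.
- **Gene sets** (universe 500, 50 terms of 10–40 genes, query 30 with 15
  planted into one term): uniform term membership; the planted term's
  overlap is far beyond chance, the rest overlap hypergeometrically.
- **Links**: each compound hits ≥ 1 and ~Poisson(4) targets.

The `write_fixture_set` helper stitches these into one coherent study on a
shared gene namespace (interactome on the first quarter of the expression
gene space, links pointing into the interactome, gene-set universe = the
interactome genes) so the full pipeline runs end to end; `scale` shrinks
all sizes proportionally for fast tests.

## Problem sizes and determinism

The test suite and the acceptance script run the pipeline at the generator
defaults above (500-node interactomes, 2000-gene matrices, 20-replicate
calibration loops, 100-replicate ranking loops), which keeps a complete run
in seconds while leaving every statistical check comfortably powered. All
randomness flows from explicit integer seeds; reports and intermediates are
byte-identical across reruns except for the report's timestamp block, and
all output tables are deterministically sorted.

## Limitations

- Compound→target links are consumed, not predicted; target-prediction
  models, database retrieval and probe-level expression preprocessing are
  upstream of this package.
- The Welch DE stage will not reproduce moderated-t gene lists exactly.
- Enrichment treats terms as flat gene sets: no ontology DAG traversal,
  term ancestry or redundancy reduction beyond kappa grouping.
- Centrality implementations are exact and single-threaded; they are meant
  for networks of up to a few thousand nodes, not interactome-scale
  all-pairs computation under time pressure.
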