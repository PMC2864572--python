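# Methods

## Model

The data are (i) an integrated physical network of named layers, each
directed (transcriptional regulation `TRI`, phosphorylation `PhI`) or
undirected (protein binding `PPI`), over a shared space of opaque,
case-sensitive gene identifiers, and (ii) a cause–effect network mapping
each perturbed gene to the set of genes differentially expressed under its
perturbation. A *path type* is an ordered sequence of 1–3 layer labels; a
*path instance* of a type is a **simple** path (all nodes distinct) whose
i-th edge belongs to the i-th layer, traversed in stored orientation for
directed layers and in either orientation for undirected ones.

Simplicity is the central counting convention. It excludes degenerate
undirected back-tracking walks (cause–partner–cause–…), and implies the
cause never reappears downstream and the effect is never an intermediate.
Counting non-simple walks instead would inflate every type containing an
undirected layer; this choice is the most likely source of numerical
divergence from other implementations of the same idea. Intermediate nodes
are otherwise unconstrained — deliberately, since the method's purpose is to
explain effect genes that are *not* reachable in one step, without requiring
intermediates to be differentially expressed.

The enrichment statistic for the primary null model is the **instance
count** summed over cause–effect pairs (not the pair count): multiple
routes between the same pair are evidence. The network null operates on the
pair-collapsed projection (below), where multiplicity is already collapsed,
so its statistic is necessarily a pair count.

## Null models and p-value rules

**Perturbation randomization.** Each cause's effect set is replaced by a
uniform sample without replacement, of the same size, from the universe
minus the cause; the layers are untouched. The default universe is the
union of network nodes and all observed effect genes, so genes that were
measured but fall outside every layer remain eligible (configurable:
`network_nodes`, `effect_genes`, `union`). Because the per-terminal path
tally from a cause does not depend on which genes are labelled "effect",
each randomization reduces to re-sampling which terminals count; the
implementation exploits this to score 10⁴ randomizations in milliseconds,
and several path types are scored against one shared ensemble, as one
randomized data set would be scored for each path in turn.

**Network randomization.** For a given type, the *projection* is the
directed network with an edge cause → g wherever at least one instance
links them. It is rewired by repeated double-edge swaps
(a→b, c→d ⇒ a→d, c→b), rejecting swaps that would create self-loops or
duplicate edges, until 10×|edges| swaps succeed — this preserves every
node's in- and out-degree exactly, i.e. the number of outgoing/incoming
paths per cause/target for that type. A proposal cap (200 × the requested
swaps) guarantees termination on frozen configurations (e.g. a complete
bipartite projection admits no valid swap and is returned unchanged).
The observed statistic is |projection edges ∩ real cause–effect pairs|,
recomputed after each rewiring to form the null.

**P-value rules** (shared by both models, one-sided, enrichment only):
with observed count ≥ 5 and positive null standard deviation,
p = Φ̄((obs − μ)/σ) from the null ensemble's moments (σ with ddof = 1);
otherwise the empirical fraction of randomizations with a count ≥ observed.
An empirical fraction of zero is reported as 1/n_random — the resolution
limit of the ensemble — rather than 0; the raw tie count is kept on the
result (`n_null_ge_observed`). A degenerate null (σ = 0) with large
observed also falls back to the empirical rule, annotated via the result's
`rule` field. Raw p-values are reported; Bonferroni over the tested types
is available but off by default. Depletion is not tested.

**Seeding.** One root seed drives everything through spawned
`numpy.random.SeedSequence` child streams (per cause for the perturbation
null, per type for the network null), so results are bit-for-bit
reproducible and replicates are independent.

## Hypergeometric tests

Per-cause specificity: for cause c and type t, the upper-tail
hypergeometric probability of the observed overlap between reach(c, t) and
c's effect set, drawn from the universe minus c. Module enrichment uses the
same tail against each gene set, with the annotation universe as
background; module members outside the universe are dropped with a warning.
Modules with fewer than 3 members are listed but not tested by default —
a hypergeometric test on 1–2 genes is uninformative.

## Modules and summaries

Instances group by (cause, type, ordered intermediates); members differ
only in the terminal node, so e.g. a `PPI-TRI-TRI` module shares both
intermediates. `fraction_explained` counts cause–effect **pairs** (a gene
perturbed under two causes is two perturbation events), and
`motif_abundance` normalizes over (pair, type) assignments — a pair
explained by k types contributes to all k; the raw tally is exposed for
alternative normalizations.

## Synthetic data

The generator draws each layer as an independent Erdős–Rényi graph
(directed or undirected as declared) and plants ground-truth structure:
for each cause, a reserved intermediate chain shared by all of that
cause's planted instances (so module extraction has real structure to
recover) plus fresh terminal genes wired as effects, with further noise
effects drawn uniformly. Planted intermediates never double as noise
targets, avoiding accidental shortcuts; all other genes — including other
causes' planted targets — stay eligible, so the noise marginal matches the
perturbation null's uniform draw. A variant flag adds direct `TRI`
cause→target edges to exercise the direct-path control
(`filter_without_direct`).

Default conditions (300 genes, 10 causes, density 0.01 per layer,
`PPI-TRI` ×8 per cause, 20 noise targets per cause) give a planted type
with ~90 observed instances against a null mean of ~17, and leave sibling
types at chance level. The generator makes no attempt to mimic real degree
distributions (no hubs beyond binomial fluctuation, no scale-free tails),
so passing recovery tests demonstrates correctness of the statistics, not
robustness to interactome topology.

**Calibration conditions.** P-value uniformity under the null is checked in
the regime where the z rule applies, using a denser null configuration
(150 genes, density 0.05, 30 noise targets per cause): expected observed
counts ≈ 11 put essentially all replicates above the z threshold. Below
five observed paths the empirical fraction rule is discrete with an atom at
1, so distributional uniformity is not the target behaviour there — only
conservativeness, which the ≥-tie-counting rule provides.

A small frozen 20-node fixture (five TF nodes, one PPI hub, one cause with
five effects) ships as packaged TSV data for regression tests; its edge
list is this package's own construction, and its `TRI-TRI` count (2) was
computed with the brute-force tuple oracle when the fixture was frozen.

## Problem sizes

The test suite and `scripts/acceptance.py` run the planted analysis at the
default conditions with 999 randomizations per null model, calibration
over 200 null data sets (999 randomizations each), and oracle comparisons
over 100 random ≤ 12-node networks for all 39 types; the full suite
completes in well under a minute on one core. Larger ensembles (the
10,000-randomization default) change only the resolution of empirical
p-values.

## Known limitations

* Exhaustive simple-path enumeration is exponential in path length; fine
  for length ≤ 3 on sparse interactomes, not intended for longer paths.
* The network null rewires the projection, not the underlying layers;
  types whose projections are tiny (< 2 edges) get a degenerate null and
  an empirical p of 1.
* Per-cause specificity uses a reach/effect overlap test, which ignores
  instance multiplicity per pair.
* Undirected layers assume symmetric traversal cost; no edge weights or
  confidences are modelled anywhere (thresholding is the user's job).
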