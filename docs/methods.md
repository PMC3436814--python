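# Methods

`tissuenet` analyzes the architecture of tissue gene regulatory networks
(TRNs): directed graphs over transcription factors (TFs), microRNAs
(miRNAs) and non-TF target genes, in which only TFs and miRNAs may be arc
sources.  A TRN is the subgraph of a genome-wide reference network induced
by the genes expressed in one tissue.  The pipeline runs four analyses over
a set of TRNs — hub statistics, colored three-vertex motif significance,
common/tissue-specific motif classification, and bow-tie decomposition of
motif instances — and ships a synthetic generator that emulates the
statistical structure of predicted regulatory maps so the whole chain is
testable without any external data.

## Synthetic data

`generate_reference` samples, for every TF and miRNA, an out-degree from a
discretized Pareto-I distribution with shape `degree_tail_exponent` (default
2.0) rescaled so its mean equals the configured mean out-degree (default 5),
then picks that many distinct targets uniformly among all other genes.  This
gives the "few highly connected regulators, many weakly connected ones"
profile characteristic of broad-scale regulatory maps while remaining a
two-parameter model.  Self-loops (autoregulation) are never generated:
the random-network nulls place arcs among distinct vertex pairs, and
excluding self-loops everywhere keeps real and null networks comparable.
Non-TF genes never gain outgoing arcs — this role constraint is enforced by
the network container itself, so it holds for every seed and parameter set.

`generate_expression` is binary (a gene is expressed in a tissue or not),
because expression acts purely as a membership filter for the induced
subgraph.  A housekeeping fraction (default 0.5) of genes is shared by all
tissues; each tissue adds its own tissue-specific fraction (default 0.2)
drawn from the remaining genes; any gene still unexpressed is assigned to
one random tissue so every reference gene appears in at least one TRN.
With these defaults the mean pairwise Jaccard similarity between tissue
gene sets is ~0.7, i.e. tissues overlap substantially but not completely.

Planted structures (hubs with a target degree, extra instances of a chosen
colored triad, bow-tie layers with fixed sizes) are inserted after
background sampling and recorded on the generated network, and the
expression generator forces the genes of a planted structure on in the
tissues it was planted in (and, for planted motifs, off elsewhere).  A
planted motif instance is only placed on a gene triple with no pre-existing
arcs, so the planted count is exact.  The planted bow-tie cycles core-TF
pairs through at least `n_core` instances on each side so that every core
gene participates in both a common-motif and a tissue-specific-motif
instance — the defining property of core genes.

What the generator does *not* emulate: sequence-level binding sites,
conservation filtering, continuous expression levels, correlated tissue
similarity structure, or the empirical degree correlations of real
predicted networks.  Passing tests therefore demonstrate that the
*analysis machinery* is correct and calibrated on networks with the right
coarse statistics, not that any biological conclusion transfers to a
particular real dataset.  Defaults (100 TF / 50 miRNA / 350 non-TF genes,
8 tissues) are chosen as the package's standard study conditions: large
enough for heavy tails and motif counts to be meaningful, small enough that
full ensemble analyses run in minutes on one core.

## Hubs, specificity index, sigma_RF

A vertex is an in-hub (out-hub) of a TRN when its in-degree (out-degree) is
significantly higher than that of the same vertex in an ensemble of 2000
equivalent random networks with the same number of vertices and arcs, the
arcs redistributed uniformly over distinct ordered vertex pairs.  The
empirical p-value uses a pseudocount, p = (1 + #{null degree >= observed})
/ (1 + n_random), so p is never 0 and a degree-0 vertex always has p = 1;
the hub criterion is p < 0.01.  The null deliberately ignores vertex roles
(the arcs may start anywhere); a role-preserving variant restricting
sources to TF/miRNA vertices is available behind `role_preserving_null`
for sensitivity analysis.  Since non-TF genes have out-degree 0, no non-TF
gene can ever be an out-hub — a structurally forced result the acceptance
checks exploit.

The specificity index of a hub over N tissues, n of which call it a hub, is
SI = (N − n)/(N − 1): the unique affine function of n that is 1 when the
gene is a hub in exactly one TRN and 0 when it is a hub in all of them.  SI
takes exactly N discrete values; no binning is applied.  An alternative
functional form can be passed as `si_func` to `build_hub_profiles`.

A hub's *active ratio* in a tissue is its TRN degree divided by its
reference degree in the same direction.  Strong hubs are hubs in every
tissue where they are expressed; weak hubs in a strict, non-empty subset.

sigma_RF measures whether hub status is more (or less) shared across
tissues than degrees alone explain.  RF_real(s) is the fraction of real
hubs of a given role and direction with SI = s.  Each of 2000 random
replicates permutes, within every tissue, the observed degree values among
the expressed genes of that role, re-identifies hubs, and recomputes the
SI spectrum.  Because the empirical hub p-value is a monotone function of
degree and permutation leaves each tissue's degree multiset unchanged,
re-identification reduces to re-applying the tissue's real hub degree
threshold — the full ER re-test would give identical hub sets.  The curve
reports the per-SI z-score (RF_real − mean_rand)/sd_rand (sample sd,
ddof=1); a raw-difference mode is selectable.  Bins with zero ensemble
variance are reported as sigma 0 with an `sd_zero` flag rather than an
infinite score — in strongly planted scenarios the null may simply never
produce fully shared hubs.

## Colored triad motifs

Triads are connected three-vertex induced subgraphs classified up to
isomorphism of the vertex-colored digraph: a signature is the lexicographic
minimum over the six vertex orderings of (role triple, 6-bit adjacency
pattern).  Ignoring colors there are exactly 13 connected directed triad
classes, which the tests verify by exhaustive enumeration of all 64
adjacency patterns.  Enumeration uses the ESU scheme (each connected triple
visited exactly once from its minimum vertex); an exhaustive
all-triples scan is retained as an independent oracle for small networks.

Structural classes: FFL (acyclic two-step path plus shortcut), FBL (the
pure directed 3-cycle; any additional arc on a 3-cycle creates a
bidirectional pair), CMPLX (contains a bidirectional TF–miRNA-style dyad
together with both a feed-forward and a feedback pattern), non-loop
otherwise.

Significance is assessed against 1000 degree-preserving randomizations:
repeated double-arc switches (a→b, c→d ⇒ a→d, c→b), rejecting proposals
that create self-loops or duplicates, with 10·|E| attempted switches per
replicate (a standard mixing heuristic, configurable; the mixing tests
check that far fewer than half of the arcs stay in place).  Bidirectional
pairs are treated as two independent arcs during switching; a
dyad-preserving mode is deliberately out of scope, and CMPLX counts could
shift under that alternative.  A motif is significant when occurrence ≥ 6
(strictly more than 5), one-sided empirical p < 0.05 (pseudocount, testing
over-representation only) and z > 2.2 with z = (occ − mean)/sd over the
ensemble.  Zero ensemble variance flags z undefined and the motif
non-significant.  A signature significant in every analyzed tissue is a
common (CM) motif; significant in at least one but not all, tissue-specific
(TS); otherwise unlabeled.

## Bow-tie decomposition

Within one tissue, the genes of CM motif instances and TS motif instances
are partitioned into core (in both), output layer (CM only) and input
layer (TS only).  TS instances are collected only in tissues where the TS
signature is itself significant, so a tissue with no significant TS motif
(the degenerate, liver-like case) has an empty input layer and core.

Composition is the TF/miRNA/non-TF fraction per layer.  Average degrees
count TRN arcs between motif-instance genes whether or not the arc lies
inside an instance (the statistic is defined from the adjacency matrix):
within-set, arcs with both endpoints in the set divided by the set size;
between sets, arcs from i to j divided by the source-set size N_i (mean
per-source-gene degree into j).  Both normalizations are switchable
(`pair` = N_i·N_j giving a density, `mean` = (N_i+N_j)/2).  Note the
per-source form is asymmetric under very unequal layer sizes — backward
flow out of a small core into a large input layer is inflated per gene —
so flow-direction comparisons are best made on the `pair` densities.

Each statistic is tested against 5000 permutations that reshuffle the
layer labels over the motif-instance genes, keeping layer sizes and the
arc set fixed; one-sided enrichment and depletion p-values are reported
with the same pseudocount estimator, NaN where a layer is empty.

Size ratios SR = layer size / union size (summing to 1) classify the
pattern.  The verbal pattern definitions (input ≫ core > output, etc.)
have no canonical numeric thresholds; the package uses a dominance factor
kappa = 2.0 ("much larger" = at least twice) and a symmetry tolerance
tau_sym = 0.1, both configurable, and returns "unclassified" rather than
forcing a label.  Checked in order: degenerate handling when a layer is
empty (the label then follows the dominant layer, e.g. (0, 0, 1) is a
degenerate output-dominated bow-tie); symmetric when |SR_in − SR_out| ≤
tau_sym and both exceed SR_core; input-dominated when SR_in ≥ kappa·SR_core
and SR_core > SR_out; output-dominated when SR_out ≥ kappa·SR_core and
SR_in < SR_core.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng`; pipeline stages
  derive their seeds as blake2s(global seed, stage name) mod 2^31, so any
  stage is reproducible standalone and a rerun is byte-identical.
  Ensemble-consuming code iterates arcs in sorted order so results do not
  depend on Python's per-process hash seed.
- ER null sampling encodes ordered distinct pairs as integers in
  [0, n(n−1)) and draws without replacement, so |E| is exact and the null
  is uniform; per-replicate degree vectors come from `bincount`.
- Empirical p-values everywhere use the add-one estimator; with ensembles
  of 2000/1000/5000 the granularity is well below every decision threshold.
- Ensemble standard deviations use ddof=1; with ≥ 1000 replicates the
  difference from the population form is negligible.
- Degenerate inputs: a TRN with zero arcs yields all hub p-values 1;
  switch randomization requires ≥ 2 arcs; the permutation test requires
  ≥ 3 motif-instance genes; empty layers are flagged rather than divided by.

## Problem sizes used in tests and analysis scripts

The default study conditions are a 500-gene reference over 8 tissues.  Hub
tests use the full 2000-network ensembles (they are cheap); motif ensembles
in tests use 100–150 switch randomizations and the analysis scripts 300,
scaled down from the 1000-replicate default as the package's standard
desk-scale configuration; calibration tests use 200-replicate ensembles,
whose p-value granularity (1/201) still resolves the 0.05 thresholds being
checked.  Planted-structure recovery is assessed over 20 generator seeds.

## Known limitations

- The synthetic tissues are exchangeable apart from planted structure; real
  tissues have correlated expression and shared lineage.
- Motif analysis is limited to three-vertex subgraphs.
- The σ_RF z-score is undefined (flagged) at SI values the null never
  reaches; interpret those bins via RF_real and the raw difference mode.
- In a full pipeline run on dense synthetic data, background-significant
  motifs contribute instances alongside planted ones, so planted bow-tie
  layer sizes are recovered exactly only when the decomposition is applied
  to the planted instance lists; the end-to-end path reports the layers of
  everything significant, as it should.
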