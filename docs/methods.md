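# Methods

This note records the models and procedures `exprmap` implements, the
choices made where the design was genuinely open, and what the synthetic
data does and does not demonstrate.

## Data model

The central object is a gene × condition matrix of real-valued, log-ratio-like
expression values with missing entries allowed, where every condition
(a tissue, time point, or strain contrast) belongs to exactly one experiment.
Invariants enforced on construction: unique gene and condition ids, at least
one gene and two conditions, every condition assigned to an experiment, and
no gene missing in *all* conditions. Grid coordinates throughout are 0-based
and x-first: x is the column (0..width−1), y the row (0..height−1).

## Median-shift normalization

For each gene and each experiment block in the plan, the median of the
gene's observed values over that block's conditions is subtracted from those
values. Conventions:

* median of an even count = midpoint of the two central order statistics
  (the standard convention; a worked odd-length example does not
  disambiguate it);
* the median is taken over observed values only, so a single observed value
  normalizes to 0 and missing entries stay missing;
* a gene with no observed value in a block is left untouched there.

The default plan shifts **all** experiments. In a real compendium only
"reference-less" experiments need the shift, but which blocks those are is a
property of the source data that the caller must state; silently guessing by
technology would be worse than an explicit configuration. The operation is
idempotent and invariant to per-(gene, block) constant offsets, and after it
the observed within-block median is 0 exactly for odd counts and to 1e-12
for even counts — these are tested properties, not aspirations.

Range normalization is deliberately not offered: rescaling every experiment
to a common dynamic range would equate biologically large and small
responses.

## Self-organizing map

**Similarity.** Profiles are compared to node vectors by Pearson correlation
over jointly observed components; missing components are simply excluded.
Euclidean distance (negated, divided by √overlap so profiles with different
missingness are comparable) is available as an alternative. A comparison
with overlap < `min_overlap` (default 3) or zero variance over the overlap
in either vector is *incomparable* and is given a −inf sentinel score, so it
can never win a BMU contest without polluting arithmetic. The zero-variance
rule is applied under both metrics for consistency, even though a Euclidean
distance to a constant vector would be numerically defined. A gene
incomparable to every node is a hard error naming the gene.

**Training.** T = `presentations_per_gene` × n_genes presentations; at
presentation t the learning rate and radius are α(t) = lr0·(1 − t/T) and
r(t) = radius0·(1 − t/T), evaluated before the update — t counts
presentations, not epochs, which is the simplest reading of a linear decay
to zero. A gene is drawn uniformly with replacement, its BMU found, and
every node within grid distance ≤ r(t) of the BMU updated component-wise:
w_j ← w_j + α(t)·(x_j − w_j), skipping components where x_j is missing (a
missing input component never moves any node component). After training,
genes are assigned once more to their BMU under the final vectors.

Open choices, fixed as follows and configurable where noted:

* **Neighbourhood**: city-block grid distance with a flat ("bubble") update —
  all neighbours receive the full α. One grid metric is used consistently
  with the spatial statistics; a Gaussian kernel and other grid metrics are
  available as options but are not the tested default, since the update is
  defined as proportional to the learning rate with no distance decay.
* **Radius comparison**: `integer grid distance ≤ real-valued r(t)` without
  rounding, avoiding stair-step artifacts in the shrinking neighbourhood.
* **Tie-break**: smallest (y, x) lexicographically, which makes training and
  assignment fully deterministic; identical profiles always co-cluster.
* **Edges**: hard boundaries, no toroidal wrap-around.
* **Initialisation**: each node component for condition c is uniform on the
  observed [min, max] of c. Initialisation and presentation draws come from
  separate child streams of the seed, so the same seed gives bit-for-bit
  identical maps and changing the presentation count cannot silently alter
  the initial grid.

Defaults (25×20 grid, lr0 = 0.1, radius0 = 10, 20 presentations per gene,
Pearson) are the standard whole-transcriptome setup for ~10k genes; at that
scale the 500 nodes average ~20 genes each. Map size selection is
acknowledged to be somewhat arbitrary and is not automated.

## Over-representation analysis

Universe N = all mapped genes (genes without annotations stay in the
universe — the test is against "the rest of the map", not the rest of the
annotated genes). Terms annotating K < 10 or K > N/4 mapped genes are
excluded as uninformative, with boundaries read literally: K = 10 and
K = ⌊N/4⌋ are kept. For every occupied node × kept term, the one-sided
Fisher p-value is the upper hypergeometric tail P(X ≥ k), computed by
`scipy.stats.hypergeom.sf` and verified in the test suite against exact
integer-arithmetic tail sums for every contingency with N ≤ 60 (relative
error < 1e-10).

BH adjustment is the step-up rule q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j clipped to 1,
implemented directly because m — the number of tests performed — may exceed
the length of a displayed p-value subset; it matches
`statsmodels.multipletests(method="fdr_bh")` when m equals the list length
(tested). **m pools over all (node, term) tests performed**; whether to pool
across nodes or adjust per node is an open question in per-cluster ORA, and
pooling is the conservative, simply-stated choice. Empty nodes contribute no
tests. A result is *reported* only if its FDR passes the threshold **and**
k ≥ 4 genes in the node carry the term; the k-filter suppresses trivially
small overlaps with extreme p-values.

Parent/child GO term overlap is not corrected for. "Non-redundant" term
counting across thresholds collapses terms whose annotated mapped-gene sets
are identical (a frequent artifact of ontology structure); this requires the
annotation table, so `count_enriched_terms` takes it as an argument. No
ontology-aware overlap correction is attempted.

Annotation propagation to ancestors (along `is_a` and `part_of` by default,
via obonet/networkx) is an explicit optional step rather than a default,
since pre-built gene→GO tables are often already propagated; propagation is
idempotent and never removes an annotation.

## Spatial statistics

**Non-randomness test.** d = mean city-block distance from each set member
to its closest other member (co-located members contribute 0). Null: sets of
the same size drawn uniformly *without replacement* from all mapped genes.
p_raw = #{d′ < d}/n_samples with **strict** inequality — ties count as "not
smaller", so p_raw = 0 is reportable, and the degenerate set "all mapped
genes" gives p = 0 because every sample reproduces the set exactly. The
add-one estimate (count+1)/(n_samples+1) is reported alongside as
`p_conservative`, clearly an extension. Multiple testing: standard
Bonferroni p_corrected = min(1, p_raw·n_tests); callers wanting the
equivalent resolution can raise n_samples by the same factor. Set members
absent from the map are dropped with a warning (annotation and map universes
routinely differ); fewer than 2 mapped members is an error.

**Reproducibility.** Co-clustered pairs are sampled uniformly from the
multiset of all within-node pairs of the main map — a node with c genes
contributes c(c−1)/2 pairs, so populous nodes weigh more, which is the
natural reading of "randomly selected co-clustered pairs". Draws are with
replacement; each pair is looked up in a uniformly chosen alternate map and
counted as "same" (identical node) and "near" (grid distance ≤ near_radius,
default 5, city-block for consistency with the spatial test; configurable).
The chance level for "same" under assignment permutation has the closed form
Σ c(c−1)/(G(G−1)) over the alternate's occupancies, which the tests use as
an oracle.

## Synthetic data

The generator emulates the *structure* of a multi-publication compendium:
several experiment blocks of a few conditions each (default 4 blocks,
8+6+4+2 = 20 conditions), planted co-expression clusters shared across
blocks, per-gene Gaussian observation noise, independent missingness, and
per-experiment dynamic-range multipliers (default 2.0 / 1.0 / 0.5 / 1.5)
emulating the mix of wide- and narrow-range experiments found in real
compendia — including the consequence that wide-range blocks dominate
correlation structure. Cluster archetypes are independent N(0, cluster_sd²)
draws per condition scaled by the block multiplier; genes are archetype +
N(0, noise_sd²); cluster labels are assigned round-robin so sizes are
balanced. Defaults — 2000 genes, 10 clusters, noise_sd = 0.3·cluster_sd,
5% missing — are the package's standard end-to-end study conditions.
Fully-masked rows are redrawn so generated matrices always satisfy the
container invariants. Planted annotation terms mark one cluster each
(enrichment_fraction of its genes, default 0.8, plus background_rate of all
others, default 0.05).

All stages draw from named child streams of one seed (archetypes / noise /
mask / annotation), so adding draws to one stage never shifts another's.

What this does **not** emulate: hybridisation physics, probe effects, strain
polymorphism, non-Gaussian noise, correlated missingness, or realistic GO
DAG structure. Passing tests therefore demonstrate that the machinery
recovers planted structure under idealised noise, not that any particular
real compendium would yield a stable map.

## Problem sizes used by the test suite

Chosen as the package's own balance of statistical resolution and quick
feedback: end-to-end recovery runs 2000 genes × 20 conditions × 10 clusters
on a 15×10 map across 5 seeds (planted-term enrichment checked on 3, cluster
compactness on all 5); spatial-test calibration uses 200 random 30-gene sets
× 100 null samples on a 1000-gene 15×10 map; type-I calibration of the
enrichment p-values uses a 6×5 map of the same data so that nodes hold ~30+
genes — with ~7 genes per node the discreteness of the hypergeometric
support makes raw p-values visibly super-uniform, and the rejection rate at
0.05 drifts below any sensible calibration band; reproducibility checks use
20000 sampled pairs against the closed-form chance value with a 3-standard-
error band.

## Known limitations

* The SOM is the classical online algorithm: O(T × nodes × conditions) per
  run, single-threaded; no batch or hierarchical variants.
* Incomparability is resolved per comparison; a gene observed in very few
  conditions may be assigned on thin evidence (overlap just above
  `min_overlap`).
* BH pooling across nodes treats strongly dependent tests (same node, nested
  terms) as exchangeable; FDR control is approximate under such dependence.
* The spatial null ignores node occupancy structure beyond what sampling
  from the realised assignment captures; it answers "is this set tighter
  than a random set of mapped genes", not "tighter than a random set with
  the same expression support".
* Region outlines are node sets (plus optional 4-connected grouping);
  drawing is left to the caller.
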