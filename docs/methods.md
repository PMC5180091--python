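# Methods

## Problem and model

Cancer driver genes — tumor suppressors (TSGs) whose loss promotes disease
and oncogenes (OGs) whose activation does — are usually found by mutation
frequency in tumor cohorts, which misses infrequently mutated drivers.
`driverforest` implements the complementary *gene-similarity* strategy: learn
what driver genes look like across a broad table of gene-level properties
(genomic, expression, protein size, post-translational modifications,
network centrality, functional annotations, tumor mutation patterns) and
rank every gene in the genome by its resemblance to known drivers.

The statistical setting is positive-unlabeled (PU) learning.  A small
high-confidence positive set (165 drivers: 84 TSGs, 81 OGs in the reference
curation) stands against a ~97-fold larger background pool that certainly
hides unrecognized drivers.  The classifier is a three-class random forest
(TSG / OG / BG) with one non-standard ingredient: a **stratified,
down-sampled bootstrap**.  Each tree trains on the full positive count drawn
with replacement from the positives plus an equally sized with-replacement
draw from the background, so every tree sees balanced classes while the
ensemble as a whole covers the entire background pool.

Scoring is strictly **out-of-bag**: each tree records its exact in-bag gene
multiset, and a gene's posterior (P_TSG, P_OG, P_BG) averages the leaf
class proportions of precisely the trees whose bag excluded it.  Training
genes are thus scored without self-influence; genes outside the training
tiers (medium/low/other confidence) are scored by every tree.  The driver
score is P(driver) = P_TSG + P_OG.  Because of per-tree down-sampling these
scores are *ranking statistics*, not calibrated probabilities, and the
package documents them as such.

Closed-form consequences of the bagging design that the tests check: a
positive is absent from a given bag with probability (1 − 1/P)^P
(0.3668 at P = 165), and a background gene enters a given bag with
probability 1 − (1 − 1/N_bg)^P (0.01028 at N_bg = 15,972, P = 165).

## Label assembly

Published driver compendia disagree, so labels are tiered.  Admission to
the high-confidence set is driven by an *ordered rule list over evidence
sources* — base curated lists, anchor-plus-k-supporting-sources rules,
source intersections, and mutation-method votes whose role assignments are
manual curation and therefore ship as data, not code.  Later rules never
re-admit a gene; a conflicting role without an explicit override is an
error (the reference curation resolves its one dual-role gene, MYCN, by
removal).  Tier precedence is high > medium > low > other > background, and
the tiers partition the universe.  Training uses only high-confidence
positives and background negatives; medium/low/other genes are excluded
from training but still ranked.

The bundled reference curation reproduces, from its rule file plus a
synthetic evidence fixture, the documented arithmetic: 84 + 81 = 165 high
confidence, 682 medium, 1,360 low, 15,972 background in a 19,486-gene
universe, and mode-of-alteration counts 46/7/31 (TSG mutation/cna/both) and
46/23/12 (OG).  The fixture is a constructed stand-in — the real source
gene lists are not redistributable — with real symbols only where the
curation names them.

## Feature preparation

Derived features: genomic density (genes within ±4 Mb of the gene's center
position, divided by the mean count, so the output averages exactly 1; the
gene counts itself, which only shifts all counts by a constant before
normalization); interaction count (mean of the available per-database
counts); unnormalized Brandes betweenness centrality; tissue-expression
median and variation; PTM site counts divided by CDS length (amino acids).

The *variation* feature is mean divided by sample standard deviation — the
reciprocal of the conventional coefficient of variation — matching the
definition printed in the source feature table; the result carries a
`cv_convention` attribute so downstream users are not misled.

Cleaning runs in a fixed order and only ever drops columns or fills missing
cells:

1. **Sparse removal** — drop a feature iff its top-to-second value frequency
   ratio exceeds 97/3 *and* its distinct-value count is under 3% of genes; a
   missing marker counts as a value on both criteria.  (Counting "unknown"
   as a distinct value works *against* removal of missing-heavy features;
   the criteria are implemented literally and this tension is noted rather
   than resolved.)
2. **Correlation removal** — greedy: repeatedly take the pair with the
   largest pairwise-complete |Spearman| above 0.95 and drop the member with
   the greater mean absolute correlation to the remaining features;
   lexicographic tie-breaks make the outcome deterministic, and exactly one
   member of an exact-duplicate pair survives.  Undefined correlations
   (constant columns) are treated as 0 with a warning.
3. **Imputation** — 5-nearest-neighbor: distances are Euclidean over
   standardized columns, restricted to mutually observed coordinates and
   rescaled by coordinate count; a missing cell becomes the mean of the
   feature over the neighbors that observe it, falling back to the column
   median when none do.  Observed cells are bit-identical after imputation.
4. **Encoding** — binary 0/1 pass-through, categorical one-hot with an
   invertible column map, continuous unchanged.

## Enrichment statistics

The headline feature analysis asks whether TSGs concentrate among the very
largest proteins, especially chromatin regulators.  Primitives:

- Hypergeometric upper tail P(X ≥ k), summed exactly in log space from
  gammaln terms (inclusive tail by default; an exclusive switch exists
  because conventions differ).  On the bundled table of the 30 largest
  high-confidence driver proteins (26 TSGs), against 84 TSGs of 165
  drivers, this gives P = 8.56 × 10⁻⁶.
- Fold enrichment (k/n)/((K−k)/(N−n)); for the documented 92-gene
  top-5%-size ∩ chromosome-organization set containing 19 of the 84
  high-confidence TSGs in a 19,486-gene universe this is 61.6, i.e. 62-fold.
- Welch's unequal-variance t with Welch–Satterthwaite df for size
  comparisons.
- Size percentiles with max-rank tie handling (largest gene = 100.0); the
  top-q cut keeps every gene at least as long as the ⌈qN⌉-th largest, so
  boundary ties are never split.

No multiple-testing correction is applied to these few targeted contrasts.

## Evaluation protocol

Precision at N per confidence tier with panel-exclusion semantics: the
high-confidence panel excludes nothing, the medium panel first removes
high-confidence genes from the ranked list, the low panel removes high and
medium.  Precision(N) = |top-N ∩ tier| / N on the filtered list, so with the
tier as the only relevant set it equals the detected fraction.  Cumulative
detection is the unnormalized, non-decreasing counterpart.

TSG-vs-OG discrimination is an OOB ROC over the 165 positives with TSG
labeled 1 and score P_TSG/(P_TSG + P_OG) — the conditional posterior of TSG
given driver, the only two-class reduction consistent with the labeling;
AUC is computed by the Mann–Whitney rank statistic with midranks.

Stability retrains the forest with a fraction of positives dropped per
replicate (forest seed held fixed so the perturbation is the only varying
factor) and reports pairwise Spearman correlations of driver rankings over
non-training genes; defaults 10 replicates, drop fraction 0.1 — free
parameters, as no published protocol pins them.

## Synthetic universes

The generator emulates the statistical structure the analysis assumes, not
tumor biology: class-conditional mean shifts (`effect_size`, in standard
deviations) on informative continuous features, some driver-generic and some
TSG- or OG-specific; class-conditional Bernoulli rates on informative binary
flags; a log-normal CDS-length column (median ≈ 480 aa, log-sd 0.55) with
planted TSG ∩ chromosome-organization genes inflated by `size_inflation`
(default 3.8, the documented median ratio of chromatin-organization TSGs to
other TSGs); completely-at-random missingness; deliberately sparse and
exact-duplicate columns for the filters to find; uniform coordinates on one
250 Mb synthetic chromosome; a Barabási–Albert interaction graph; log-normal
tissue expression; and a noisy multi-source evidence matrix (per-source
sensitivity 0.9, false-positive rate 0.005, role-flip 0.05 — chosen once as
plausible multi-study evidence rates).

Desk-scale defaults are 2,000 genes, 40 TSGs, 40 OGs, ~40 features — the
full 19,486 × 131 scale is supported but unnecessary for verifying the
machinery.  What passing tests show: the pipeline recovers planted
structure of the assumed form (shifted means, enriched flags, inflated
sizes) under MCAR missingness.  What they cannot show: performance on real
driver data, whose feature dependencies, missingness mechanisms, and label
noise are richer than anything planted here.

## Numerical and design choices

- Per-tree seeds derive from the master seed and the tree index through a
  counter-based `SeedSequence` scheme: any tree is reconstructible in
  isolation and parallel execution cannot change results.
- Tree growth is delegated to scikit-learn's CART (`criterion="gini"`,
  `max_features=⌊√p⌋` by default, grown to purity); the ensemble, bag
  bookkeeping, OOB aggregation and unnormalized Gini importance (total
  weighted impurity decrease per feature, averaged over trees) are
  implemented in the package.
- OOB votes are soft (leaf class proportions averaged), which yields usable
  posteriors even with few OOB trees; a hard-vote forest would differ
  slightly.
- The positive bootstrap draws with replacement by default (a
  without-replacement switch exists, since reference implementations differ
  in `sampsize` semantics for a stratum equal to its pool).
- Ranking ties break lexicographically by gene identifier; a gene with zero
  OOB trees gets an undefined posterior and is excluded from ranking with a
  warning.
- Effect-size monotonicity is verified on levels spanning null → default
  (0.0 / 0.75 / 1.5): above ≈1.5 the held-out drivers' median rank sits at
  its floor, so higher levels only reproduce the plateau.

## Limitations

Posteriors are uncalibrated by design.  The evidence fixture reproduces
documented set sizes, not real gene lists, so tier membership of synthetic
placeholder genes is arbitrary.  The generator plants no inter-feature
dependence beyond the duplicate columns, no informative missingness, and no
tumor-type structure.  Full-scale runs (10⁵ trees on 19,486 × 131) are
supported by the same code paths but are not exercised in the test suite.
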