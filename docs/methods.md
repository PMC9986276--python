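# Methods

`emotifre` classifies candidate regulatory elements as active or non-active
enhancers from sequence alone and extracts the transcription-factor motifs
that drive the classification. This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Problem setting

Open-chromatin regions (ATAC-seq peaks) are split into **active enhancers**
(regions overlapping an H3K27ac ChIP-seq peak by at least one base) and
**non-active enhancers** (no overlap). Promoter-proximal regions — anything
overlapping a (−1000, +100) window around an annotated TSS, strand-mirrored
for minus-strand genes — are removed from both sets, since they regulate
transcription by a different mechanism. Surviving regions are re-centered
to a fixed length N around the peak midpoint (floor of the integer midpoint;
for odd N the upstream side receives floor(N/2) and the downstream side
ceil(N/2)), and sequences containing any N base are dropped so that one-hot
encoding is unambiguous. All interval arithmetic is BED-convention 0-based
half-open.

The two classes differ in base composition as well as motif content: active
enhancers are GC-richer. The per-sequence G+C fraction (N bases excluded
from the denominator) is compared between classes with the two-sided
Mann–Whitney rank-sum test — the sets are unpaired and of different sizes,
so a signed-rank (paired) test is not applicable.

## Classifier

Sequences are one-hot encoded (channel order A, C, G, T) and fed to a small
convolutional network:

    conv1d(n_filters, kernel_size) → ReLU → global max pool per filter
    → dense(dense_units, ReLU) → single sigmoid unit

Defaults: 32 filters of width 16, 32 dense units, Adam at learning rate
1e-3, batch 64, at most 100 epochs with early stopping on validation loss
(patience 10), stratified 70/15/15 train/validation/test split, binary
cross-entropy with inverse-frequency class weights (the real class sizes
are far from balanced, and unweighted training biases the sigmoid). These
are standard settings for single-conv-layer genomics CNNs of this size; a
grid-search helper trains every combination of a user grid on identical
splits and selects by validation AUROC. Reverse-complement augmentation is
available as a flagged option and off by default.

The network, its backpropagation and the optimizer are implemented directly
on NumPy arrays. The model is small enough that explicit im2col matrix
multiplication trains it in seconds on one CPU, and an explicit backward
pass yields exact gradients with respect to the input — the quantity the
attribution stage integrates. With a fixed seed, training is deterministic
on a given machine.

The comparison baseline is logistic regression on the flattened one-hot
matrix, trained on the same splits. A "linear regression" on 0/1 labels is
statistically incoherent for classification, so the linear model uses a
sigmoid link; the comparison metric is held-out AUROC either way.

## Attribution

Integrated Gradients along the straight path from a baseline to the input,
right Riemann sum with 128 steps by default. The baseline is the uniform
profile (0.25 in every channel) — the standard neutral reference for
one-hot DNA, and the choice that makes hypothetical scores symmetric across
bases. Attribution is computed on the pre-sigmoid logit by default because
the probability gradient vanishes under saturation; a flag switches to
probability-scale attribution.

Three per-sequence matrices are kept:

* **raw** attribution `(x − baseline) ⊙ mean path gradient`, which carries
  the completeness axiom: its sum converges to `f(x) − f(baseline)`;
* **hypothetical** scores `mean path gradient ⊙ (1 − baseline)`, the
  attribution each base would receive were it observed;
* **importance**, the hypothetical matrix projected onto the observed
  one-hot sequence (identical to the raw attribution at observed entries).

Completeness is verified on the raw attribution. The tolerance is absolute
(0.01) for probability-scale attribution, where the output has magnitude at
most 1; on the logit scale the discretization error of a 128-step right sum
is on the order of 0.5% of the output difference for a trained network, so
the check there is relative. Violations are logged, never corrected.

## Motif discovery

A deliberately simple, deterministic aggregator condenses attribution
tracks into motifs (the full TF-MoDISco machinery — fine-grained similarity,
Leiden clustering, metaclusters — is intentionally not reproduced; the
acceptance surface is motif recovery, which this procedure achieves):

1. **Seqlets.** Per sequence, every window of width W = 15 is scored by its
   summed observed-base importance. The keep threshold is the 99th
   percentile of |window sums| under 5 random permutations of that
   sequence's position-importance values (fixed seed). Kept windows are
   resolved greedily by descending |score| so seqlets never overlap.
2. **Sign partition.** Seqlets split by attribution sign: positive seqlets
   push the active-enhancer probability up, negative ones down. Clusters
   never mix signs, and a motif's importance score (mean member score)
   states which set it is enriched in.
3. **Greedy clustering.** Seqlets processed by descending |score|; each is
   compared to existing centroids by best-offset Pearson correlation of
   hypothetical slices, both orientations, requiring ≥ 70% column overlap;
   it joins the best centroid at correlation ≥ 0.7, else founds a new
   cluster. Centroids are running means of aligned member hypotheticals;
   reverse-complement joins store the member complemented (motif
   strandedness is arbitrary).
4. **PWM.** Member one-hot slices aligned at their joining offsets are
   summed per column; a pseudocount of 0.5 per column (split over bases) is
   added before normalization. Frame columns covered by no member are
   dropped. Clusters with fewer than 3 members are discarded as noise.

## Trimming, stringency and the spurious-motif filter

Column information content is `IC = 2 + Σ p log2 p` bits (0·log2 0 := 0).
Aggregated motifs carry uninformative flanks; trimming keeps the span
between the first and last column with IC > 0.3 bits and flags a motif with
no such column as degenerate. A position is *stringent* at IC > 1.9 bits;
genuine TF preferences are rarely near-deterministic, so a mostly stringent
PWM is suspect.

A motif is kept only if it passes all seven criteria:

1. **bias** — the fraction of columns whose preferred base(s) are all G/C
   is below 80%, and likewise for A/T. A column's preferred set is every
   base within 1e-9 of the column maximum; ties spanning both groups
   (including uniform columns) count toward neither. This is one concrete
   reading of the composition-bias rule, isolated in one function so it can
   be swapped.
2. **length** — trimmed width > 4 nt.
3. **stringency** — stringent positions < 75%.
4. **correspond** — the database search returns at least one non-degenerate
   match with positive similarity.
5. **overlap** — the best match covers ≥ 70% of the query width.
6. **similarity q** — the best match's BH-corrected q-value < 0.05.
7. **expression** — the matched TF passes the transcription rule below.

Criteria 5–7 are properties of the best match; when no valid match exists
(criterion 4 fails) they are recorded as not applicable rather than failed,
and the overall verdict fails through criterion 4. The overall flag is the
conjunction of the seven.

### Similarity search

For a query and a database entry, every ungapped offset in both
orientations is considered, provided the alignment covers at least 70% of
the shorter motif (floor two columns). Alignments are scored by the **sum**
of per-column Pearson correlations between aligned probability columns; the
reported score is the mean over the selected alignment. Two choices here
deserve justification:

* *Minimum overlap.* With unconstrained overlaps, any two motifs align
  perfectly on one lucky column pair, saturating both the ranking and the
  null.
* *Sum vs mean.* Under a mean score, a short chance alignment can outscore
  a long consistent one (a 5-column reconstruction under the null beat a
  true full-width match in roughly 0.3% of shuffles); the summed score makes
  longer consistent alignments dominate, the same aggregation logic TOMTOM
  uses.

The p-value is empirical: the best summed score is compared against
shuffled queries, where a shuffle permutes the column order **and**,
independently per column, the four channel values within the column. The
channel permutation preserves each column's information content while
breaking base identity. Column-order-only shuffles span at most w!
distinct queries — fewer when columns repeat, as they do in GC-skewed
motifs — and floor the p-value so high that even an exact match cannot
reach significance after multiple-testing correction. The default is 5000
shuffles: Benjamini–Hochberg across a database of ~60 entries at α = 0.05
requires trustworthy p-values near 0.0017, and with only 1000 shuffles a
single binomial fluctuation in the null doubles the estimate. Zero-variance
(uniform) columns have undefined correlation; they contribute 0 and set a
degenerate flag rather than propagate NaN. q-values across the database are
BH-corrected (`scipy.stats.false_discovery_control`).

### Scanning and enrichment

Sequences are scanned on both strands with the log2-odds matrix against a
uniform 0.25 background; PWM entries are floored at 1e-4 before the log so
database motifs containing exact zeros stay finite. A sequence is a *hit*
when some window reaches 80% of the maximum achievable log-odds (the
threshold fraction is exposed; no single convention is canonical across
scanning tools). Enrichment of hits in actives vs non-actives is a
two-sided Fisher exact test; reported odds ratios use the Haldane
half-count correction when a cell is zero.

### Expression rule

A TF is *transcribed* if its expression rises at least 2-fold from Day 0 to
Day 26 and does not rise from Day 26 to Day 39 (Day 39 ≤ Day 26, no
tolerance band). A pseudocount of 1 expression unit guards the ratio
against zero baselines. This filters motif matches to factors actually
induced in the progenitor stage.

## Co-occurrence

For a motif pair, per-sequence hit indicators define a 2×2 table
(both / A only / B only / neither) tested with a two-sided Fisher exact
test. The table can also be reconstructed directly from published marginal
counts — total sequences, hits of each motif, shared — since those counts
are inputs, not measurements. The test is two-sided: the direction of
association is reported through the odds ratio, not assumed.

## Synthetic data

The generators produce data with the statistical structure the method
assumes, with truth manifests for every planted feature:

* **Backgrounds** are i.i.d. order-0 sequences with P(G)=P(C)=gc/2. The
  reference conditions are 2,000 + 2,000 sequences of 200 bp with the
  active set at GC 0.55 and the non-active at 0.45 — the two classes differ
  in GC composition, as the real sets do — and the ASCL1-like core CAGCTGC
  implanted in 40% of actives at uniform random positions (implants
  overwrite background, keeping length fixed). With motif content alone a
  40% implant rate caps achievable AUROC at 0.70 (0.4 + 0.6·0.5); the
  two-component signal is what makes the classification task realistic.
* **The AND task** plants both of two motifs in every positive (motif A
  uniformly in the left half, B in the right, in all classes, so placement
  carries no label information and implants cannot overwrite each other)
  and exactly one of the two in each negative. Each motif's marginal
  presence is then weakly informative, while the pair interaction separates
  the classes — the signal a single affine map dilutes across positions but
  a conv/max-pool network composes.
* **The toy genome** plants candidate peaks, H3K27ac marks over a known
  subset and TSSs inside chosen promoter windows, so the full preprocessing
  chain has exact expected counts.
* **The motif database** holds softened PWMs of the eight TF cores the
  analyses revolve around (ASCL1/NHLH1, SOX4/SOX11, ZEB1, NEUROG2, CTCF,
  NR2F1) plus random decoys. Minor probabilities are drawn from a Dirichlet
  rather than split evenly: exactly equal minors make a column invariant
  under a quarter of channel permutations — an artifact real binding models
  do not show — which would blunt the similarity null.
* **The expression table** realizes the expected patterns: the ASCL1/SOX
  family rising ≥ 2-fold into Day 26 then leveling off; ZEB1/NEUROG2/NR2F1
  failing the fold rule; CTCF high but flat (expressed, not induced); flat
  decoys.
* **Filter fixtures**: eight constructed (motif, database, expression)
  triples, one failing exactly each of the seven criteria and one passing
  all, used to exercise the filter ledger criterion by criterion.

What the synthetic benchmarks do **not** show: order-0 backgrounds lack the
dinucleotide structure, repeats and CpG islands of real enhancers; implanted
consensus instances are cleaner than genomic binding sites; and the toy
motif database is far smaller than JASPAR-scale collections. Passing these
benchmarks demonstrates that the machinery is correct and recovers planted
structure, not genome-scale performance.

## Problem sizes

The bundled checks train on the reference 2,000 + 2,000 × 200 bp conditions
(attribution on a 600-sequence subset at 128 steps; motif recovery repeated
over five seeds), which keeps a full verification run within minutes on a
single CPU while leaving the training problem hard enough that an
underpowered model fails it.

## Known limitations

* The similarity p-value is distribution-free but empirical; it is
  comparable to TOMTOM's analytic q-values in spirit, not numerically.
* The greedy seqlet clustering is order-dependent (by |score|); a different
  extraction threshold shifts motif widths, which the IC trimming then
  largely normalizes.
* GC-composition differences between classes leak into attribution: beside
  the implanted motif, discovery also reports composition-driven patterns
  (GC-rich positive, AT-rich negative motifs). The filter criteria — bias
  and database correspondence in particular — are what removes them, as in
  the real workflow.
* The pipeline treats the REPTILE-style candidate filtering as upstream: it
  consumes candidate BEDs as given.
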