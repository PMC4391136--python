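# Methods

## The problem

Shotgun metagenomic pipelines count reads per gene family (KEGG Orthology
group, "KO") and must normalize those counts before samples can be
compared. The near-universal convention — dividing each gene's abundance by
the sample total ("compositional" normalization) — yields unitless relative
abundances that depend on everything else in the sample. Three
sample-specific properties in particular distort them: the abundance-
weighted **average genome size** (bigger genomes dilute every individual
gene's relative share), the **species richness**, and the **mappability**
of community members to reference genomes (poorly characterized taxa lose
reads to unannotated genes, inflating the apparent share of well-conserved
genes). The result is spurious inter-sample variation: genes that are
identically present in every community member still appear to vary across
samples.

## Marker normalization (average genomic copy numbers)

`scgnorm` instead anchors every sample to a set of **universal single-copy
genes** (USiCGs) — KOs present in nearly all prokaryotic genomes at one
copy. Each sample's length-normalized gene abundances are divided by the
*median* abundance of the markers in that sample:

    a_hat(k, s) = a(k, s) / median_{m in markers} a(m, s)

Because every cell contributes exactly one copy of each marker, the marker
median estimates "abundance per genome copy", and the normalized value of
any gene is its **average genomic copy number** across the cells of the
community — the gene content of a typical community member. Two properties
follow directly and are enforced by tests:

* the marker median equals 1 in every normalized sample;
* the output is invariant to any per-sample rescaling of the input, so
  sequencing depth and compositional closure cancel exactly.

The median is taken over the full marker set with undetected markers
counted as zeros: zeros are measurements, and with 76 markers the median
tolerates a few dropouts. A guard (default: at least 10 markers detected,
and a positive median) rejects degenerate samples, or drops them under the
`on_low="drop"` mode. Even-length medians are the mean of the two central
values. Zero abundances remain exactly zero through every normalization;
no pseudocounts are introduced.

### Marker selection

Markers are selected from a genome-by-KO copy matrix by a prevalence band
and a copy cutoff: prevalence (fraction of genomes with copy ≥ 1) in
`[prevalence_min, prevalence_max)` and mean copy number **conditional on
presence** strictly below `mean_copy_max`. Defaults: strict band
prevalence ≥ 0.915 with mean copy < 1.1; relaxed ("semi-universal") band
[0.85, 0.915) with the same copy cutoff. The band is closed below and open
above so the two sets are disjoint by construction; a prevalence exactly at
the cutoff is included. The packaged default lists (76 strict, 72 semi)
are synthetic stand-ins curated from well-characterized universal
single-copy orthologs — ribosomal proteins, aminoacyl-tRNA synthetases and
core translation/transcription machinery — and are labelled as such in
their file names and headers.

Gene co-occurrence uses presence/absence only: pairs with Jaccard
similarity strictly above 0.95 form a graph whose maximal cliques
(Bron–Kerbosch with pivoting, via networkx) of at least five genes are
reported as clusters. Overlapping cliques are all reported. KOs absent
from every genome have undefined similarity and are excluded with a log
message.

## Gene-specific bias correction

Marker normalization fixes *inter*-sample distortion but not
*intra*-sample bias: within one sample the 76 markers — all true copy
number 1 — still differ systematically, and consistently so across
samples, because gene properties (GC content, length variability across
the orthology group, annotation recall/precision, conservation) bias the
measurement. The correction model treats the markers as a calibration set:

* response: each marker's fold-change, its abundance over the mean marker
  abundance in the sample (responses average to 1 by construction); the
  ratio scale, not log, matches the fold-change definition;
* covariates: standardized gene properties (missing values imputed with
  the training-set median before standardization);
* model: elastic net (`fold ~ intercept + Σ w_j z_j`), mixing parameter
  default 0.5 with 1.0 (pure L1) available.

Model selection is nested cross-validation with folds **grouped by marker
KO** (a marker's observations never straddle train and test — the strict
held-out-gene reading; fold assignment is a seeded permutation of marker
ids). Outer folds (default 5) give the held-out R², computed per fold and
averaged; the penalty is chosen inside each outer training set by inner
cross-validation (scikit-learn's `ElasticNetCV` over its default penalty
path); the reported model is refit on all markers with the median selected
penalty and standardization parameters recomputed from all markers. A
zero-variance response short-circuits to the trivial model (all weights 0,
R² reported as 0, warning).

Correction divides each gene's abundance by its predicted fold-change —
the unique choice that maps a perfectly predicted marker back to its
expected value of 1. Predictions are clamped below at 0.01 to prevent sign
flips or explosions for genes far outside the marker property range (clamp
events are logged); genes without property values pass through uncorrected
(count logged); zeros stay zero, so the correction is per-sample scale
free. Two operating modes exist: a per-sample fit (`fit_bias_model`) and a
pooled "generic" model learned once across many samples
(`fit_shared_bias_model`) and applied to new samples unchanged. Models
serialize to flat, diffable key-value text.

## Sample properties and correlation machinery

From OTU profile bundles (PICRUSt-style: per-sample OTU relative
abundances, per-OTU predicted KO copies, per-OTU NSTI):

* **OTU genome size** = Σ copies × average KO length (bp); **average
  genome size** = abundance-weighted mean over OTUs;
* **richness** = number of OTUs above a detection threshold (default 0);
* **mappability** = abundance-weighted mean of (1 − NSTI). NSTI of absent
  OTUs is ignored; present OTUs lacking NSTI are dropped with the weights
  renormalized over the retained OTUs and the dropped mass logged.

`partial_correlation` residualizes both variables on the controls by OLS
and correlates the residuals; p-values are two-sided from a t distribution
with n − 2 − #controls degrees of freedom; with no controls it reduces to
plain Pearson. A residual whose variance is at float-roundoff level
(≤ 1e-24 of the original variance) is treated as exactly explained and
returns r = 0 with a warning. `residual_correlation` robustly fits the
response on a regressor (IRLS, bisquare weights, tuning constant 4.685 —
the conventional 95%-efficiency default) and correlates the residuals with
a probe.

## The simulator

The simulator is the ground-truth instrument: communities with known gene
content, so the true average copy number of every KO is computable exactly
(abundance-weighted mean of per-genome copies, normalized by the float sum
of abundances so uniformly single-copy genes are exactly 1.0).

Defaults define the benchmark conditions:

* **pool**: 21 genomes over a 600-KO universe — 76 markers (copy 1 in
  every genome), a 35-KO invariant pathway at identical copies in every
  genome (so its true abundance is constant across any community, and all
  observed variation is spurious by construction), and 489 accessory KOs
  present per genome with Bernoulli probability spanning 0.10–0.95 across
  genomes, at copies 1 + Poisson(0.3). Average KO lengths are log-normal
  around ~900 bp (clipped to 150–5000 bp); annotated genome lengths
  consequently span more than 3-fold, which is what makes average genome
  size a live confounder. Unannotated (intergenic) padding defaults to 10%
  of annotated length.
* **communities**: 10 genomes drawn uniformly per sample, relative
  abundances log-uniform over [1, 100] then normalized (max/min ratio
  ≤ 100 by construction).
* **reads**: 500,000 reads of 101 bp per sample by default. Reads land on
  genomes multinomially with probability ∝ relative abundance × genome
  *length* (longer genomes contribute more DNA — the mechanism behind the
  genome-size confounding of compositional profiles), then within a genome
  on a KO (or padding) ∝ copies × gene length. Padding reads are
  unassigned.
* **annotation error**: origin-tracked reads are assigned at the KO level
  rather than via sequence alignment; per-KO recall and a uniform
  misassignment probability emulate annotation error. No sequences, quality
  scores or sequencing-error models are generated.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning; identical seeds reproduce identical outputs.

What the simulator does *not* emulate: real read mapping and its
homology-dependent errors, strain-level variation, uneven coverage along
genomes, 16S copy-number effects, or realistic phylogenetic structure in
gene content. Passing the benchmarks therefore shows that the estimator
recovers copy numbers when its model of the data holds — depth effects,
composition closure and genome-size confounding are removed exactly — not
that every real-data bias is corrected.

### Benchmark scale

Tests and the acceptance script run the benchmark at 20 samples ×
100,000 reads (one fifth of the default read depth), a size chosen so the
whole run takes seconds while leaving per-sample counting noise far below
the effect sizes being measured. At this scale the per-sample regression
of corrected abundance on true copy number has mean slope ≈ 1.00, the
invariant pathway's CoV under marker normalization is ≈ 0.015–0.02
(vs ≈ 0.13–0.17 compositional), and the closed-form genome-size estimate
correlates with the true average genome size at r ≈ 0.998.

## Genome-size-based alternatives

Two estimators of per-sample average genome size are provided for
comparison, both used to rescale compositional profiles:

* closed form from marker read density: `EGS = (a + b·L^−c)/x` with
  defaults a = 21.2, b = 4230, c = 0.733 and read length L. The density x
  is Σ(matched bases / marker gene length) over marker-hitting reads,
  divided by total sequenced bases — the division by total bases is this
  package's depth-invariant reading of a per-sample density. Note EGS is
  strictly *decreasing* in both x and L.
* per-marker panel estimate `G_i = (g_i + L − 2m)/f_i` (gene length g,
  read length L default 75, minimum overlap m default 90, relative
  abundance f), averaged over a small panel of universal genes and
  multiplied into the relative abundances. Panel markers with f = 0 are
  skipped (at least one required). The panel itself is a configurable
  input with no packaged default.

## Comparative-analysis layer

* **Pathway abundance**: sum of member-KO abundances; absent members count
  as zero.
* **Differential features**: two-sided Wilcoxon rank-sum per feature
  (scipy; exact for small tie-free groups, tie- and continuity-corrected
  normal otherwise; midranks for ties), Bonferroni or Benjamini–Hochberg
  adjustment (adjusted p floored at raw p), optional
  higher-median-in-group filter for disease-associated pathway calls.
* **CoV bootstrap**: CoV = sd (n−1) / mean over all samples and over
  seeded random subsets without replacement (defaults: 100 subsets of 10).
* **Slope vs truth**: per-sample OLS of corrected abundance on true copy
  number, free intercept; summaries are the mean and CoV of the slopes.
* **OTU-specific genes (OSGs)**: KOs carried by exactly one OTU *present*
  in a sample. Their abundance should track their OTU's: Pearson
  correlation across the samples where the pairing holds (pairs observed
  in < 5 samples excluded), and a fold-change concordance in which, per
  OTU, samples are ordered by OTU abundance and only consecutive pairs are
  compared; the discrepancy is the symmetric |log(OSG fold-change / OTU
  fold-change)| (the log-ratio form is this package's choice).
* **Correlation-structure similarity**: per KO, the Pearson correlation
  between its vector of genomic Jaccard similarities to all other KOs and
  its vector of metagenomic abundance correlations, diagonal dropped.
* **Cross-study recovery**: the alternative setting's significant set is
  truncated to the reference's size by raw p (ties broken by feature id,
  logged) before counting the intersection — preventing artificially high
  recall when the cross-study comparison floods the significance list.

## Numerical and design notes

* Tables are validated on construction: non-negative, no missing cells
  (explicit zeros), unique identifiers; compositional columns must sum to
  1 within 1e-9. Readers reject malformed input with row/column locations
  rather than coercing; an explicit flag turns empty cells into zeros with
  a logged count.
* Table orientation is KOs-as-rows; a transpose flag handles
  samples-as-rows input. Identifiers are opaque strings. The `#stage=`
  sidecar line recording a table's processing stage is this package's
  convention.
* Values are serialized with 15 significant digits; read/write round trips
  are the identity to < 1e-10.
* The processing-stage enum includes `genome_size_corrected` for the
  output of the genome-size schemes, which otherwise have no stage.
* BIOM input is not supported (TSV only); model files, marker lists and
  pathway maps are plain text.

## Known limitations

* The bias model is linear in standardized properties; strongly nonlinear
  property effects are only partially captured, and extrapolation beyond
  the marker property range is guarded only by the prediction clamp.
* Held-out R² of the bias model is computed per outer fold and averaged;
  with ~15 test markers per fold the estimate is noisy, and single fits
  can land a tenth above or below the average over replicates.
* Marker selection thresholds are taken as fixed defaults, not re-derived
  from a genome database.
* The simulator's annotation-error model (per-KO recall plus uniform
  misassignment) is a coarse stand-in for alignment-based annotation.
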