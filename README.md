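# scgnorm

Single-copy marker-gene normalization of metagenomic functional profiles.

Shotgun metagenomics measures the functional capacity of a microbial
community by counting reads per gene family (KEGG Orthology group, "KO").
The standard normalization — dividing by the sample total — produces
relative abundances that are confounded by the community's average genome
size, species richness and mappability to reference genomes: genes that
are identically present in every member genome still appear to vary
between samples. `scgnorm` is for microbiome researchers who want
abundances they can compare across samples and interpret biologically.

Instead of the sample total, each sample is divided by the median
abundance of a set of **universal single-copy genes** (USiCGs) — KOs found
in essentially all prokaryotic genomes at exactly one copy:

    â(k, s) = a(k, s) / median_{m ∈ USiCGs} a(m, s)

Since every cell carries one copy of each marker, the marker median is the
per-sample abundance of "one genomic copy", and â(k, s) estimates the
**average genomic copy number** of gene k — the gene content of a typical
community member. The marker median is 1 in every normalized sample, and
the result is invariant to sequencing depth and compositional closure.

The package also provides:

* **gene-specific bias correction** — an elastic-net model on gene
  properties (GC content, length variability, annotation recall, ...),
  trained on the markers of a sample with nested marker-grouped
  cross-validation and used to divide every gene by its predicted
  measurement bias;
* **marker selection** from genome×KO copy matrices (prevalence band +
  conditional mean-copy cutoff) and Jaccard co-occurrence clustering;
* **sample-property estimation** (average genome size, richness,
  mappability) from OTU profile bundles, plus partial/residual correlation
  machinery;
* **a mock-community shotgun simulator** with origin-tracked reads and
  exact per-sample true copy numbers, including an invariant pathway whose
  observed variation is spurious by construction;
* **comparative analyses**: Wilcoxon rank-sum differential KOs/pathways
  with FDR control, CoV bootstraps, slope-vs-truth regression,
  OTU-specific-gene concordance, correlation-structure similarity and
  cross-study recovery;
* two genome-size-based alternative normalizations (closed-form effective
  genome size from marker read density, and a per-marker panel estimate)
  for comparison.

## Worked example

`examples/02_simulated_benchmark.py` simulates 20 samples (10 genomes each
from a 21-genome pool, abundances spanning up to 100-fold, 100,000 reads
per sample), normalizes the counts, and scores both schemes against the
known truth:

```python
import scgnorm as sg

ds = sg.simulate_dataset(n_samples=20, n_reads=100_000, seed=11)
marker_norm = sg.marker_normalize(
    sg.length_normalize(ds.counts, ds.ko_length), ds.markers
)
summary = sg.slope_vs_truth(marker_norm, ds.truth)
```

It prints:

```
marker normalization: mean slope vs truth = 1.000 (CoV of slopes 0.013)
invariant pathway CoV: marker-normalized 0.018 vs compositional 0.130
bootstrap (100 subsets of 10): mean subset CoV 0.018 vs 0.132
```

The mean per-sample regression slope of 1.000 means the normalized values
*are* the true average copy numbers, not just proportional to them. The
invariant pathway has identical copy numbers in every pool genome, so its
true abundance is constant: the coefficient of variation of 0.018 under
marker normalization is residual counting noise, while the 0.130 under
compositional normalization is the spurious variation induced by
genome-size and composition effects. The other scripts in `examples/`
cover bias correction, marker selection, sample properties and
differential pathway testing, one capability each.

A thin CLI wraps the same functions:

```sh
scgnorm simulate --n-samples 20 --seed 11 --out-dir sim/
scgnorm normalize --input sim/ko_counts.tsv --ko-lengths sim/ko_lengths.tsv \
    --marker-set sim/markers.txt --method marker --output corrected.tsv
scgnorm evaluate slope --input corrected.tsv --truth sim/true_copy_number.tsv
```

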