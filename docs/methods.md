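# Methods

## Scope and data model

`cnvsweep` implements the analysis stages between a window-depth matrix and
a table of candidate differentiated CNV loci: read-depth genotyping,
per-locus V_ST and Weir–Cockerham F_ST between a case and a control group,
top-quantile candidate selection and intersection, gene overlap and
hypergeometric pathway enrichment. Upstream read processing (QC, alignment,
deduplication) is out of scope; the tested contract starts at a TSV of
per-individual read counts over fixed-width windows. All coordinates are
1-based inclusive internally and on disk; BED input/output converts at the
boundary.

## Synthetic cohort generator

The generator emulates a two-breed goat cohort of 37 females — 23 cases
carrying the trait and 14 controls — genotyped at 12,310 CNV loci built
from 800 bp windows. It produces truth in two layers so every downstream
stage has an oracle:

1. **Truth copy numbers.** Each locus draws a per-locus minor copy class
   (CN 1 or CN 3, equally likely) carried at frequency 0.2; everyone else is
   diploid (CN 2). A fraction `frac_differentiated` (default 1%, i.e.
   round(0.01·12310) = 123 loci) is *planted*: the case group's copy numbers
   are additionally shifted by ±2 (sign per locus), clipped to [0, 8]. Loci
   are redrawn until at least 2 carriers exist, because CNV loci are by
   definition ascertained polymorphic variants — a "CNV" locus nobody
   carries would not appear in a caller's output, and an unranked locus
   would silently shrink the selection universe.
2. **Read depth.** Each locus expands into `windows_per_locus` adjacent
   800 bp windows sharing the locus copy number; depth at window w of
   individual i is Poisson(f_i · λ · CN/2 · g(GC_w)) with λ = 30 reads per
   diploid window, a per-individual library-size factor f_i ~ U(0.8, 1.2),
   and an optional sinusoidal GC bias g(GC) = 1 + A·sin(2πGC) (A = 0 by
   default; the knob exists to exercise the GC-correction stage). An
   optional overdispersion multiplier m ≥ 1 gamma-mixes the Poisson mean,
   giving a negative-binomial marginal with variance m times the mean, for
   robustness tests.

Loci default to 4 windows (~3.2 kb). Reported CNV regions in livestock
resequencing studies span several windows — top signals in such scans
commonly cover a few to tens of kilobases — and multi-window loci are
what makes rounding-based integer genotyping reliable at λ = 30: a single
800 bp window at that depth has normalized-CN noise of ~0.37 sd against a
rounding half-width of 0.5, whereas the 4-window mean brings per-entry call
accuracy to ~99%. Loci are separated by a 2-window gap so that run-length
merging of aberrant windows recovers exactly the simulated locus spans.

What the generator deliberately does **not** model: linkage and demographic
structure between loci (loci are independent), breed substructure within
groups, mappability/repeat artifacts, shared boundaries between overlapping
CNVs, and sex-chromosome dosage. Tests passing on this cohort therefore
demonstrate correctness of the statistics and the recovery machinery under
idealized sequencing noise, not robustness to real-data artifacts.

## Genotyping

* **Normalization**: ncn[i,w] = 2·depth[i,w] / median over autosomal windows
  of individual i, so each individual's median normalized CN is exactly 2.
  The median is robust to CNV-rich regions; X/Y windows are normalized with
  the same factor but excluded from it.
* **GC correction** (optional): windows are grouped into 20 equal-width GC
  bins; each value is divided by the individual's bin-median/global-median
  ratio.
* **Locus definition**: a window is aberrant when ≥ 5% of individuals fall
  outside [1.5, 2.5]; maximal runs of coordinate-adjacent aberrant windows
  on one chromosome become loci. The 1.5/2.5 bounds and the carrier
  fraction are explicit knobs — real callers bury equivalents inside their
  merging heuristics.
* **Integer calls**: locus ncn (mean over member windows) rounded half away
  from zero and clipped to [0, cn_max = 8]. Half-away rounding is
  deterministic and unbiased for CN x.5 boundaries, unlike banker's
  rounding, which would systematically pull 2.5 calls down to 2.
* **QC**: the silhouette coefficient of the integer-CN clustering on 1-D
  distances (singleton classes contribute 0; one class scores 0) and the
  folded non-modal class frequency (MAF). Retention requires silhouette
  ≥ 0.6 **and** MAF ≥ 0.05. The source protocol words both thresholds with
  "≤"; read literally that would *retain only* poorly separated, mostly
  monomorphic loci, so the thresholds are interpreted as the conventional
  retention criteria (filter out silhouette < 0.6 or MAF < 0.05). Both are
  configurable.

Note one property of the silhouette on interleaved 1-D data: classes with
identical means score strongly *negative* (≈ −0.5), not 0; the QC filter
only relies on well-separated classes scoring high.

## Sweep statistics

* **V_ST** is computed on continuous normalized copy number (not integer
  calls): that is how the statistic is defined for intensity/depth-ratio
  data, and rounding discards exactly the within-group variance it
  measures. Group variances use the sample (n−1) convention by default,
  with population-size weighting V_S = (n₁V₁ + n₂V₂)/(n₁+n₂). The
  convention is a flag because it changes values at n = 23/14: the two
  conventions give different numbers even for n₁ = n₂ (e.g. identical
  groups score exactly 0 under the population convention but slightly
  negative under the sample convention), although at n₁ = n₂ they induce
  the same ranking. Loci with V_T = 0 are flagged undefined and excluded
  from ranking.
* **F_ST** is the Weir & Cockerham (1984) single-locus two-population
  estimator θ = a/(a+b+c) from allele and heterozygote frequencies of a
  biallelic encoding of integer CN: deletion loci map CN 2/1/0 to
  ref/ref / ref/alt / alt/alt; duplication loci map CN 2/3/≥4 likewise;
  mixed loci are split into a deletion and a duplication sub-locus and the
  larger θ is reported. The encoding is isolated in one function
  (`cn_to_biallelic`) because depth-based CNV genotypes are not inherently
  biallelic and alternative encodings are defensible. Monomorphic loci
  (a+b+c = 0) are undefined and excluded from ranking.
* Negative V_ST and θ values are reported as-is; clamping at 0 would alter
  distributional tests while leaving the top-1% selection unchanged.
* **Selection**: k = ⌊αN⌋ (minimum 1) top-scoring loci over the N defined
  scores, boundary ties broken by ascending genome order; the threshold is
  reported as the smallest selected score, matching the "top 1% ≥ t"
  convention of published scans. The intersection of the V_ST and F_ST
  candidate sets is an exact set intersection in genome order.

At null (no planted loci) the two statistics are strongly positively
correlated — both respond to the same chance case/control difference at a
locus — so the candidate intersection is far above the k²/N ≈ 1.23
independence expectation (measured: ~100/123 when both are computed from
the same truth copy numbers, ~53/123 on the depth-genotyped path where
V_ST sees continuous noise that F_ST's rounded genotypes do not). A small
intersection on real data — published scans of this design report only a
handful of shared loci out of each top-1% set — indicates much weaker
cross-statistic correlation there: such analyses feed the two statistics
different representations of the data (continuous depth ratios vs called
VCF genotypes from a separate tool), on top of biological and technical
noise this simulation does not model.

## Enrichment

Gene assignment uses any-overlap (≥ 1 shared base, both intervals
inclusive) with an optional flank (default 0 — the annotation window of the
original analysis is unstated). The pathway test is the exact upper-tail
hypergeometric probability P(X ≥ k) for k candidate genes in a pathway of
K background genes, drawing n candidates from a background of N (default
background: all genes in the supplied annotation, configurable).
"Corrected p" is interpreted as Benjamini–Hochberg across the tested
pathways (the web service used by the original analysis offers several
corrections without naming one); significance is q ≤ 0.05.

## Pipeline and reproducibility

`run_all` executes simulate → genotype → sweep → annotate → enrich from one
YAML config, writes every stage table plus `summary.yaml`, and is
byte-reproducible for a fixed seed. `genotype.source: truth` is the QC-free
mode: the sweep ranks the simulated truth copy numbers directly so exactly
`n_loci` loci are ranked and the selection counts are exact functions of
(n_loci, α); `source: depth` runs the full genotyper. All randomness flows
from a single integer seed through separate, numbered child streams for the
cohort and the depth stages.

Problem sizes used by the test suite and the acceptance script: the full
37 × 12,310 cohort (49,240 windows) for selection counts, concordance and
recall; 250–1,500-locus cohorts for unit tests. The complete default-scale
pass (simulate + depth + genotype + sweep) takes on the order of ten
seconds on one CPU.

## Known limitations

* The genotyper is a transparent reimplementation of the read-depth
  genotyping stage, not of any specific caller: no k-mer uniqueness masks,
  no duplicated-window absolute-copy-number correction, no multi-sample
  refinement. Its locus discovery relies on depth aberrance and window
  adjacency only.
* The biallelic encoding behind F_ST is one defensible bridge from CN
  genotypes to an allele-frequency estimator; θ values for multi-allelic
  duplications (CN > 4) saturate.
* X-chromosome dosage is not modelled; X windows, when present, are
  normalized like autosomes.
* Real pathway databases and ortholog mappings are not shipped; enrichment
  counts depend entirely on the supplied GMT.
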