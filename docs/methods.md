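# Methods

## Coordinates and domain types

All intervals are 0-based half-open (BED convention) internally; GTF's
1-based inclusive coordinates are converted on read and write. The TSS of
a minus-strand transcript is `end − 1`, its biological 5′ end. Transcripts
must be stranded (the analyses assume directional libraries); peaks and
coverage may be unstranded. Peak summits default to the interval midpoint
when the input BED carries no summit column, because peak provenance does
not travel with exported BED files.

## The synthetic study

The generator emulates the statistical structure of a hypoxia time-point
experiment in a cell line: a miniature genome (4 × 1.5 Mb), a multi-class
transcript annotation, negative-binomial count matrices across six
conditions (normoxia, hypoxia, hypoxia + siHIF1α / siHIF2α / siBoth /
siControl), HIF-1/HIF-2 binding peaks, and per-base coverage tracks for
RNApol2, H3K4me3, DNase and stranded RNA-seq. Everything is deterministic
under one seed (independent numpy streams per component).

**Planted effects and their defaults.**

| effect | default | note |
|---|---|---|
| class log2FC means | mRNA +0.3, lncRNA +0.3, miRNA +0.2, snRNA −0.5, tRNA −0.4, piwiRNA −0.3 | per-transcript sd 0.5 |
| HIF targets | 40% of up-regulated mRNA/lncRNA; labels 40/40/20% HIF1/HIF2/both | boosted log2FC ~ N(1.8, 0.4), ≥0.8 |
| proximal peaks | summit within ±1.5 kb of the target TSS | one per factor implied by the label |
| distal peaks | 50% (HIF-1) / 70% (HIF-2) of each factor's sites, placed >4 kb from every TSS | the distal fractions are the planted condition |
| novel loci | 37 intergenic + 54 antisense (500–3000 bp) | antisense sit fully inside an mRNA on the opposite strand |
| promoter CpG islands | planted by sequence at 55% of novel TSSs, 350–650 bp upstream | background is AT-rich and CpG-depleted so the island finder is genuinely exercised |
| pausing | Gaussian pause peak at TSS+42 bp (σ 50 bp) + uniform gene-body signal | body ∝ condition expression at HIF targets, pause height constant (pause release); a 15% de-novo minority starts at 2% of full signal in normoxia |
| knockdown | efficiency 0.9; 'both' targets split their induction in log space between factors | siBoth removes both components |
| counts | common NB dispersion 0.01 (BCV 0.1, the usual cell-line scale); base means log-uniform 50–2000, targets and novel ≥ 200 | one library per condition, replicates configurable |

**Conservation of total output.** Relative (per-million) fold-changes
necessarily have abundance-weighted mean ≈ 0, so planted per-transcript
fold-changes are only recoverable if the planted configuration conserves
expected total output between conditions. The generator therefore scales
the abundances of the down-regulated structural classes so that the
expected hypoxic library equals the normoxic one (biologically sensible:
tRNAs and snRNAs are by far the most abundant non-ribosomal RNAs), and
additionally equalizes expected sequencing depth across samples
(`equalize_depth`, on by default). With this in place plain CPM recovers
the planted class-median signs; a median-of-ratios ("effective library
size") normalization is also provided for data without that guarantee.

**What the generator does not model.** Read-level sampling, splicing and
isoform structure, sequencing error, fragment-length effects, mappability,
replicate-level biological variability, tagwise dispersion, and ChIP
background noise (ChIP tracks are smooth kernels; the RNApol2/H3K4me3
tracks carry signal only at pol II transcript classes — mRNA, lncRNA,
miRNA — since structural RNAs are pol I/III transcribed, and planted novel
loci are deliberately excluded from ChIP tracks). Passing recovery tests
therefore demonstrates correctness of the analysis logic under the planted
model, not robustness to the noise structure of real sequencing data.

## Analysis choices

* **Class priority** (rRNA, tRNA, snRNA, miRNA, piwiRNA, mRNA, lncRNA):
  short/structural classes are matched before long classes, mirroring
  sequential mapping against class databases; configurable. Matching is
  same-strand only (directional libraries); class ties break by larger
  overlap, then id.
* **Abundance filter**: a transcript survives iff its mean raw count over
  the two contrast samples meets its class threshold (boundary
  inclusive). Default thresholds: 10 for classes whose median transcript
  length is under 200 nt, 50 otherwise.
* **Fold-change**: CPM with pseudocount 0.5 CPM; log2FC is exactly
  antisymmetric and finite. Quartiles use linear interpolation (stated
  because box-plot conventions differ); whiskers are the full range.
* **Induction ranking** breaks ties by higher mean abundance, then id, so
  downstream selections are fully deterministic.
* **siRNA dependence** (δ = 0.5 log2): HIF1 if siHIF1α ≤ −δ and
  siHIF2α > −δ; HIF2 mirrored; both if both ≤ −δ; none otherwise.
* **Novel assembly** replaces a graph-based assembler with single-exon
  coverage merging (min depth 0.25 signal/bp, gap ≤ 50 bp, length ≥ 200
  bp): the downstream classification, not isoform structure, is what this
  pipeline exercises. The putative TSS is the 5′-most covered base.
  Recovered loci are quantified directly from the stranded coverage of
  the two conditions (pseudocount 0.01 signal/bp), keeping the stage
  independent of any ground truth.
* **CpG islands**: 200-bp sliding windows (step 1) qualifying on
  G+C ≥ 0.5 and CpG obs/exp ≥ 0.6 are merged into maximal regions and
  re-tested as a whole; `obs/exp = CpG·L/(C·G)`.
* **Coding potential**: longest ATG→stop ORF over the three forward
  frames of the oriented transcript sequence, as a fraction of its
  length; < 0.3 is called non-coding. A deliberately simple, auditable
  proxy.
* **Peak assignment**: distance is summit→TSS (the summit best localizes
  binding), signed in transcript orientation, absolute for the 2.5-kb
  threshold; equidistant ties break to the more abundant transcript.
  "Expressed" means survived the abundance filter for the contrast at
  hand.
* **Enrichment**: weighted KS running sum (hits add |score|^p, p = 1,
  normalized by total hit weight; misses subtract 1/(N−Nh)); the null
  permutes gene labels (there are no replicate samples to permute), with
  p = (1 + #{|ES*| ≥ |ES|, same sign})/(1 + n_perm), n_perm = 1000.
* **Travelling ratio**: promoter [TSS−30, TSS+300), body [TSS+300, TES),
  the windows the statistic originates from; transcripts ≤ 330 bp are
  skipped. TR is invariant under global track scaling. Metagene profiles
  normalize per-base densities by 1e9/total signal (an FPKM-like unit) so
  unequal-depth conditions are comparable; raw mode preserves additivity.
* **Group shift**: Δlog2 TR per gene; groups compared with an internal
  Wilcoxon rank-sum (normal approximation with tie correction). Direct
  targets are proximal-assigned transcripts (|distance| ≤ 2.5 kb);
  controls have no site within 10 kb at this genome scale (the full-scale
  analysis used a 1-Mb criterion; this miniature genome cannot hold one).
* **Induction modes** (pseudocount 0.1 signal/bp): pause release if body
  ≥2× and promoter <1.5×; de novo if body ≥2× and promoter ≥2×; anything
  intermediate is reported unchanged. Thresholds are configurable; the
  regimes are qualitative.

## Problem sizes and determinism

The default study (368 public transcripts, 91 novel loci, ~210 peaks,
6 Mb genome) was chosen so that the complete pipeline, including genome
simulation and genome-wide CpG scanning, runs in seconds on one CPU while
keeping ≥30 transcripts per class for the median-sign checks and ~60 HIF
targets for the recovery rates. Rerunning any stage with the same
configuration reproduces byte-identical data outputs; the run manifest
records seed, parameters, and stage list.

## Known limitations

Single-exon assembly cannot separate overlapping same-strand transcripts;
the coding-potential proxy ignores codon usage and homology; the
enrichment null is gene-label permutation, which ignores inter-gene
correlation; distance-based "direct target" assignment is a heuristic for
true regulatory linkage; and the pause-summit offset is resolved only to
the metagene bin width (10 bp).
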