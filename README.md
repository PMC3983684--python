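# hypoxrna

Integrative analysis of the hypoxic coding **and** non-coding transcriptome.

Low oxygen rewires transcription through the hypoxia-inducible factors
(HIF-1α/HIF-2α), and directional RNA-seq shows that the response is not
limited to mRNAs: every RNA class is regulated, with class-specific
direction (mRNA/lncRNA/miRNA globally up, snRNA/tRNA/piwiRNA globally
down), previously non-annotated intergenic and antisense transcripts are
induced, and at direct HIF targets RNA polymerase II is activated largely
by **release of promoter-proximal pausing** rather than de novo
recruitment. This package implements that entire analysis as a tested,
reusable pipeline over small standard-format inputs, together with a
seeded synthetic-data generator that plants all of those effects so each
analysis stage can be validated by parameter recovery.

The pipeline stages (each a library module, a CLI subcommand, and a
numbered driver under `analysis/`):

1. **Class assignment** — features are mapped sequentially against the
   RNA-class annotation by priority (structural classes before long
   classes), ribosomal features removed, low-abundance transcripts dropped
   with class-specific thresholds (higher for classes of longer RNAs).
2. **Expression** — CPM normalization, pseudocounted log2 fold-changes
   `log2((b + c)/(a + c))` for hypoxia/normoxia and each HIF-siRNA vs
   control, class-wise box-whisker summaries, induction ranking, and the
   siRNA dependence matrix (HIF1 / HIF2 / both / none calls at
   |Δlog2| ≥ 0.5).
3. **Novel transcripts** — stranded coverage not explained by same-strand
   annotation is merged (gap ≤ 50 bp, length ≥ 200 bp) into single-exon
   candidates, classified intergenic vs antisense, and annotated with
   promoter CpG islands (Gardiner-Garden–Frommer criteria: ≥200 bp,
   G+C ≥ 0.5, CpG obs/exp ≥ 0.6), an ORF-fraction coding-potential score,
   and sense/antisense co-/counter-regulation.
4. **HIF association** — each binding site is assigned to the closest
   expressed promoter (summit→TSS), distances summarized with the
   fraction beyond 2.5 kb, and a weighted Kolmogorov–Smirnov running-sum
   enrichment score with gene-label permutation null (GSEA-style) tests
   whether HIF-bound transcripts concentrate among the most induced.
5. **Pausing** — TSS-anchored metagene profiles; the travelling ratio
   TR = mean signal density in [TSS−30, TSS+300) / mean density in
   [TSS+300, TES); Δlog2 TR between conditions compared across gene
   groups with an internal tie-corrected Wilcoxon rank-sum; per-gene
   classification into pause release (body ≥2×, promoter <1.5×) vs de
   novo recruitment (both ≥2×).

## Worked example

```sh
hypoxrna run-all --seed 7 --outdir results/study
python analysis/04_novel.py
python analysis/06_pausing.py
```

prints (seed 7 defaults):

```
novel transcripts: 91 = 37 intergenic + 54 antisense
CpG island within 1 kb of the putative promoter: 49 (54%)
low coding potential (<0.3): 90/91
RNApol2 pause summit: +45 bp from the TSS
travelling-ratio shift (hypoxia vs normoxia): direct HIF targets median -1.61 log2,
distal controls +0.00 log2, rank-sum p=2.22e-35
```

That is the full story in miniature: the discovery stage recovers every
planted non-annotated locus and the intergenic/antisense split exactly;
roughly 55% carry a promoter CpG island; essentially all are non-coding;
polymerase pauses just downstream of the TSS (planted at +42 bp, found in
the +40..+50 bin); and hypoxia drops the travelling ratio specifically at
direct HIF targets — the pause-release signature — while transcripts far
from any binding site are untouched.

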