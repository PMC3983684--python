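"""Discovery and classification of non-annotated transcripts.

Contiguous blocks of stranded expression signal not explained by the
same-strand annotation are assembled into single-exon candidates, then
classified as intergenic (overlapping nothing) or antisense (overlapping
an annotated gene on the opposite strand only). Candidates are annotated
with promoter CpG-island proximity, an ORF-based coding-potential score,
hypoxic fold-change, and — for antisense transcripts — whether they are
co- or counter-regulated with their overlapping sense partner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AnnotationSet, CoverageTrack, GenomicInterval, overlap_length

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class NovelTranscript:
    id: str
    interval: GenomicInterval
    category: str                      # intergenic | antisense
    overlapping_sense_id: str | None = None
    cpg_within_1kb: bool | None = None
    coding_potential: float | None = None
    log2fc: float | None = None
    regulation_pair: str | None = None  # co_regulated | counter_regulated | unclassified

    @property
    def tss(self) -> int:
        """Putative TSS: the 5'-most covered base of the candidate."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass(frozen=True)
class CpgIsland:
    interval: GenomicInterval
    gc_fraction: float
    obs_exp_cpg: float


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_unexplained(
    coverage_by_strand: dict[str, CoverageTrack],
    annotation: AnnotationSet,
    min_depth: float = 0.25,
    max_gap: int = 50,
    min_length: int = 200,
) -> list[GenomicInterval]:
    """Merge per-base signal >= min_depth outside the same-strand
    annotation footprint into stranded candidate intervals.

    Blocks separated by gaps <= max_gap are merged; candidates shorter
    than min_length are dropped.
    """
    candidates: list[GenomicInterval] = []
    for strand, track in sorted(coverage_by_strand.items()):
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            mask = arr >= min_depth
            for t in annotation:
                if t.interval.chrom == chrom and t.interval.strand == strand:
                    mask[t.interval.start:t.interval.end] = False
            if not mask.any():
                continue
            padded = np.concatenate(([False], mask, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            starts, ends = edges[::2], edges[1::2]
            merged: list[list[int]] = []
            for s, e in zip(starts, ends):
                if merged and s - merged[-1][1] <= max_gap:
                    merged[-1][1] = e
                else:
                    merged.append([int(s), int(e)])
            for s, e in merged:
                if e - s >= min_length:
                    candidates.append(GenomicInterval(chrom, s, e, strand))
    candidates.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
    return candidates


def classify_novel(
    candidates: list[GenomicInterval], annotation: AnnotationSet
) -> list[NovelTranscript]:
    """Intergenic if a candidate overlaps nothing on either strand;
    antisense if it overlaps annotation on the opposite strand only (the
    partner with the largest overlap is recorded); any same-strand overlap
    disqualifies the candidate (not novel)."""
    out: list[NovelTranscript] = []
    n = 0
    for iv in candidates:
        same = annotation.query(iv, mode="same_strand")
        if same:
            continue
        opposite = annotation.query(iv, mode="opposite_strand")
        n += 1
        if opposite:
            host = max(opposite, key=lambda t: (overlap_length(iv, t.interval), t.id))
            out.append(NovelTranscript(f"candidate_{n:04d}", iv, "antisense", host.id))
        else:
            out.append(NovelTranscript(f"candidate_{n:04d}", iv, "intergenic", None))
    return out


# ---------------------------------------------------------------------------
# CpG islands (Gardiner-Garden & Frommer criteria)
# ---------------------------------------------------------------------------

def _island_stats(seq_codes_c: np.ndarray, seq_codes_g: np.ndarray,
                  start: int, end: int) -> tuple[float, float]:
    c = int(seq_codes_c[start:end].sum())
    g = int(seq_codes_g[start:end].sum())
    cpg = int((seq_codes_c[start:end - 1] & seq_codes_g[start + 1:end]).sum())
    length = end - start
    gc = (c + g) / length
    oe = (cpg * length) / (c * g) if c > 0 and g > 0 else 0.0
    return gc, oe


def find_cpg_islands(
    sequence: str,
    min_length: int = 200,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
    window: int = 200,
    step: int = 1,
    chrom: str = "chr",
) -> list[CpgIsland]:
    """Sliding-window CpG island finder.

    Windows of ``window`` bp qualifying on G+C fraction and observed/
    expected CpG ratio (obs/exp = CpG count x length / (C count x G
    count)) are merged into maximal runs, re-tested as a whole, and
    reported when they still satisfy all thresholds and min_length.
    """
    seq = sequence.upper()
    if len(seq) < window:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int32)
    is_g = (arr == ord("G")).astype(np.int32)
    cpg = np.zeros_like(is_c)
    cpg[:-1] = is_c[:-1] & is_g[1:]

    def roll(x: np.ndarray, w: int) -> np.ndarray:
        cs = np.concatenate(([0], np.cumsum(x)))
        return cs[w:] - cs[:-w]

    c_w = roll(is_c, window)
    g_w = roll(is_g, window)
    cpg_w = roll(cpg, window)[: c_w.size]  # CpG straddling the window end counts to its start window
    gc_ok = (c_w + g_w) / window >= gc_min
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((c_w > 0) & (g_w > 0), cpg_w * window / (c_w * g_w), 0.0)
    qual = np.flatnonzero(gc_ok & (oe >= oe_min))[::step]
    if qual.size == 0:
        return []
    # merge qualifying windows into maximal regions
    regions: list[list[int]] = []
    for i in qual:
        s, e = int(i), int(i) + window
        if regions and s <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], e)
        else:
            regions.append([s, e])
    islands: list[CpgIsland] = []
    for s, e in regions:
        gc, oe_whole = _island_stats(is_c, is_g, s, e)
        if e - s >= min_length and gc >= gc_min and oe_whole >= oe_min:
            islands.append(CpgIsland(GenomicInterval(chrom, s, e, "."), gc, oe_whole))
    return islands


def promoter_cpg_flag(
    novel: NovelTranscript, islands: list[CpgIsland], max_distance: int = 1000
) -> bool:
    """True iff any island lies within ``max_distance`` bp (either
    direction) of the putative TSS."""
    tss = novel.tss
    for isl in islands:
        iv = isl.interval
        if iv.chrom != novel.interval.chrom:
            continue
        if iv.start <= tss < iv.end:
            return True
        dist = iv.start - tss if iv.start > tss else tss - (iv.end - 1)
        if dist <= max_distance:
            return True
    return False


# ---------------------------------------------------------------------------
# Coding potential
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def transcript_sequence(genome: dict[str, str], iv: GenomicInterval) -> str:
    seq = genome[iv.chrom][iv.start:iv.end]
    return reverse_complement(seq) if iv.strand == "-" else seq


def coding_potential(sequence: str) -> float:
    """Longest ORF (ATG..stop, any of the 3 forward frames) as a fraction
    of transcript length; low values indicate non-coding RNAs."""
    seq = sequence.upper()
    if len(seq) < 60:
        raise ValueError("sequence shorter than 60 nt")
    best = 0
    for frame in range(3):
        orf_start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if orf_start is None and codon == "ATG":
                orf_start = i
            elif orf_start is not None and codon in STOP_CODONS:
                best = max(best, i + 3 - orf_start)
                orf_start = None
    return best / len(seq)


# ---------------------------------------------------------------------------
# Sense/antisense co-regulation
# ---------------------------------------------------------------------------

def pair_regulation(novel_lfc: float, sense_lfc: float, delta: float = 0.5) -> str:
    """co_regulated when both |log2FC| >= delta with the same sign,
    counter_regulated when signs oppose, else unclassified."""
    if abs(novel_lfc) >= delta and abs(sense_lfc) >= delta:
        return "co_regulated" if novel_lfc * sense_lfc > 0 else "counter_regulated"
    return "unclassified"
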