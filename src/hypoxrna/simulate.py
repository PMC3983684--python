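"""Seeded generator for a miniature hypoxic-transcriptome study.

Produces a small genome, a multi-class transcript annotation, condition
count matrices (normoxia / hypoxia / HIF-siRNA knockdowns), HIF-1/HIF-2
binding peaks, and per-base coverage tracks, all with planted, recoverable
effects recorded in a :class:`GroundTruth` object:

* class-specific hypoxic regulation (mRNA/lncRNA/miRNA globally up,
  snRNA/tRNA/piwiRNA globally down);
* a subset of up-regulated mRNA/lncRNA transcripts that are HIF-1- and/or
  HIF-2-dependent, each with a binding peak within 2.5 kb of its TSS, plus
  distal peaks tuned so that 50% of HIF-1 and 70% of HIF-2 sites lie
  further than 2.5 kb from any expressed promoter;
* non-annotated intergenic and antisense loci (default 37 + 54 = 91), a
  55% subset of which get a CpG island planted by sequence composition
  within 1 kb of the putative promoter;
* promoter-paused RNA polymerase II whose summit sits 42 bp downstream of
  the TSS and whose gene-body signal rises in hypoxia at direct HIF
  targets at constant promoter peak (pause release), except for a minority
  of de-novo-recruitment genes where promoter and body both rise from
  near zero;
* DNase promoter accessibility identical between conditions.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    AnnotationSet,
    CountMatrix,
    CoverageTrack,
    GenomicInterval,
    Peak,
    TranscriptRecord,
)
from intervaltree import IntervalTree
import pandas as pd

SAMPLES = (
    "normoxia",
    "hypoxia",
    "hypoxia_siHIF1a",
    "hypoxia_siHIF2a",
    "hypoxia_siBoth",
    "hypoxia_siControl",
)

_EDGE_MARGIN = 3000  # bp kept free at chromosome ends (metagene windows, island planting)
_PLACE_MARGIN = 200  # bp kept free around each placed public transcript

POL2_CLASSES = ("mRNA", "lncRNA", "miRNA", "novel")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    seed: int = 7
    n_chroms: int = 4
    chrom_length: int = 1_500_000

    class_counts: dict = field(default_factory=lambda: {
        "mRNA": 150, "lncRNA": 60, "miRNA": 40, "snRNA": 40,
        "tRNA": 40, "piwiRNA": 30, "rRNA": 8,
    })
    class_length_ranges: dict = field(default_factory=lambda: {
        "mRNA": (2000, 20000), "lncRNA": (500, 10000), "miRNA": (60, 120),
        "snRNA": (70, 300), "tRNA": (70, 300), "piwiRNA": (70, 300),
        "rRNA": (1500, 5000), "novel": (500, 3000),
    })
    class_effect: dict = field(default_factory=lambda: {
        "mRNA": 0.3, "lncRNA": 0.3, "miRNA": 0.2, "snRNA": -0.5,
        "tRNA": -0.4, "piwiRNA": -0.3, "rRNA": 0.0,
    })
    effect_sd: float = 0.5

    # HIF dependence
    frac_hif_targets: float = 0.4     # of up-regulated mRNA/lncRNA
    hif1_frac: float = 0.4            # label split among targets; remainder 'both'
    hif2_frac: float = 0.4
    target_lfc_mean: float = 1.8
    target_lfc_sd: float = 0.4
    target_lfc_min: float = 0.8
    hif1_distal_frac: float = 0.5     # planted fraction of peaks >2.5 kb from promoters
    hif2_distal_frac: float = 0.7
    proximal_max_offset: int = 1500   # summit placed within this of the target TSS
    distal_min_tss_distance: int = 4000

    # counts
    dispersion: float = 0.01          # common NB dispersion (BCV 0.1, cell-line scale)
    base_mean_range: tuple = (50.0, 2000.0)
    target_base_mean_min: float = 200.0
    knockdown_efficiency: float = 0.9
    n_replicates: int = 1
    # Planted fold-changes are defined on the relative (per-million) scale
    # that sequencing measures: expected depth is equalized across samples
    # so a faithful CPM analysis recovers them without composition bias.
    equalize_depth: bool = True

    # coverage
    pause_offset: int = 42
    pause_width: float = 50.0
    pause_height: float = 20.0
    body_height: float = 0.5
    de_novo_frac: float = 0.15
    de_novo_residual: float = 0.02
    h3k4me3_shift: int = 150
    h3k4me3_width: float = 150.0
    h3k4me3_height: float = 10.0
    dnase_width: float = 100.0
    dnase_height: float = 15.0

    # novel loci
    n_novel_intergenic: int = 37
    n_novel_antisense: int = 54
    novel_lfc_mean: float = 1.5
    novel_lfc_sd: float = 0.8
    cpg_frac: float = 0.55
    cpg_island_length: int = 300
    cpg_island_offset: int = 650      # island end this far upstream of the novel TSS

    def __post_init__(self) -> None:
        for name in ("frac_hif_targets", "hif1_frac", "hif2_frac", "cpg_frac",
                     "hif1_distal_frac", "hif2_distal_frac", "de_novo_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.pause_offset < 0:
            raise ValueError("pause_offset must be >= 0")
        if self.hif1_frac + self.hif2_frac > 1.0:
            raise ValueError("hif1_frac + hif2_frac must not exceed 1")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        return {name: self.chrom_length for name in self.chrom_names()}

    @classmethod
    def tiny(cls, seed: int = 0) -> "SimulationConfig":
        """A reduced-scale configuration for fast smoke tests."""
        return cls(
            seed=seed,
            n_chroms=2,
            chrom_length=250_000,
            class_counts={"mRNA": 25, "lncRNA": 10, "miRNA": 8, "snRNA": 8,
                          "tRNA": 8, "piwiRNA": 6, "rRNA": 2},
            class_length_ranges={
                "mRNA": (1500, 6000), "lncRNA": (500, 3000), "miRNA": (60, 120),
                "snRNA": (70, 300), "tRNA": (70, 300), "piwiRNA": (70, 300),
                "rRNA": (1000, 2000), "novel": (400, 1500),
            },
            n_novel_intergenic=5,
            n_novel_antisense=4,
        )


@dataclass
class GroundTruth:
    """Planted truth: what a faithful analysis should recover."""

    true_lfc: dict                      # transcript id -> planted log2 fold-change
    hif_label: dict                     # transcript id -> none|HIF1|HIF2|both
    base_mean: dict                     # transcript id -> normoxic NB mean
    novel_transcripts: list             # TranscriptRecord (absent from public annotation)
    novel_intergenic_ids: list
    novel_antisense_ids: list
    antisense_host: dict                # novel id -> overlapped sense mRNA id
    cpg_flagged_ids: set                # novel ids with a planted promoter CpG island
    de_novo_ids: set                    # HIF targets recruited de novo (not pause release)
    pause_offset: int
    peak_target: dict = field(default_factory=dict)  # peak id -> intended transcript id or None

    @property
    def hif_target_ids(self) -> list:
        return sorted(t for t, lab in self.hif_label.items() if lab != "none")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig) -> tuple[AnnotationSet, GroundTruth]:
    """Place the public annotation and the planted novel loci.

    Public transcripts are non-overlapping (with a safety margin) on either
    strand; antisense novel loci sit fully inside a sense mRNA on the
    opposite strand; intergenic novel loci overlap nothing.
    """
    rng = _rng(config, 1)
    chroms = config.chrom_names()
    occupied = {c: IntervalTree() for c in chroms}

    def try_place(length: int, max_tries: int = 500) -> GenomicInterval | None:
        for _ in range(max_tries):
            chrom = chroms[rng.integers(len(chroms))]
            lo = _EDGE_MARGIN
            hi = config.chrom_length - _EDGE_MARGIN - length
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            if not occupied[chrom].overlap(start - _PLACE_MARGIN, start + length + _PLACE_MARGIN):
                strand = "+" if rng.random() < 0.5 else "-"
                occupied[chrom].addi(start, start + length)
                return GenomicInterval(chrom, start, start + length, strand)
        return None

    # draw (class, length) for public transcripts and place longest first
    todo: list[tuple[str, int]] = []
    for cls, n in config.class_counts.items():
        lo, hi = config.class_length_ranges[cls]
        for i in range(n):
            todo.append((cls, int(rng.integers(lo, hi + 1))))
    order = sorted(range(len(todo)), key=lambda i: -todo[i][1])
    placed: dict[int, GenomicInterval] = {}
    for i in order:
        iv = try_place(todo[i][1])
        if iv is None:
            raise RuntimeError(
                "could not place requested transcripts; increase chrom_length or n_chroms"
            )
        placed[i] = iv
    counters: dict[str, int] = {}
    public: list[TranscriptRecord] = []
    for i, (cls, _) in enumerate(todo):
        counters[cls] = counters.get(cls, 0) + 1
        public.append(TranscriptRecord(f"{cls}_{counters[cls]:04d}", placed[i], cls))
    annotation = AnnotationSet(public)

    # planted effect sizes
    true_lfc: dict[str, float] = {}
    for t in public:
        true_lfc[t.id] = float(rng.normal(config.class_effect[t.rna_class], config.effect_sd))

    # HIF targets among up-regulated mRNA / lncRNA
    up = [t.id for t in public if t.rna_class in ("mRNA", "lncRNA") and true_lfc[t.id] > 0]
    n_targets = int(round(config.frac_hif_targets * len(up)))
    target_ids = sorted(rng.choice(up, size=n_targets, replace=False).tolist())
    hif_label = {t.id: "none" for t in public}
    n1 = int(round(config.hif1_frac * n_targets))
    n2 = int(round(config.hif2_frac * n_targets))
    shuffled = list(rng.permutation(target_ids))
    for tid in shuffled[:n1]:
        hif_label[tid] = "HIF1"
    for tid in shuffled[n1:n1 + n2]:
        hif_label[tid] = "HIF2"
    for tid in shuffled[n1 + n2:]:
        hif_label[tid] = "both"
    for tid in target_ids:
        lfc = rng.normal(config.target_lfc_mean, config.target_lfc_sd)
        true_lfc[tid] = float(max(lfc, config.target_lfc_min))
    n_denovo = int(round(config.de_novo_frac * n_targets))
    de_novo_ids = set(rng.choice(target_ids, size=n_denovo, replace=False).tolist()) if n_denovo else set()

    # base means (log-uniform); targets kept clearly expressed
    lo, hi = config.base_mean_range
    base_mean = {}
    for t in public:
        m = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if hif_label[t.id] != "none":
            m = max(m, config.target_base_mean_min)
        base_mean[t.id] = m

    # novel loci: intergenic (overlap nothing) + antisense (inside an mRNA, opposite strand)
    novel: list[TranscriptRecord] = []
    nlo, nhi = config.class_length_ranges["novel"]
    intergenic_ids, antisense_ids = [], []
    antisense_host: dict[str, str] = {}
    for i in range(config.n_novel_intergenic):
        iv = try_place(int(rng.integers(nlo, nhi + 1)))
        if iv is None:
            raise RuntimeError("could not place intergenic novel loci")
        tid = f"novel_ig_{i + 1:03d}"
        novel.append(TranscriptRecord(tid, iv, "novel"))
        intergenic_ids.append(tid)
    hosts = [t for t in public if t.rna_class == "mRNA" and t.length >= nlo + 400]
    if len(hosts) < config.n_novel_antisense:
        raise RuntimeError("not enough mRNA hosts for antisense novel loci")
    host_pick = rng.choice(len(hosts), size=config.n_novel_antisense, replace=False)
    for i, hidx in enumerate(host_pick):
        host = hosts[int(hidx)]
        length = int(min(rng.integers(nlo, nhi + 1), host.length - 200))
        lo_s = host.interval.start + 100
        hi_s = host.interval.end - 100 - length
        start = int(rng.integers(lo_s, hi_s + 1))
        strand = "-" if host.interval.strand == "+" else "+"
        tid = f"novel_as_{i + 1:03d}"
        novel.append(TranscriptRecord(
            tid, GenomicInterval(host.interval.chrom, start, start + length, strand), "novel"))
        antisense_ids.append(tid)
        antisense_host[tid] = host.id
    for t in novel:
        true_lfc[t.id] = float(rng.normal(config.novel_lfc_mean, config.novel_lfc_sd))
        hif_label[t.id] = "none"
        base_mean[t.id] = max(
            float(np.exp(rng.uniform(np.log(lo), np.log(hi)))), config.target_base_mean_min)

    # Conserve total transcriptional output between conditions: scale the
    # abundances of the down-regulated structural classes (in cells these
    # are by far the most abundant non-ribosomal RNAs) so that the expected
    # hypoxic library equals the normoxic one. Planted fold-changes are
    # then recoverable on the relative (per-million) scale that sequencing
    # measures, with no composition bias.
    down_classes = {c for c, e in config.class_effect.items() if e < 0}
    all_records = public + novel
    s_up_n = sum(base_mean[t.id] for t in all_records
                 if t.rna_class not in down_classes)
    s_up_h = sum(base_mean[t.id] * 2.0 ** true_lfc[t.id] for t in all_records
                 if t.rna_class not in down_classes)
    s_dn_n = sum(base_mean[t.id] for t in all_records if t.rna_class in down_classes)
    s_dn_h = sum(base_mean[t.id] * 2.0 ** true_lfc[t.id] for t in all_records
                 if t.rna_class in down_classes)
    if s_dn_n > s_dn_h and s_up_h > s_up_n:
        g = (s_up_h - s_up_n) / (s_dn_n - s_dn_h)
        for t in all_records:
            if t.rna_class in down_classes:
                base_mean[t.id] *= g

    novel_ids = intergenic_ids + antisense_ids
    n_flag = int(round(config.cpg_frac * len(novel_ids)))
    cpg_flagged = set(rng.choice(novel_ids, size=n_flag, replace=False).tolist()) if n_flag else set()

    truth = GroundTruth(
        true_lfc=true_lfc,
        hif_label=hif_label,
        base_mean=base_mean,
        novel_transcripts=novel,
        novel_intergenic_ids=intergenic_ids,
        novel_antisense_ids=antisense_ids,
        antisense_host=antisense_host,
        cpg_flagged_ids=cpg_flagged,
        de_novo_ids=de_novo_ids,
        pause_offset=config.pause_offset,
    )
    return annotation, truth


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# AT-rich, CpG-depleted background so that CpG islands are a sequence signal
_BG_P = (0.32, 0.18, 0.18, 0.32)
_ISLAND_P = (0.17, 0.33, 0.33, 0.17)
_CPG_DEPLETION = 0.85  # fraction of background CpG dinucleotides disrupted


def simulate_genome(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[dict[str, str], dict[str, int]]:
    """Random CpG-depleted genome with CpG islands planted upstream of the
    flagged novel-transcript TSSs. Returns (sequences, chrom_sizes)."""
    if truth is None:
        _, truth = simulate_annotation(config)
    rng = _rng(config, 2)
    codes: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names():
        arr = rng.choice(4, size=config.chrom_length, p=_BG_P).astype(np.uint8)
        cg = np.flatnonzero((arr[:-1] == 1) & (arr[1:] == 2))
        hit = cg[rng.random(cg.size) < _CPG_DEPLETION]
        arr[hit + 1] = np.where(rng.random(hit.size) < 0.5, 0, 3)
        codes[chrom] = arr
    by_id = {t.id: t for t in truth.novel_transcripts}
    for tid in sorted(truth.cpg_flagged_ids):
        t = by_id[tid]
        L = config.cpg_island_length
        if t.interval.strand == "+":
            start = t.tss - config.cpg_island_offset
        else:
            start = t.tss + config.cpg_island_offset - L
        start = max(0, min(start, config.chrom_length - L))
        island = rng.choice(4, size=L, p=_ISLAND_P).astype(np.uint8)
        codes[t.interval.chrom][start:start + L] = island
    seqs = {c: _BASES[a].tobytes().decode("ascii") for c, a in codes.items()}
    return seqs, config.chrom_sizes()


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    config: SimulationConfig, annotation: AnnotationSet, truth: GroundTruth
) -> list[Peak]:
    """HIF-1/HIF-2 peaks: one proximal peak (summit within 2.5 kb of the
    TSS) per dependent transcript, plus distal peaks far from every TSS so
    the planted distal fractions are exact."""
    rng = _rng(config, 3)
    all_tss: dict[str, list[int]] = {c: [] for c in config.chrom_names()}
    for t in list(annotation) + truth.novel_transcripts:
        all_tss[t.interval.chrom].append(t.tss)
    tss_arr = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in all_tss.items()}

    peaks: list[Peak] = []
    counter = {"HIF1": 0, "HIF2": 0}

    def add_peak(factor: str, summit: int, chrom: str, target: str | None) -> None:
        counter[factor] += 1
        pid = f"{factor}_peak_{counter[factor]:04d}"
        half = 250
        start = max(0, summit - half)
        end = min(config.chrom_length, summit + half)
        peaks.append(Peak(pid, GenomicInterval(chrom, start, end, "."), summit, factor))
        truth.peak_target[pid] = target

    n_prox = {"HIF1": 0, "HIF2": 0}
    for tid in truth.hif_target_ids:
        t = annotation[tid]
        label = truth.hif_label[tid]
        for factor in ("HIF1", "HIF2"):
            if label in (factor, "both"):
                off = int(rng.integers(-config.proximal_max_offset,
                                       config.proximal_max_offset + 1))
                summit = int(np.clip(t.tss + off, 300, config.chrom_length - 300))
                add_peak(factor, summit, t.interval.chrom, tid)
                n_prox[factor] += 1

    chroms = config.chrom_names()
    for factor, frac in (("HIF1", config.hif1_distal_frac), ("HIF2", config.hif2_distal_frac)):
        if frac >= 1.0:
            raise ValueError("distal fraction must be < 1")
        n_distal = int(round(n_prox[factor] * frac / (1.0 - frac)))
        made = 0
        tries = 0
        while made < n_distal:
            tries += 1
            if tries > 100_000:
                raise RuntimeError("could not place distal peaks away from all TSSs")
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(_EDGE_MARGIN, config.chrom_length - _EDGE_MARGIN))
            arr = tss_arr[chrom]
            i = np.searchsorted(arr, pos)
            d = min(
                abs(pos - arr[i - 1]) if i > 0 else np.inf,
                abs(arr[i] - pos) if i < arr.size else np.inf,
            )
            if d > config.distal_min_tss_distance:
                add_peak(factor, pos, chrom, None)
                made += 1
    return peaks


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _condition_means(config: SimulationConfig, truth: GroundTruth, tid: str) -> dict[str, float]:
    base = truth.base_mean[tid]
    lfc = truth.true_lfc[tid]
    label = truth.hif_label[tid]
    ke = config.knockdown_efficiency
    F = 2.0 ** lfc
    hyp = base * F

    def knocked(fold: float) -> float:
        # residual induction after knockdown of the factor driving `fold`
        return 1.0 + (fold - 1.0) * (1.0 - ke)

    if label == "HIF1":
        si1, si2, siB = base * knocked(F), hyp, base * knocked(F)
    elif label == "HIF2":
        si1, si2, siB = hyp, base * knocked(F), base * knocked(F)
    elif label == "both":
        Fh = math.sqrt(F) if F > 0 else 0.0  # induction split equally between factors
        si1 = base * knocked(Fh) * Fh
        si2 = base * Fh * knocked(Fh)
        siB = base * knocked(Fh) * knocked(Fh)
    else:
        si1 = si2 = siB = hyp
    return {
        "normoxia": base,
        "hypoxia": hyp,
        "hypoxia_siHIF1a": si1,
        "hypoxia_siHIF2a": si2,
        "hypoxia_siBoth": siB,
        "hypoxia_siControl": hyp,
    }


def _depth_scales(config: SimulationConfig, annotation: AnnotationSet,
                  truth: GroundTruth) -> dict[str, float]:
    """Per-sample factors equalizing expected totals to the normoxic depth
    (identity when equalize_depth is off)."""
    if not config.equalize_depth:
        return {s: 1.0 for s in SAMPLES}
    ids = [t.id for t in annotation] + [t.id for t in truth.novel_transcripts]
    totals = {s: 0.0 for s in SAMPLES}
    for tid in ids:
        for s, mu in _condition_means(config, truth, tid).items():
            totals[s] += mu
    return {s: totals["normoxia"] / totals[s] for s in SAMPLES}


def simulate_counts(
    config: SimulationConfig, annotation: AnnotationSet, truth: GroundTruth
) -> CountMatrix:
    """Negative-binomial counts (common dispersion) for all transcripts,
    public and novel, across the six conditions."""
    rng = _rng(config, 4)
    ids = [t.id for t in annotation] + [t.id for t in truth.novel_transcripts]
    scales = _depth_scales(config, annotation, truth)
    cols = []
    for s in SAMPLES:
        if config.n_replicates == 1:
            cols.append(s)
        else:
            cols.extend(f"{s}_rep{r + 1}" for r in range(config.n_replicates))
    mat = np.zeros((len(ids), len(cols)), dtype=np.int64)
    disp = config.dispersion
    for i, tid in enumerate(ids):
        means = _condition_means(config, truth, tid)
        for j, col in enumerate(cols):
            sample = col.rsplit("_rep", 1)[0] if config.n_replicates > 1 else col
            mu = means[sample] * scales[sample]
            if disp < 1e-9:
                mat[i, j] = rng.poisson(mu)
            else:
                n = 1.0 / disp
                mat[i, j] = rng.negative_binomial(n, n / (n + mu))
    return CountMatrix(pd.DataFrame(mat, index=ids, columns=cols))


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def _add_gaussian(arr: np.ndarray, centre: int, sd: float, amp: float) -> None:
    lo = max(0, int(centre - 4 * sd))
    hi = min(arr.size, int(centre + 4 * sd) + 1)
    if hi <= lo:
        return
    x = np.arange(lo, hi)
    arr[lo:hi] += amp * np.exp(-0.5 * ((x - centre) / sd) ** 2)


def simulate_coverage(
    config: SimulationConfig,
    annotation: AnnotationSet,
    truth: GroundTruth,
    condition: str,
    mark: str = "RNApol2",
) -> CoverageTrack:
    """ChIP coverage for one mark in one condition over the public annotation.

    RNApol2: a Gaussian pause peak at TSS + pause_offset (strand-aware) plus
    uniform gene-body signal. In hypoxia the body rises at HIF targets while
    the pause peak stays constant (pause release); de-novo-recruitment
    genes start from ``de_novo_residual`` of full signal in normoxia.
    H3K4me3 mirrors RNApol2 with a broader, downstream-shifted kernel.
    DNase is a fixed promoter kernel, identical between conditions.
    """
    if condition not in ("normoxia", "hypoxia"):
        raise ValueError(f"condition must be normoxia or hypoxia, got {condition!r}")
    if mark not in ("RNApol2", "H3K4me3", "DNase"):
        raise ValueError(f"unknown mark {mark!r}")
    values = {c: np.zeros(config.chrom_length, dtype=np.float32)
              for c in config.chrom_names()}
    for t in annotation:
        # RNApol2 and its associated promoter methylation mark only pol II
        # transcript classes; structural RNAs are pol I/III transcribed
        if mark in ("RNApol2", "H3K4me3") and t.rna_class not in POL2_CLASSES:
            continue
        arr = values[t.interval.chrom]
        e_norm = truth.base_mean[t.id] / 100.0
        label = truth.hif_label[t.id]
        fold = 2.0 ** truth.true_lfc[t.id] if label != "none" else 1.0
        scale = 1.0
        if t.id in truth.de_novo_ids and condition == "normoxia":
            scale = config.de_novo_residual
        e_body = e_norm * (fold if condition == "hypoxia" else 1.0) * scale
        direction = 1 if t.interval.strand == "+" else -1
        if mark == "RNApol2":
            pause_centre = t.tss + direction * config.pause_offset
            _add_gaussian(arr, pause_centre, config.pause_width,
                          config.pause_height * e_norm * scale)
            arr[t.interval.start:t.interval.end] += config.body_height * e_body
        elif mark == "H3K4me3":
            centre = t.tss + direction * config.h3k4me3_shift
            _add_gaussian(arr, centre, config.h3k4me3_width,
                          config.h3k4me3_height * e_norm * scale)
        elif mark == "DNase":
            _add_gaussian(arr, t.tss, config.dnase_width,
                          config.dnase_height * e_norm)
    return CoverageTrack(mark=mark, condition=condition, values=values)


def simulate_rnaseq_coverage(
    config: SimulationConfig,
    annotation: AnnotationSet,
    truth: GroundTruth,
    condition: str,
    strand: str,
) -> CoverageTrack:
    """Stranded RNA-seq-like coverage: uniform signal over each transcript
    (public and novel) proportional to its expected expression."""
    if strand not in "+-":
        raise ValueError("strand must be + or -")
    values = {c: np.zeros(config.chrom_length, dtype=np.float32)
              for c in config.chrom_names()}
    scale = _depth_scales(config, annotation, truth)[condition]
    for t in list(annotation) + truth.novel_transcripts:
        if t.interval.strand != strand:
            continue
        mu = _condition_means(config, truth, t.id)[condition] * scale
        values[t.interval.chrom][t.interval.start:t.interval.end] += mu / 100.0
    return CoverageTrack(mark="RNAseq", condition=condition, values=values, strand=strand)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    annotation: AnnotationSet
    truth: GroundTruth
    genome: dict
    chrom_sizes: dict
    counts: CountMatrix
    peaks: list
    tracks: dict  # (mark, condition) -> CoverageTrack; RNAseq keyed (mark, condition, strand)


def run_simulation(config: SimulationConfig, with_genome: bool = True) -> SimulationResult:
    """Generate the full synthetic study deterministically from the seed."""
    annotation, truth = simulate_annotation(config)
    genome, chrom_sizes = (
        simulate_genome(config, truth) if with_genome else ({}, config.chrom_sizes())
    )
    peaks = simulate_peaks(config, annotation, truth)
    counts = simulate_counts(config, annotation, truth)
    tracks: dict = {}
    for mark in ("RNApol2", "H3K4me3", "DNase"):
        for cond in ("normoxia", "hypoxia"):
            tracks[(mark, cond)] = simulate_coverage(config, annotation, truth, cond, mark)
    for cond in ("normoxia", "hypoxia"):
        for strand in "+-":
            tracks[("RNAseq", cond, strand)] = simulate_rnaseq_coverage(
                config, annotation, truth, cond, strand)
    return SimulationResult(config, annotation, truth, genome, chrom_sizes,
                            counts, peaks, tracks)
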