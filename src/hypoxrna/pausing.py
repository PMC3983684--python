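"""RNA polymerase II promoter-pausing analysis.

Metagene profiles around the TSS, the travelling ratio (promoter-proximal
signal density over gene-body density; high values indicate pausing), its
shift between normoxia and hypoxia for direct HIF targets versus distal
controls, and classification of hypoxic induction as release of
promoter-paused polymerase versus de novo recruitment.

Promoter/body windows follow the convention the travelling ratio
originates from: promoter = TSS-30..TSS+300, body = TSS+300..TES, both
strand-aware.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import AnnotationSet, CoverageTrack, TranscriptRecord

PROMOTER_WINDOW = (-30, 300)
BODY_START = 300


def select_top_induced(ranked: pd.DataFrame, n: int = 100) -> list[str]:
    """The n transcripts most upregulated by hypoxia (any class), as a
    prefix of the induction ranking."""
    if len(ranked) < n:
        raise ValueError(f"only {len(ranked)} ranked transcripts, need {n}")
    return list(ranked.index[:n])


def _oriented_window(arr: np.ndarray, tss: int, strand: str, up: int, down: int) -> np.ndarray | None:
    """Signal from `up` to `down` bp relative to the TSS, oriented 5'->3'.

    Returns None when the window falls off the chromosome.
    """
    if strand == "+":
        lo, hi = tss + up, tss + down
        if lo < 0 or hi > arr.size:
            return None
        return arr[lo:hi]
    lo, hi = tss - down + 1, tss - up + 1
    if lo < 0 or hi > arr.size:
        return None
    return arr[lo:hi][::-1]


@dataclass
class MetageneProfile:
    mark: str
    condition: str
    window: tuple
    bin_size: int
    values: np.ndarray       # mean signal per bin across genes
    n_genes: int
    normalized: bool

    def bin_centres(self) -> np.ndarray:
        up, down = self.window
        return np.arange(up, down, self.bin_size) + self.bin_size / 2.0


def metagene(
    track: CoverageTrack,
    genes: list[TranscriptRecord],
    window: tuple = (-2000, 2000),
    bin_size: int = 10,
    normalize: bool = True,
) -> MetageneProfile:
    """Mean signal per bin around the TSS, oriented 5'->3' and averaged
    over genes.

    With ``normalize``, per-base densities are scaled by 1e9 / total track
    signal (an FPKM-like unit) so conditions of different depth are
    comparable; raw mode preserves additivity for linearity checks.
    """
    if not genes:
        raise ValueError("empty gene list")
    up, down = window
    span = down - up
    if span % bin_size:
        raise ValueError("window span must be a multiple of bin_size")
    nbins = span // bin_size
    acc = np.zeros(nbins, dtype=np.float64)
    used = 0
    for g in genes:
        arr = track.values.get(g.interval.chrom)
        if arr is None:
            continue
        w = _oriented_window(arr, g.tss, g.interval.strand, up, down)
        if w is None:
            warnings.warn(f"gene {g.id} too close to chromosome edge; skipped")
            continue
        acc += w.reshape(nbins, bin_size).mean(axis=1)
        used += 1
    if used == 0:
        raise ValueError("no usable genes for metagene profile")
    values = acc / used
    if normalize:
        total = track.total_signal
        if total <= 0:
            raise ValueError("cannot normalize a zero-signal track")
        values = values * 1e9 / total
    return MetageneProfile(track.mark, track.condition, window, bin_size,
                           values, used, normalize)


def pause_summit_offset(profile: MetageneProfile) -> float:
    """Offset (bp from TSS) of the bin centre with maximal signal; ties go
    to the smallest offset. Errors on a flat profile."""
    v = profile.values
    if np.allclose(v, v[0]):
        raise ValueError("flat profile has no summit")
    centres = profile.bin_centres()
    best = np.flatnonzero(v == v.max())
    return float(centres[best[np.argmin(np.abs(centres[best]))]])


@dataclass
class TravellingRatioResult:
    transcript_id: str
    condition: str
    promoter_density: float
    body_density: float
    tr: float | None  # None when the body has no signal


def travelling_ratio(
    track: CoverageTrack,
    transcripts: list[TranscriptRecord],
    promoter_window: tuple = PROMOTER_WINDOW,
    body_start: int = BODY_START,
) -> dict[str, TravellingRatioResult]:
    """Promoter-proximal over gene-body signal density per transcript.

    Transcripts whose body window (TSS+body_start..TES) would be empty are
    skipped with a warning.
    """
    out: dict[str, TravellingRatioResult] = {}
    for t in transcripts:
        if t.length <= body_start + (-promoter_window[0]):
            warnings.warn(f"transcript {t.id} too short for travelling ratio; skipped")
            continue
        arr = track.values[t.interval.chrom]
        prom = _oriented_window(arr, t.tss, t.interval.strand,
                                promoter_window[0], promoter_window[1])
        body = _oriented_window(arr, t.tss, t.interval.strand, body_start, t.length)
        if prom is None or body is None:
            warnings.warn(f"transcript {t.id} too close to chromosome edge; skipped")
            continue
        p, b = float(prom.mean()), float(body.mean())
        out[t.id] = TravellingRatioResult(
            t.id, track.condition, p, b, (p / b) if b > 0 else None)
    return out


# ---------------------------------------------------------------------------
# Rank-sum statistic (implemented internally; normal approximation with
# tie correction)
# ---------------------------------------------------------------------------

def rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Wilcoxon rank-sum: returns (W, z, two-sided p).

    W is the sum of ranks of ``x`` in the pooled sample (average ranks for
    ties); z uses the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    ranks[order] = np.arange(1, pooled.size + 1)
    # average ranks over ties
    vals, inv, counts = np.unique(pooled, return_inverse=True, return_counts=True)
    sums = np.zeros(vals.size)
    np.add.at(sums, inv, ranks)
    ranks = sums[inv] / counts[inv]
    W = float(ranks[:n1].sum())
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    tie_term = float(((counts ** 3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return W, 0.0, 1.0
    z = (W - mean) / math.sqrt(var)
    p = float(2.0 * 0.5 * math.erfc(abs(z) / math.sqrt(2.0)))
    return W, float(z), min(p, 1.0)


def tr_shift(
    tr_normoxia: dict[str, TravellingRatioResult],
    tr_hypoxia: dict[str, TravellingRatioResult],
    gene_groups: dict[str, list[str]],
) -> dict:
    """Per-group median Delta log2 TR (hypoxia minus normoxia) plus a
    rank-sum comparison of the first two groups.

    Pause release lowers the travelling ratio, so direct HIF targets are
    expected to show negative Delta log2 TR relative to distal controls.
    """
    if len(gene_groups) < 2:
        raise ValueError("need at least two gene groups")
    deltas: dict[str, np.ndarray] = {}
    for name, ids in gene_groups.items():
        vals = []
        for tid in ids:
            a, b = tr_normoxia.get(tid), tr_hypoxia.get(tid)
            if a and b and a.tr and b.tr:
                vals.append(math.log2(b.tr) - math.log2(a.tr))
        if len(vals) < 5:
            raise ValueError(f"group {name!r} has fewer than 5 usable genes")
        deltas[name] = np.array(vals)
    g1, g2 = list(gene_groups)[:2]
    W, z, p = rank_sum(deltas[g1], deltas[g2])
    return {
        "medians": {name: float(np.median(v)) for name, v in deltas.items()},
        "n": {name: int(v.size) for name, v in deltas.items()},
        "groups_compared": (g1, g2),
        "W": W,
        "z": z,
        "p_value": p,
    }


def classify_induction_mode(
    prom_norm: float,
    prom_hyp: float,
    body_norm: float,
    body_hyp: float,
    body_fold_min: float = 2.0,
    prom_release_max: float = 1.5,
    prom_denovo_min: float = 2.0,
    pseudo: float = 0.1,
) -> str:
    """Pause release: the gene body gains polymerase while the promoter
    peak barely changes; de novo recruitment: promoter and body both rise.
    Intermediate patterns are 'unchanged'. Densities in signal/bp, with a
    pseudocount guarding empty windows."""
    body_ratio = (body_hyp + pseudo) / (body_norm + pseudo)
    prom_ratio = (prom_hyp + pseudo) / (prom_norm + pseudo)
    if body_ratio >= body_fold_min and prom_ratio < prom_release_max:
        return "pause_release"
    if body_ratio >= body_fold_min and prom_ratio >= prom_denovo_min:
        return "de_novo_recruitment"
    return "unchanged"
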