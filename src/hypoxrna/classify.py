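"""Sequential RNA-class assignment and class-specific abundance filtering.

Each transcribed feature is assigned to exactly one RNA class by priority
(structural/short RNA databases are consulted before long RNA classes, as
in sequential mapping pipelines for ribosome-depleted directional
libraries); ribosomal features are diverted to a removed pool; features
matching nothing are kept as input for novel-transcript discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    AnnotationSet,
    CountMatrix,
    GenomicInterval,
    overlap_length,
)

DEFAULT_PRIORITY = ("rRNA", "tRNA", "snRNA", "miRNA", "piwiRNA", "mRNA", "lncRNA")


@dataclass(frozen=True)
class ClassPriority:
    """Ordered class labels, highest priority first."""

    order: tuple = DEFAULT_PRIORITY

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("priority order contains duplicates")

    def rank(self, rna_class: str) -> int:
        return self.order.index(rna_class)


@dataclass
class ClassifiedCounts:
    """Partition of input features: per-class assignments, unassigned
    features (novel-discovery input), and removed ribosomal features."""

    assigned: dict = field(default_factory=dict)   # class -> list of (feature, transcript id)
    unassigned: list = field(default_factory=list)
    rrna_removed: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    @property
    def n_input(self) -> int:
        return self.n_assigned + len(self.unassigned) + self.rrna_removed


def assign_class(
    feature: GenomicInterval,
    annotation: AnnotationSet,
    priority: ClassPriority = ClassPriority(),
) -> tuple[str | None, str | None]:
    """Assign a feature to the highest-priority RNA class with a
    same-strand overlapping transcript.

    Within the winning class, ties are broken by largest overlap length,
    then lexicographic transcript id. Returns (class, transcript id), or
    (None, None) when nothing overlaps on the same strand.
    """
    hits = annotation.query(feature, mode="same_strand")
    if not hits:
        return None, None
    covered = [t for t in hits if t.rna_class in priority.order]
    if not covered:
        missing = sorted({t.rna_class for t in hits})
        raise ValueError(f"priority order does not cover classes {missing}")
    best = min(
        covered,
        key=lambda t: (priority.rank(t.rna_class), -overlap_length(feature, t.interval), t.id),
    )
    return best.rna_class, best.id


def classify_all(
    features: list[GenomicInterval],
    annotation: AnnotationSet,
    priority: ClassPriority = ClassPriority(),
) -> ClassifiedCounts:
    """Assign every feature; rRNA assignments are diverted to the removed
    pool. The output partitions the input exactly."""
    out = ClassifiedCounts()
    for f in features:
        cls, tid = assign_class(f, annotation, priority)
        if cls is None:
            out.unassigned.append(f)
        elif cls == "rRNA":
            out.rrna_removed += 1
        else:
            out.assigned.setdefault(cls, []).append((f, tid))
    return out


def default_thresholds(annotation: AnnotationSet, short_cut: int = 200,
                       low: float = 10.0, high: float = 50.0) -> dict[str, float]:
    """Class thresholds on mean raw count: ``low`` for classes whose median
    transcript length is under ``short_cut`` nt, ``high`` otherwise —
    higher thresholds for classes of longer RNAs."""
    lengths: dict[str, list[int]] = {}
    for t in annotation:
        lengths.setdefault(t.rna_class, []).append(t.length)
    return {
        cls: (low if float(np.median(v)) < short_cut else high)
        for cls, v in lengths.items()
    }


def filter_low_abundance(
    counts: CountMatrix,
    classes: dict[str, str],
    thresholds: dict[str, float],
    contrast_samples: tuple[str, str] = ("normoxia", "hypoxia"),
) -> CountMatrix:
    """Keep a transcript iff its mean raw count across the two contrast
    samples meets its class threshold (boundary inclusive). Row order is
    preserved."""
    present = {classes[tid] for tid in counts.transcript_ids if tid in classes}
    missing = sorted(present - set(thresholds))
    if missing:
        raise ValueError(f"thresholds missing for classes {missing}")
    sub = counts.counts[list(contrast_samples)]
    means = sub.mean(axis=1)
    keep = [
        tid for tid in counts.transcript_ids
        if tid in classes and means[tid] >= thresholds[classes[tid]]
    ]
    return CountMatrix(counts.counts.loc[keep])
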