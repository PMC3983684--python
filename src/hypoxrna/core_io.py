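"""Domain types, readers/writers for standard genomic formats, and
strand-aware interval algebra.

Coordinates are 0-based half-open internally (BED convention). GTF's
1-based inclusive coordinates are converted on read and write. The TSS of
a minus-strand transcript is ``end - 1`` (its biological 5' end).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

STRANDS = {"+", "-", "."}
RNA_CLASSES = {"mRNA", "lncRNA", "miRNA", "snRNA", "tRNA", "piwiRNA", "rRNA", "novel"}
FACTORS = {"HIF1", "HIF2"}
MARKS = {"RNApol2", "H3K4me3", "DNase", "RNAseq"}


class ParseError(ValueError):
    """A file did not parse in the expected dialect."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {sorted(STRANDS)}")

    @property
    def length(self) -> int:
        return self.end - self.start


def overlaps(a: GenomicInterval, b: GenomicInterval, mode: str = "any_strand") -> bool:
    """True iff the half-open ranges intersect on the same chromosome and
    the strand relation matches ``mode``.

    ``same_strand`` / ``opposite_strand`` require both intervals to carry a
    definite strand ('.' never satisfies either relation).
    """
    if a.chrom != b.chrom:
        return False
    if not (a.start < b.end and b.start < a.end):
        return False
    if mode == "any_strand":
        return True
    if mode == "same_strand":
        return a.strand in "+-" and a.strand == b.strand
    if mode == "opposite_strand":
        return {a.strand, b.strand} == {"+", "-"}
    raise ValueError(f"unknown overlap mode: {mode}")


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class TranscriptRecord:
    """A strand-aware transcript with an RNA class label and TSS."""

    id: str
    interval: GenomicInterval
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValidationError(f"unknown RNA class {self.rna_class!r} for {self.id}")
        if self.interval.strand not in "+-":
            raise ValidationError(f"transcript {self.id} must be stranded (directional data)")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (3' end), inclusive coordinate."""
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start

    @property
    def length(self) -> int:
        return self.interval.length


class AnnotationSet:
    """A collection of transcripts with a per-chromosome interval index.

    Index queries are guaranteed to match a linear scan (tested property).
    """

    def __init__(self, transcripts: Iterable[TranscriptRecord]):
        self.transcripts: list[TranscriptRecord] = list(transcripts)
        ids = [t.id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate transcript ids: {dup[:5]}")
        self._by_id = {t.id: t for t in self.transcripts}
        self._trees: dict[str, IntervalTree] = {}
        for t in self.transcripts:
            tree = self._trees.setdefault(t.interval.chrom, IntervalTree())
            tree.addi(t.interval.start, t.interval.end, t)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def __getitem__(self, tid: str) -> TranscriptRecord:
        return self._by_id[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self._by_id

    def query(self, interval: GenomicInterval, mode: str = "any_strand") -> list[TranscriptRecord]:
        """Transcripts overlapping ``interval`` under the given strand mode."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start, interval.end)]
        out = [t for t in hits if overlaps(interval, t.interval, mode)]
        out.sort(key=lambda t: t.id)
        return out

    def subset(self, ids: Iterable[str]) -> "AnnotationSet":
        wanted = set(ids)
        return AnnotationSet(t for t in self.transcripts if t.id in wanted)


@dataclass(frozen=True)
class Peak:
    """A ChIP binding interval with a summit position and bound factor."""

    id: str
    interval: GenomicInterval
    summit: int
    factor: str

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValidationError(f"factor must be one of {sorted(FACTORS)}")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(f"summit {self.summit} outside peak {self.id}")


@dataclass
class CoverageTrack:
    """Per-base signal for one mark in one condition.

    ``values`` maps chromosome name to a non-negative float array covering
    the whole chromosome.
    """

    mark: str
    condition: str
    values: dict[str, np.ndarray]
    strand: str = "."

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValidationError(f"unknown mark {self.mark!r}")
        for chrom, arr in self.values.items():
            if np.any(arr < 0):
                raise ValidationError(f"negative coverage on {chrom}")

    @property
    def total_signal(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))


@dataclass
class CountMatrix:
    """Raw counts, transcripts x samples, with per-sample library sizes."""

    counts: pd.DataFrame  # index = transcript ids, columns = sample ids

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{ln}: expected two tab-separated columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in sorted(sizes):
            fh.write(f"{name}\t{sizes[name]}\n")


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_annotation(path: str | os.PathLike, format: str = "GTF") -> AnnotationSet:
    """Read a transcript annotation from GTF (transcript features) or BED12.

    The RNA class is taken from the ``rna_class`` GTF attribute or, for
    BED12, from a 13th column. GTF 1-based inclusive coordinates become
    0-based half-open; the TSS is computed strand-correctly.
    """
    fmt = format.upper()
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "GTF":
                    if len(fields) < 9:
                        raise ParseError("expected 9 GTF columns")
                    chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
                    if feature != "transcript":
                        continue
                    a = _parse_gtf_attributes(attrs)
                    tid = a.get("transcript_id")
                    if tid is None:
                        raise ParseError("missing transcript_id attribute")
                    rna_class = a.get("rna_class")
                    if rna_class is None:
                        raise ParseError("missing rna_class attribute")
                    iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
                elif fmt == "BED12":
                    if len(fields) < 12:
                        raise ParseError("expected >=12 BED columns")
                    chrom, start, end, tid, _, strand = fields[:6]
                    if len(fields) < 13:
                        raise ParseError("expected rna_class in column 13")
                    rna_class = fields[12]
                    iv = GenomicInterval(chrom, int(start), int(end), strand)
                else:
                    raise ValueError(f"unknown annotation format: {format}")
                if tid in seen:
                    raise ValidationError(f"duplicate transcript id {tid!r}")
                seen.add(tid)
                records.append(TranscriptRecord(tid, iv, rna_class))
            except (ParseError, ValidationError) as exc:
                raise type(exc)(f"{path}:{ln}: {exc}") from None
    return AnnotationSet(records)


def write_annotation(annotation: AnnotationSet, path: str | os.PathLike) -> None:
    """Write transcripts as GTF (1-based inclusive coordinates)."""
    rows = sorted(annotation, key=lambda t: (t.interval.chrom, t.interval.start, t.id))
    with open(path, "w") as fh:
        for t in rows:
            iv = t.interval
            attrs = f'transcript_id "{t.id}"; rna_class "{t.rna_class}";'
            fh.write(
                f"{iv.chrom}\thypoxrna\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def read_peaks(path: str | os.PathLike, factor: str) -> list[Peak]:
    """Read ChIP peaks from BED (>=3 columns).

    Column 5 (0-based index 4), when present and integer, is interpreted as
    the summit offset from the peak start; otherwise the summit defaults to
    the interval midpoint.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{ln}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValidationError(f"{path}:{ln}: end <= start")
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else f"{factor}_peak_{ln}"
            if len(fields) > 4 and fields[4] not in (".", ""):
                summit = start + int(fields[4])
            else:
                summit = start + (end - start) // 2
            peaks.append(Peak(name, GenomicInterval(chrom, start, end, "."), summit, factor))
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | os.PathLike) -> None:
    rows = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.id))
    with open(path, "w") as fh:
        for p in rows:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.id}\t{p.summit - iv.start}\n")


def read_coverage(
    path: str | os.PathLike,
    mark: str,
    condition: str,
    chrom_sizes: dict[str, int],
    strand: str = ".",
) -> CoverageTrack:
    """Read a bedGraph into per-base arrays; uncovered bases are zero.

    Overlapping bedGraph intervals are rejected as ambiguous.
    """
    values = {chrom: np.zeros(size, dtype=np.float32) for chrom, size in chrom_sizes.items()}
    covered = {chrom: np.zeros(size, dtype=bool) for chrom, size in chrom_sizes.items()}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{ln}: expected 4 bedGraph columns")
            chrom, start, end, val = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in values:
                raise ValidationError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom] or start < 0 or end <= start:
                raise ValidationError(f"{path}:{ln}: interval outside chromosome bounds")
            if val < 0:
                raise ValidationError(f"{path}:{ln}: negative signal value")
            if covered[chrom][start:end].any():
                raise ValidationError(f"{path}:{ln}: overlapping bedGraph intervals")
            covered[chrom][start:end] = True
            values[chrom][start:end] = val
    return CoverageTrack(mark=mark, condition=condition, values=values, strand=strand)


def write_coverage(track: CoverageTrack, path: str | os.PathLike, decimals: int = 4) -> None:
    """Write a coverage track as bedGraph, run-length encoding equal values
    (after rounding) and skipping zero runs."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = np.round(track.values[chrom].astype(np.float64), decimals)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_table(rows: Iterable[dict], path: str | os.PathLike, schema: Sequence[str]) -> None:
    """Write dict rows as a TSV with header, sorted by the first schema key."""
    rows = list(rows)
    for r in rows:
        missing = [c for c in schema if c not in r]
        if missing:
            raise ValidationError(f"row missing columns {missing}")
    rows.sort(key=lambda r: str(r[schema[0]]))
    with open(path, "w") as fh:
        fh.write("\t".join(schema) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in schema) + "\n")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_counts(path: str | os.PathLike) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.astype(np.int64))


def write_counts(cm: CountMatrix, path: str | os.PathLike) -> None:
    cm.counts.sort_index().to_csv(path, sep="\t", index_label="transcript_id")
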