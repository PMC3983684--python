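"""Novel-transcript assembly, classification, CpG islands, coding
potential, and sense/antisense co-regulation."""

import numpy as np
import pytest

from hypoxrna.core_io import AnnotationSet, CoverageTrack, GenomicInterval, TranscriptRecord
from hypoxrna.novel import (
    NovelTranscript,
    assemble_unexplained,
    classify_novel,
    coding_potential,
    find_cpg_islands,
    pair_regulation,
    promoter_cpg_flag,
    transcript_sequence,
)


def _track(arrays, strand):
    return CoverageTrack("RNAseq", "hypoxia", arrays, strand=strand)


def _empty_ann():
    return AnnotationSet([])


def test_gap_merge_rule():
    arr = np.zeros(2000, dtype=np.float32)
    arr[100:400] = 1.0
    arr[450:800] = 1.0  # 50 bp gap
    cov = {"+": _track({"chr1": arr}, "+"), "-": _track({"chr1": np.zeros(2000, np.float32)}, "-")}
    one = assemble_unexplained(cov, _empty_ann(), min_depth=0.5, max_gap=100, min_length=200)
    assert [(c.start, c.end) for c in one] == [(100, 800)]
    two = assemble_unexplained(cov, _empty_ann(), min_depth=0.5, max_gap=20, min_length=200)
    assert [(c.start, c.end) for c in two] == [(100, 400), (450, 800)]


def test_same_strand_annotation_masks_signal():
    arr = np.zeros(1000, dtype=np.float32)
    arr[0:900] = 2.0
    ann = AnnotationSet([TranscriptRecord("m", GenomicInterval("chr1", 0, 600, "+"), "mRNA")])
    cov = {"+": _track({"chr1": arr}, "+")}
    out = assemble_unexplained(cov, ann, min_depth=0.5, max_gap=10, min_length=200)
    assert [(c.start, c.end) for c in out] == [(600, 900)]


def test_classify_novel_categories():
    ann = AnnotationSet([TranscriptRecord("m", GenomicInterval("chr1", 1000, 3000, "-"), "mRNA")])
    cands = [
        GenomicInterval("chr1", 1500, 2200, "+"),   # antisense to m
        GenomicInterval("chr1", 5000, 5600, "+"),   # desert -> intergenic
        GenomicInterval("chr1", 1500, 2200, "-"),   # same strand -> discarded
    ]
    out = classify_novel(cands, ann)
    cats = {(n.interval.start, n.interval.strand): n for n in out}
    assert len(out) == 2
    assert cats[(1500, "+")].category == "antisense"
    assert cats[(1500, "+")].overlapping_sense_id == "m"
    assert cats[(5000, "+")].category == "intergenic"


def test_recovery_of_planted_novel_loci(default_sim):
    sim = default_sim
    cov = {s: sim.tracks[("RNAseq", "hypoxia", s)] for s in "+-"}
    cands = assemble_unexplained(cov, sim.annotation)
    out = classify_novel(cands, sim.annotation)
    assert len(out) == len(sim.truth.novel_transcripts)
    planted = sim.truth.novel_transcripts
    for n in out:
        iv = n.interval
        ro = max(
            (max(0, min(iv.end, t.interval.end) - max(iv.start, t.interval.start))
             / max(iv.length, t.interval.length))
            for t in planted
            if t.interval.chrom == iv.chrom and t.interval.strand == iv.strand
        )
        assert ro >= 0.9
    n_ig = sum(1 for n in out if n.category == "intergenic")
    n_as = sum(1 for n in out if n.category == "antisense")
    assert n_ig == len(sim.truth.novel_intergenic_ids)
    assert n_as == len(sim.truth.novel_antisense_ids)


def test_cpg_island_on_pure_cg_repeat():
    islands = find_cpg_islands("CG" * 150)
    assert len(islands) == 1
    isl = islands[0]
    assert isl.gc_fraction == pytest.approx(1.0)
    assert isl.obs_exp_cpg >= 1.0
    assert find_cpg_islands("AT" * 150) == []
    assert find_cpg_islands("N" * 300) == []


def test_islands_disjoint_and_self_consistent():
    rng = np.random.default_rng(12)
    bg = rng.choice(list("ACGT"), p=[0.32, 0.18, 0.18, 0.32], size=20_000)
    seq = "".join(bg)
    seq = seq[:5000] + "CG" * 200 + seq[5400:10_000] + "GC" * 100 + seq[10_200:]
    islands = find_cpg_islands(seq)
    assert islands
    spans = sorted((i.interval.start, i.interval.end) for i in islands)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2  # never self-overlapping
    for isl in islands:
        sub = seq[isl.interval.start:isl.interval.end]
        c, g = sub.count("C"), sub.count("G")
        cpg = sub.count("CG")
        assert len(sub) >= 200
        assert (c + g) / len(sub) >= 0.5
        assert cpg * len(sub) / (c * g) >= 0.6


def test_promoter_flag_boundaries():
    tss = 5299
    nt = NovelTranscript("n", GenomicInterval("chr1", tss, tss + 500, "+"), "intergenic")
    def isl(s, e):
        from hypoxrna.novel import CpgIsland
        return [CpgIsland(GenomicInterval("chr1", s, e, "."), 0.6, 0.7)]
    # island ending 999 bp upstream (end-1 == tss-999)
    assert promoter_cpg_flag(nt, isl(4000, tss - 999 + 1)) is True
    # island ending 1001 bp upstream
    assert promoter_cpg_flag(nt, isl(3000, tss - 1001 + 1)) is False
    # island starting exactly 1000 bp downstream
    assert promoter_cpg_flag(nt, isl(tss + 1000, tss + 1200)) is True
    assert promoter_cpg_flag(nt, isl(tss + 1001, tss + 1200)) is False


def test_cpg_flag_fraction_recovers_planted(default_sim):
    sim = default_sim
    cov = {s: sim.tracks[("RNAseq", "hypoxia", s)] for s in "+-"}
    out = classify_novel(assemble_unexplained(cov, sim.annotation), sim.annotation)
    islands = {c: find_cpg_islands(sim.genome[c], chrom=c) for c in sim.genome}
    flags = [promoter_cpg_flag(n, islands[n.interval.chrom]) for n in out]
    frac = float(np.mean(flags))
    assert abs(frac - sim.config.cpg_frac) <= 0.1


def test_coding_potential_trivials_and_oracle():
    orf = "ATG" + "GCT" * 30 + "TAA"
    assert coding_potential(orf) == pytest.approx(1.0)
    no_atg = "GGGCCC" * 20
    assert coding_potential(no_atg) == 0.0
    with pytest.raises(ValueError):
        coding_potential("ATG" * 10)

    def brute(seq):
        best = 0
        stops = {"TAA", "TAG", "TGA"}
        for i in range(len(seq)):
            if seq[i:i + 3] == "ATG":
                j = i + 3
                while j + 3 <= len(seq):
                    if seq[j:j + 3] in stops:
                        best = max(best, j + 3 - i)
                        break
                    j += 3
        return best / len(seq)

    rng = np.random.default_rng(21)
    for _ in range(200):
        n = int(rng.integers(60, 400))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        assert coding_potential(seq) == pytest.approx(brute(seq))


def test_random_long_sequences_low_coding_potential():
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGT"), p=[0.32, 0.18, 0.18, 0.32], size=1000))
    assert coding_potential(seq) < 0.3


def test_planted_novel_are_noncoding(default_sim):
    sim = default_sim
    scores = [
        coding_potential(transcript_sequence(sim.genome, t.interval))
        for t in sim.truth.novel_transcripts
    ]
    assert np.mean([s < 0.3 for s in scores]) >= 0.95


@pytest.mark.parametrize("novel,sense,expected", [
    (2.0, 1.0, "co_regulated"),
    (2.0, -1.0, "counter_regulated"),
    (2.0, 0.1, "unclassified"),
    (-0.6, -0.7, "co_regulated"),
])
def test_pair_regulation_rules(novel, sense, expected):
    assert pair_regulation(novel, sense) == expected
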