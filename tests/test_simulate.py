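"""Generator determinism and the planted-truth guarantees, checked by
brute-force scans."""

import numpy as np
import pytest

from hypoxrna.core_io import overlaps
from hypoxrna.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_counts,
    simulate_coverage,
    simulate_genome,
)


def test_genome_deterministic_bytes():
    cfg = SimulationConfig.tiny(seed=5)
    ann, truth = simulate_annotation(cfg)
    g1, s1 = simulate_genome(cfg, truth)
    g2, s2 = simulate_genome(cfg, truth)
    assert g1 == g2 and s1 == s2


def test_counts_deterministic(tiny_sim):
    cfg = tiny_sim.config
    c2 = simulate_counts(cfg, tiny_sim.annotation, tiny_sim.truth)
    assert tiny_sim.counts.counts.equals(c2.counts)


def test_novel_overlap_structure_brute_force(tiny_sim):
    ann, truth = tiny_sim.annotation, tiny_sim.truth
    public = list(ann)
    by_id = {t.id: t for t in truth.novel_transcripts}
    for tid in truth.novel_intergenic_ids:
        iv = by_id[tid].interval
        assert not any(overlaps(iv, t.interval, "any_strand") for t in public)
    for tid in truth.novel_antisense_ids:
        iv = by_id[tid].interval
        hits = [t for t in public
                if t.rna_class == "mRNA" and overlaps(iv, t.interval, "opposite_strand")]
        assert hits, f"{tid} overlaps no mRNA on the opposite strand"
        assert not any(overlaps(iv, t.interval, "same_strand") for t in public)
    # planted loci absent from the public annotation
    assert not any(tid in ann for tid in by_id)


def test_zero_novel_config():
    cfg = SimulationConfig.tiny(seed=1)
    cfg.n_novel_intergenic = 0
    cfg.n_novel_antisense = 0
    cfg.cpg_frac = 0.0
    _, truth = simulate_annotation(cfg)
    assert truth.novel_intergenic_ids == [] and truth.novel_antisense_ids == []
    assert truth.cpg_flagged_ids == set()


def test_hif_targets_have_proximal_peak(default_sim):
    truth = default_sim.truth
    ann = default_sim.annotation
    by_target = {}
    for p in default_sim.peaks:
        tid = truth.peak_target[p.id]
        if tid is not None:
            by_target.setdefault(tid, []).append(p)
    for tid in truth.hif_target_ids:
        label = truth.hif_label[tid]
        tss = ann[tid].tss
        factors = {p.factor for p in by_target.get(tid, [])
                   if abs(p.summit - tss) <= 2500}
        expected = {"HIF1", "HIF2"} if label == "both" else {label}
        assert expected <= factors


def test_distal_peaks_far_from_every_tss(default_sim):
    truth = default_sim.truth
    tsss = {}
    for t in list(default_sim.annotation) + truth.novel_transcripts:
        tsss.setdefault(t.interval.chrom, []).append(t.tss)
    cfg = default_sim.config
    for p in default_sim.peaks:
        if truth.peak_target[p.id] is None:
            d = min(abs(p.summit - x) for x in tsss[p.interval.chrom])
            assert d > cfg.distal_min_tss_distance


def test_true_lfc_class_medians_near_config(default_sim):
    """Planted per-transcript effects centre on the configured class means
    (HIF targets are boosted separately and excluded)."""
    cfg, truth = default_sim.config, default_sim.truth
    by_class = {}
    for t in default_sim.annotation:
        if truth.hif_label[t.id] == "none":
            by_class.setdefault(t.rna_class, []).append(truth.true_lfc[t.id])
    for cls, vals in by_class.items():
        if len(vals) < 30:
            continue
        tol = 2 * cfg.effect_sd / np.sqrt(len(vals))
        # median of a normal sample: allow the usual 1.25 sd inflation
        assert abs(np.median(vals) - cfg.class_effect[cls]) < 2.5 * tol + 0.1


def test_count_ratio_approaches_planted_fold():
    """With vanishing dispersion and a large mean, hypoxia/normoxia count
    ratios converge on 2^lfc (law of large numbers)."""
    cfg = SimulationConfig.tiny(seed=9)
    cfg.dispersion = 0.0
    cfg.equalize_depth = False
    cfg.base_mean_range = (1e5, 1e5 + 1)
    cfg.target_base_mean_min = 1e5
    cfg.frac_hif_targets = 0.0
    cfg.n_novel_intergenic = 0
    cfg.n_novel_antisense = 0
    ann, truth = simulate_annotation(cfg)
    counts = simulate_counts(cfg, ann, truth)
    ratios = counts.counts["hypoxia"] / counts.counts["normoxia"]
    expected = np.array([2.0 ** truth.true_lfc[t] for t in counts.transcript_ids])
    assert np.allclose(ratios.to_numpy(), expected, rtol=0.05)


def test_full_knockdown_abolishes_induction():
    from hypoxrna.simulate import _condition_means

    cfg = SimulationConfig.tiny(seed=2)
    cfg.knockdown_efficiency = 1.0
    ann, truth = simulate_annotation(cfg)
    both = [t for t, lab in truth.hif_label.items() if lab == "both"]
    assert both
    for tid in both:
        m = _condition_means(cfg, truth, tid)
        assert m["hypoxia_siBoth"] == pytest.approx(truth.base_mean[tid])


def test_dnase_identical_between_conditions(tiny_sim):
    sim = tiny_sim
    a = simulate_coverage(sim.config, sim.annotation, sim.truth, "normoxia", "DNase")
    b = simulate_coverage(sim.config, sim.annotation, sim.truth, "hypoxia", "DNase")
    for chrom in a.values:
        assert np.array_equal(a.values[chrom], b.values[chrom])


def test_pause_kernel_argmax_at_planted_offset(tiny_sim):
    sim = tiny_sim
    track = sim.tracks[("RNApol2", "normoxia")]
    cfg = sim.config
    for t in sim.annotation:
        if t.rna_class != "mRNA":
            continue
        arr = track.values[t.interval.chrom]
        lo, hi = t.tss - 300, t.tss + 301
        local = arr[lo:hi]
        direction = 1 if t.interval.strand == "+" else -1
        expect = t.tss + direction * cfg.pause_offset
        got = lo + int(np.argmax(local))
        # neighbours can add signal; allow a few bp of slack
        assert abs(got - expect) <= 5


def test_hif_target_body_rises_pause_constant(default_sim):
    sim = default_sim
    norm = sim.tracks[("RNApol2", "normoxia")]
    hyp = sim.tracks[("RNApol2", "hypoxia")]
    checked = 0
    for tid in sim.truth.hif_target_ids:
        if tid in sim.truth.de_novo_ids:
            continue
        t = sim.annotation[tid]
        iv = t.interval
        direction = 1 if iv.strand == "+" else -1
        summit = t.tss + direction * sim.config.pause_offset
        body = slice(iv.start + 600, iv.end) if iv.strand == "+" else slice(iv.start, iv.end - 600)
        n_arr, h_arr = norm.values[iv.chrom], hyp.values[iv.chrom]
        assert h_arr[body].mean() > n_arr[body].mean()
        assert h_arr[summit] == pytest.approx(n_arr[summit], rel=0.35)
        checked += 1
    assert checked >= 30


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(cpg_frac=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(pause_offset=-1)
    with pytest.raises(ValueError):
        SimulationConfig(hif1_frac=0.7, hif2_frac=0.7)
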