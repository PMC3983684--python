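"""Metagene orientation, travelling-ratio arithmetic and invariances,
rank-sum statistic, and induction-mode classification."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from hypoxrna.core_io import AnnotationSet, CoverageTrack, GenomicInterval, TranscriptRecord
from hypoxrna.pausing import (
    classify_induction_mode,
    metagene,
    pause_summit_offset,
    rank_sum,
    select_top_induced,
    travelling_ratio,
    tr_shift,
)


def _tr(tid, start, end, strand="+"):
    return TranscriptRecord(tid, GenomicInterval("chr1", start, end, strand), "mRNA")


def _track(arr, condition="normoxia", mark="RNApol2"):
    return CoverageTrack(mark, condition, {"chr1": np.asarray(arr, dtype=np.float64)})


def test_select_top_is_ranking_prefix():
    import pandas as pd

    ranked = pd.DataFrame({"score": [3.0, 2.0, 1.0]}, index=["a", "b", "c"])
    assert select_top_induced(ranked, 1) == ["a"]
    assert select_top_induced(ranked, 3) == ["a", "b", "c"]
    with pytest.raises(ValueError):
        select_top_induced(ranked, 4)


def test_metagene_flat_track_flat_profile():
    track = _track(np.full(10_000, 3.0))
    prof = metagene(track, [_tr("a", 4000, 6000)], window=(-1000, 1000), bin_size=10,
                    normalize=False)
    assert np.allclose(prof.values, 3.0)
    with pytest.raises(ValueError):
        metagene(track, [], window=(-1000, 1000))


def test_metagene_additive_on_raw_signal():
    rng = np.random.default_rng(2)
    a = rng.random(10_000)
    b = rng.random(10_000)
    genes = [_tr("a", 4000, 6000), _tr("b", 5000, 8000, "-")]
    pa = metagene(_track(a), genes, (-500, 500), 10, normalize=False).values
    pb = metagene(_track(b), genes, (-500, 500), 10, normalize=False).values
    pab = metagene(_track(a + b), genes, (-500, 500), 10, normalize=False).values
    assert np.allclose(pab, pa + pb)


def test_metagene_mirror_symmetry():
    """A minus-strand gene over the mirrored track gives the mirrored
    profile of a plus-strand gene."""
    rng = np.random.default_rng(3)
    sig = rng.random(10_000)
    fwd = metagene(_track(sig), [_tr("f", 5000, 6000, "+")], (-1000, 1000), 10,
                   normalize=False).values
    mirrored = sig[::-1].copy()
    # plus-strand TSS 5000 maps to minus-strand TSS at 9999-5000
    g = TranscriptRecord("r", GenomicInterval("chr1", 9999 - 6000 + 1, 9999 - 5000 + 1, "-"), "mRNA")
    rev = metagene(_track(mirrored), [g], (-1000, 1000), 10, normalize=False).values
    assert np.allclose(fwd, rev)


def test_summit_offset_conventions():
    track = _track(np.zeros(10_000))
    track.values["chr1"][5100:5110] = 2.0  # bin [+100,+110) for TSS 5000
    prof = metagene(track, [_tr("a", 5000, 8000)], (-1000, 1000), 10, normalize=False)
    assert pause_summit_offset(prof) == pytest.approx(105.0)
    flat = metagene(_track(np.ones(10_000)), [_tr("a", 5000, 8000)], (-1000, 1000), 10,
                    normalize=False)
    with pytest.raises(ValueError):
        pause_summit_offset(flat)


def test_travelling_ratio_values_and_scale_invariance():
    arr = np.full(20_000, 2.0)
    uniform = travelling_ratio(_track(arr), [_tr("a", 5000, 9000)])["a"]
    assert uniform.tr == pytest.approx(1.0)
    arr2 = np.zeros(20_000)
    arr2[4970:5300] = 10.0
    arr2[5300:9000] = 2.0
    t = travelling_ratio(_track(arr2), [_tr("a", 5000, 9000)])["a"]
    assert t.tr == pytest.approx(5.0)
    t7 = travelling_ratio(_track(arr2 * 7), [_tr("a", 5000, 9000)])["a"]
    assert t7.tr == pytest.approx(t.tr)


def test_travelling_ratio_skips_short():
    with pytest.warns(UserWarning, match="too short"):
        out = travelling_ratio(_track(np.ones(10_000)), [_tr("s", 5000, 5200)])
    assert out == {}


def test_rank_sum_matches_exact_enumeration():
    """For n<=8 without ties the normal-approximation W equals the exact
    rank-sum statistic, and the p-value tracks the exact permutation tail."""
    rng = np.random.default_rng(14)
    for _ in range(200):
        n1, n2 = int(rng.integers(3, 5)), int(rng.integers(3, 5))
        pooled = rng.permutation(rng.normal(size=n1 + n2) * 10)
        x, y = pooled[:n1], pooled[n1:]
        W, z, p = rank_sum(x, y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        assert W == pytest.approx(ranks[:n1].sum())
        # exact permutation distribution of W: the z-score must use its
        # exact mean and variance (enumerated, not formulaic)
        all_ranks = list(range(1, n1 + n2 + 1))
        ws = np.array([sum(c) for c in itertools.combinations(all_ranks, n1)])
        assert z == pytest.approx((W - ws.mean()) / ws.std(ddof=0), abs=1e-10)
        z_sp, p_sp = sps.ranksums(x, y)
        assert p == pytest.approx(p_sp, abs=1e-10)


def test_rank_sum_tie_correction_matches_reference():
    """With ties the tie-corrected normal p matches Mann-Whitney's
    asymptotic p (no continuity correction); W and U are equivalent."""
    rng = np.random.default_rng(15)
    for _ in range(50):
        n1 = 12
        x = rng.integers(0, 5, size=n1).astype(float)
        y = rng.integers(0, 5, size=15).astype(float)
        if np.all(np.concatenate([x, y]) == x[0]):
            continue
        W, z, p = rank_sum(x, y)
        res = sps.mannwhitneyu(x, y, use_continuity=False,
                               alternative="two-sided", method="asymptotic")
        assert W - n1 * (n1 + 1) / 2 == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue, abs=1e-10)


def test_tr_shift_identical_conditions_null():
    arr = np.zeros(50_000)
    rng = np.random.default_rng(4)
    genes = []
    for i in range(12):
        s = 2000 + i * 4000
        arr[s - 100:s + 200] = 5 + rng.random()
        arr[s + 200:s + 2000] = 1 + rng.random()
        genes.append(_tr(f"g{i}", s, s + 2000))
    tn = travelling_ratio(_track(arr, "normoxia"), genes)
    th = travelling_ratio(_track(arr, "hypoxia"), genes)
    out = tr_shift(tn, th, {"a": [f"g{i}" for i in range(6)],
                            "b": [f"g{i}" for i in range(6, 12)]})
    assert out["medians"]["a"] == 0.0 and out["medians"]["b"] == 0.0
    assert out["p_value"] > 0.9
    with pytest.raises(ValueError, match="fewer than 5"):
        tr_shift(tn, th, {"a": ["g0"], "b": ["g1"]})


@pytest.mark.parametrize("pn,ph,bn,bh,expected", [
    (10, 10, 1, 4, "pause_release"),
    (0.1, 5, 0.1, 3, "de_novo_recruitment"),
    (10, 10, 1, 1.2, "unchanged"),
    (10, 17, 1, 4, "unchanged"),  # intermediate promoter gain
])
def test_induction_mode_rules(pn, ph, bn, bh, expected):
    assert classify_induction_mode(pn, ph, bn, bh) == expected


def test_pause_release_lowers_tr_on_generator(default_sim):
    sim = default_sim
    tn = travelling_ratio(sim.tracks[("RNApol2", "normoxia")],
                          [sim.annotation[t] for t in sim.truth.hif_target_ids])
    th = travelling_ratio(sim.tracks[("RNApol2", "hypoxia")],
                          [sim.annotation[t] for t in sim.truth.hif_target_ids])
    for tid in sim.truth.hif_target_ids:
        if tid in sim.truth.de_novo_ids or tid not in tn:
            continue
        assert th[tid].tr < tn[tid].tr


def test_dnase_metagene_identical_between_conditions(default_sim):
    sim = default_sim
    genes = [t for t in sim.annotation if t.rna_class == "mRNA"][:50]
    a = metagene(sim.tracks[("DNase", "normoxia")], genes, normalize=False)
    b = metagene(sim.tracks[("DNase", "hypoxia")], genes, normalize=False)
    assert np.array_equal(a.values, b.values)
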