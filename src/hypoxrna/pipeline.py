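"""End-to-end orchestration: each stage reads its inputs from disk, runs
the corresponding library functions, and writes TSV/JSON artifacts, so any
stage can be rerun from its predecessors' outputs. Rerunning with the
same configuration reproduces byte-identical data outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import expression as ex
from . import hif as hf
from . import novel as nv
from . import pausing as pz
from .core_io import (
    AnnotationSet,
    CountMatrix,
    read_annotation,
    read_chrom_sizes,
    read_counts,
    read_coverage,
    read_fasta,
    read_peaks,
    write_annotation,
    write_chrom_sizes,
    write_counts,
    write_coverage,
    write_fasta,
    write_peaks,
    write_table,
)
from .simulate import SimulationConfig, run_simulation

log = logging.getLogger("hypoxrna")

STAGES = ("simulate", "classify", "express", "novel", "hif", "pausing", "report")


@dataclass
class PipelineConfig:
    outdir: str = "out"
    seed: int = 7
    stages: tuple = STAGES
    sim: dict = field(default_factory=dict)          # SimulationConfig overrides
    pseudocount: float = 0.5
    sirna_delta: float = 0.5
    min_depth: float = 0.25
    max_gap: int = 50
    min_length: int = 200
    coding_threshold: float = 0.3
    cpg_max_distance: int = 1000
    distance_cutoff: int = 2500
    gsea_weight_p: float = 1.0
    gsea_n_perm: int = 1000
    metagene_window: tuple = (-2000, 2000)
    metagene_bin: int = 10
    top_n: int = 100
    distal_min_distance: int = 10000  # controls: no peak summit within this of the TSS

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "metagene_window" in raw:
            raw["metagene_window"] = tuple(raw["metagene_window"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.sim)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    sim = run_simulation(cfg.sim_config())
    write_fasta(sim.genome, outdir / "genome.fa")
    write_chrom_sizes(sim.chrom_sizes, outdir / "chrom.sizes")
    write_annotation(sim.annotation, outdir / "annotation.gtf")
    write_counts(sim.counts, outdir / "counts.tsv")
    for factor in ("HIF1", "HIF2"):
        write_peaks([p for p in sim.peaks if p.factor == factor],
                    outdir / f"peaks_{factor.lower()}.bed")
    for (key, track) in sim.tracks.items():
        if key[0] == "RNAseq":
            name = f"rnaseq_{key[1]}_{'plus' if key[2] == '+' else 'minus'}.bedgraph"
        else:
            name = f"{key[0].lower()}_{key[1]}.bedgraph"
        write_coverage(track, outdir / name)
    truth = sim.truth
    rows = []
    for t in list(sim.annotation) + truth.novel_transcripts:
        iv = t.interval
        rows.append({
            "transcript_id": t.id, "chrom": iv.chrom, "start": iv.start,
            "end": iv.end, "strand": iv.strand, "rna_class": t.rna_class,
            "true_lfc": f"{truth.true_lfc[t.id]:.6f}",
            "hif_label": truth.hif_label[t.id],
            "base_mean": f"{truth.base_mean[t.id]:.4f}",
            "novel_category": ("intergenic" if t.id in truth.novel_intergenic_ids
                               else "antisense" if t.id in truth.novel_antisense_ids
                               else "."),
            "antisense_host": truth.antisense_host.get(t.id, "."),
            "cpg_planted": int(t.id in truth.cpg_flagged_ids),
            "de_novo": int(t.id in truth.de_novo_ids),
        })
    write_table(rows, outdir / "truth.tsv", list(rows[0].keys()))
    _write_json({"pause_offset": truth.pause_offset,
                 "peak_target": {k: (v or ".") for k, v in sorted(truth.peak_target.items())}},
                outdir / "truth_peaks.json")


def stage_classify(cfg: PipelineConfig, outdir: Path) -> None:
    annotation = read_annotation(outdir / "annotation.gtf", "GTF")
    counts = read_counts(outdir / "counts.tsv")
    # run the sequential class assignment over the annotated features;
    # ribosomal features are diverted and excluded from all downstream work
    classified = cl.classify_all([t.interval for t in annotation], annotation)
    classes = {tid: c for c, pairs in classified.assigned.items() for _, tid in pairs}
    keep = [t for t in counts.transcript_ids if t in classes]
    public = CountMatrix(counts.counts.loc[keep])
    thresholds = cl.default_thresholds(annotation)
    filtered = cl.filter_low_abundance(public, classes, thresholds)
    write_counts(filtered, outdir / "filtered_counts.tsv")
    rows = [{"transcript_id": t, "rna_class": classes[t]} for t in filtered.transcript_ids]
    write_table(rows, outdir / "classes.tsv", ["transcript_id", "rna_class"])
    summary = [
        {"rna_class": c, "n_annotated": sum(1 for t in annotation if t.rna_class == c),
         "n_retained": sum(1 for t in filtered.transcript_ids if classes[t] == c),
         "threshold": thresholds[c]}
        for c in sorted(thresholds)
    ]
    write_table(summary, outdir / "class_filter_summary.tsv",
                ["rna_class", "n_annotated", "n_retained", "threshold"])


def stage_express(cfg: PipelineConfig, outdir: Path) -> None:
    filtered = read_counts(outdir / "filtered_counts.tsv")
    classes = pd.read_csv(outdir / "classes.tsv", sep="\t", index_col=0)["rna_class"].to_dict()
    expr = ex.build_expression_table(filtered, classes, cfg.pseudocount)
    expr.sort_index().to_csv(outdir / "expression.tsv", sep="\t",
                             index_label="transcript_id", float_format="%.6f")
    summaries = ex.summarize_by_class(expr)
    rows = [dataclasses.asdict(s) for s in summaries.values()]
    for r in rows:
        for k, v in r.items():
            if isinstance(v, float):
                r[k] = f"{v:.6f}"
    write_table(rows, outdir / "class_summary.tsv",
                ["rna_class", "n", "whisker_min", "q1", "median", "q3", "whisker_max"])
    ranked = ex.rank_by_induction(expr)
    ranked.to_csv(outdir / "ranked.tsv", sep="\t", index_label="transcript_id",
                  float_format="%.6f")


def stage_novel(cfg: PipelineConfig, outdir: Path) -> None:
    annotation = read_annotation(outdir / "annotation.gtf", "GTF")
    sizes = read_chrom_sizes(outdir / "chrom.sizes")
    cov = {
        cond: {
            s: read_coverage(outdir / f"rnaseq_{cond}_{name}.bedgraph", "RNAseq",
                             cond, sizes, strand=s)
            for s, name in (("+", "plus"), ("-", "minus"))
        }
        for cond in ("normoxia", "hypoxia")
    }
    candidates = nv.assemble_unexplained(cov["hypoxia"], annotation, cfg.min_depth,
                                         cfg.max_gap, cfg.min_length)
    novels = nv.classify_novel(candidates, annotation)
    genome = read_fasta(outdir / "genome.fa")
    islands_by_chrom = {
        c: nv.find_cpg_islands(genome[c], chrom=c) for c in sorted(genome)
    }
    expr = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
    rows = []
    cov_pseudo = 0.01  # signal/bp; novel loci quantified from coverage, not counts
    for n in novels:
        n.cpg_within_1kb = nv.promoter_cpg_flag(
            n, islands_by_chrom[n.interval.chrom], cfg.cpg_max_distance)
        seq = nv.transcript_sequence(genome, n.interval)
        n.coding_potential = nv.coding_potential(seq) if len(seq) >= 60 else None
        iv = n.interval
        means = {
            cond: float(cov[cond][iv.strand].values[iv.chrom][iv.start:iv.end].mean())
            for cond in ("normoxia", "hypoxia")
        }
        n.log2fc = float(np.log2((means["hypoxia"] + cov_pseudo)
                                 / (means["normoxia"] + cov_pseudo)))
        if n.category == "antisense" and n.overlapping_sense_id in expr.index:
            n.regulation_pair = nv.pair_regulation(
                n.log2fc, float(expr.loc[n.overlapping_sense_id, "log2fc_hypoxia"]))
        rows.append({
            "id": n.id, "chrom": n.interval.chrom, "start": n.interval.start,
            "end": n.interval.end, "strand": n.interval.strand,
            "category": n.category,
            "overlapping_sense_id": n.overlapping_sense_id or ".",
            "cpg_within_1kb": int(bool(n.cpg_within_1kb)),
            "coding_potential": "." if n.coding_potential is None else f"{n.coding_potential:.4f}",
            "log2fc": "." if n.log2fc is None else f"{n.log2fc:.4f}",
            "regulation_pair": n.regulation_pair or ".",
        })
    write_table(rows, outdir / "novel.tsv",
                ["id", "chrom", "start", "end", "strand", "category",
                 "overlapping_sense_id", "cpg_within_1kb", "coding_potential",
                 "log2fc", "regulation_pair"])
    with open(outdir / "novel.bed", "w") as fh:
        for n in sorted(novels, key=lambda x: (x.interval.chrom, x.interval.start)):
            iv = n.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{n.id}\t0\t{iv.strand}\n")


def stage_hif(cfg: PipelineConfig, outdir: Path) -> None:
    annotation = read_annotation(outdir / "annotation.gtf", "GTF")
    expr = pd.read_csv(outdir / "expression.tsv", sep="\t", index_col=0)
    expressed = annotation.subset([t for t in expr.index if t in annotation])
    abundance = expr[["cpm_normoxia", "cpm_hypoxia"]].mean(axis=1).to_dict()
    peaks = []
    for factor in ("HIF1", "HIF2"):
        peaks.extend(read_peaks(outdir / f"peaks_{factor.lower()}.bed", factor))
    assignments = hf.nearest_expressed_promoter(peaks, expressed, abundance)
    rows = [{
        "peak_id": a.peak_id, "factor": a.factor, "transcript_id": a.transcript_id,
        "rna_class": a.rna_class, "distance": a.distance,
    } for a in assignments]
    write_table(rows, outdir / "peak_assignments.tsv",
                ["peak_id", "factor", "transcript_id", "rna_class", "distance"])

    summary = hf.distance_summary(assignments, cfg.distance_cutoff)
    drows = [{"factor": f, "n": s["n"],
              "frac_beyond_cutoff": f"{s['frac_beyond_cutoff']:.6f}"}
             for f, s in summary.items()]
    write_table(drows, outdir / "distance_summary.tsv", ["factor", "n", "frac_beyond_cutoff"])
    props = hf.class_proportions(assignments)
    prows = [{"factor": f, "rna_class": c, "share": f"{v:.6f}"}
             for f in props for c, v in props[f].items()]
    write_table(prows, outdir / "class_proportions.tsv", ["factor", "rna_class", "share"])

    ranked = pd.read_csv(outdir / "ranked.tsv", sep="\t", index_col=0)
    bound = sorted({a.transcript_id for a in assignments})
    enr = hf.gsea(ranked, bound, cfg.gsea_weight_p, cfg.gsea_n_perm, seed=cfg.seed)
    _write_json({"es": enr.es, "p_value": enr.p_value, "n_perm": enr.n_perm,
                 "n_set": len(bound), "n_leading_edge": len(enr.leading_edge),
                 "seed": enr.seed}, outdir / "enrichment.json")

    mat = ex.sirna_matrix(expr, bound, class_filter=None, delta=cfg.sirna_delta)
    mat.table.to_csv(outdir / "sirna_matrix.tsv", sep="\t",
                     index_label="transcript_id", float_format="%.6f")


def stage_pausing(cfg: PipelineConfig, outdir: Path) -> None:
    annotation = read_annotation(outdir / "annotation.gtf", "GTF")
    sizes = read_chrom_sizes(outdir / "chrom.sizes")
    tracks = {
        (mark, cond): read_coverage(
            outdir / f"{mark.lower()}_{cond}.bedgraph", mark, cond, sizes)
        for mark in ("RNApol2", "H3K4me3", "DNase")
        for cond in ("normoxia", "hypoxia")
    }
    ranked = pd.read_csv(outdir / "ranked.tsv", sep="\t", index_col=0)
    top = pz.select_top_induced(ranked, min(cfg.top_n, len(ranked)))
    top_genes = [annotation[t] for t in top if t in annotation]
    mrows = []
    for (mark, cond), track in sorted(tracks.items()):
        prof = pz.metagene(track, top_genes, cfg.metagene_window, cfg.metagene_bin)
        for centre, val in zip(prof.bin_centres(), prof.values):
            mrows.append({"mark": mark, "condition": cond,
                          "bin_centre": f"{centre:.1f}", "value": f"{val:.6f}"})
    with open(outdir / "metagene.tsv", "w") as fh:
        fh.write("mark\tcondition\tbin_centre\tvalue\n")
        for r in mrows:
            fh.write(f"{r['mark']}\t{r['condition']}\t{r['bin_centre']}\t{r['value']}\n")

    long_enough = [t for t in annotation if t.length > 330 and t.id in ranked.index]
    tr_norm = pz.travelling_ratio(tracks[("RNApol2", "normoxia")], long_enough)
    tr_hyp = pz.travelling_ratio(tracks[("RNApol2", "hypoxia")], long_enough)
    trows = []
    for tid in sorted(set(tr_norm) & set(tr_hyp)):
        a, b = tr_norm[tid], tr_hyp[tid]
        trows.append({
            "transcript_id": tid,
            "prom_normoxia": f"{a.promoter_density:.6f}",
            "body_normoxia": f"{a.body_density:.6f}",
            "tr_normoxia": "." if a.tr is None else f"{a.tr:.6f}",
            "prom_hypoxia": f"{b.promoter_density:.6f}",
            "body_hypoxia": f"{b.body_density:.6f}",
            "tr_hypoxia": "." if b.tr is None else f"{b.tr:.6f}",
            "mode": pz.classify_induction_mode(
                a.promoter_density, b.promoter_density, a.body_density, b.body_density),
        })
    write_table(trows, outdir / "travelling_ratio.tsv", list(trows[0].keys()))

    assignments = pd.read_csv(outdir / "peak_assignments.tsv", sep="\t")
    proximal = set(assignments.loc[assignments["distance"].abs() <= cfg.distance_cutoff,
                                   "transcript_id"])
    near_any = {}
    for _, r in assignments.iterrows():
        tid = r["transcript_id"]
        near_any[tid] = min(near_any.get(tid, np.inf), abs(r["distance"]))
    direct = [t.id for t in long_enough if t.id in proximal]
    distal = [t.id for t in long_enough
              if near_any.get(t.id, np.inf) > cfg.distal_min_distance]
    shift = pz.tr_shift(tr_norm, tr_hyp, {"direct": direct, "distal": distal})
    _write_json(shift, outdir / "tr_shift.json")


def stage_report(cfg: PipelineConfig, outdir: Path) -> None:
    """Figure-equivalent summary tables, a pure function of stage outputs."""
    needed = ["class_summary.tsv", "class_proportions.tsv", "distance_summary.tsv",
              "metagene.tsv", "travelling_ratio.tsv"]
    for f in needed:
        if not (outdir / f).exists():
            raise FileNotFoundError(f"report requires stage output {f}")
    report = {}
    counts = read_counts(outdir / "counts.tsv")
    annotation = read_annotation(outdir / "annotation.gtf", "GTF")
    nonribo = [t.id for t in annotation if t.rna_class != "rRNA"
               if t.id in counts.counts.index]
    sub = counts.counts.loc[nonribo]
    report["detected_nonribosomal"] = {
        "normoxia": int((sub["normoxia"] > 0).sum()),
        "hypoxia": int((sub["hypoxia"] > 0).sum()),
    }
    cs = pd.read_csv(outdir / "class_summary.tsv", sep="\t")
    report["class_fold_change"] = cs.to_dict(orient="records")
    ds = pd.read_csv(outdir / "distance_summary.tsv", sep="\t")
    report["distal_fractions"] = ds.to_dict(orient="records")
    tr = pd.read_csv(outdir / "travelling_ratio.tsv", sep="\t")
    report["induction_modes"] = tr["mode"].value_counts().to_dict()
    if (outdir / "novel.tsv").exists():
        nvl = pd.read_csv(outdir / "novel.tsv", sep="\t")
        report["novel"] = {
            "total": int(len(nvl)),
            "intergenic": int((nvl["category"] == "intergenic").sum()),
            "antisense": int((nvl["category"] == "antisense").sum()),
            "pct_cpg_within_1kb": (
                round(100.0 * nvl["cpg_within_1kb"].mean(), 1) if len(nvl) else None),
        }
    _write_json(report, outdir / "report.json")


_STAGE_FN = {
    "simulate": stage_simulate,
    "classify": stage_classify,
    "express": stage_express,
    "novel": stage_novel,
    "hif": stage_hif,
    "pausing": stage_pausing,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured stages in dependency order and write a manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": [], "parameters": dataclasses.asdict(cfg)}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        log.info("running stage %s", stage)
        try:
            _STAGE_FN[stage](cfg, outdir)
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(stage)
    _write_json(manifest, outdir / "manifest.json")
    return outdir
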