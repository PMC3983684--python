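"""Normalization, fold-change, class-wise summaries, induction ranking,
the siRNA HIF-dependence matrix, and cross-platform concordance.

Counts are normalized to counts per million (CPM); log2 fold-changes use a
pseudocount so they are finite for every retained transcript. This
replaces negative-binomial differential testing: the class-level
conclusions downstream depend on fold-change direction and ranking, which
CPM preserves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix

DEFAULT_PSEUDOCOUNT = 0.5  # CPM units

CONTRASTS = {
    "hypoxia": ("normoxia", "hypoxia"),
    "siHIF1a": ("hypoxia_siControl", "hypoxia_siHIF1a"),
    "siHIF2a": ("hypoxia_siControl", "hypoxia_siHIF2a"),
    "siBoth": ("hypoxia_siControl", "hypoxia_siBoth"),
}


def normalize_cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6, per sample."""
    libs = counts.lib_sizes
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    return counts.counts / libs * 1e6


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Raw library sizes are distorted by asymmetric regulation (a handful of
    strongly induced transcripts inflate the hypoxic library and shift
    every fold-change); the median ratio to the per-transcript geometric
    mean is robust to that composition effect. Rows with a zero anywhere
    are excluded from the reference, as usual.
    """
    mat = counts.counts.to_numpy(dtype=float)
    keep = (mat > 0).all(axis=1)
    if keep.sum() < 1:
        raise ValueError("no all-positive rows for size-factor estimation")
    logs = np.log(mat[keep])
    ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=counts.counts.columns)


def normalize_cpm_robust(counts: CountMatrix) -> pd.DataFrame:
    """CPM on composition-corrected effective library sizes.

    The effective library size of sample j is (geometric-mean raw library
    size) x (median-of-ratios factor of j), so values stay on a
    counts-per-million scale.
    """
    libs = counts.lib_sizes
    if (libs <= 0).any():
        raise ValueError("zero library size")
    eff = float(np.exp(np.log(libs.to_numpy(dtype=float)).mean())) * size_factors(counts)
    return counts.counts / eff * 1e6


def log2_fold_change(
    norm_a: pd.Series | np.ndarray,
    norm_b: pd.Series | np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series | np.ndarray:
    """log2((b + pc) / (a + pc)), b versus a."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log2(norm_b + pseudocount) - np.log2(norm_a + pseudocount)


def build_expression_table(
    counts: CountMatrix,
    classes: dict[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    contrasts: dict[str, tuple[str, str]] | None = None,
    robust: bool = False,
) -> pd.DataFrame:
    """Per-transcript CPM for every sample plus log2FC for every contrast
    whose two samples are present, and the RNA class.

    ``robust`` uses median-of-ratios effective library sizes (recommended;
    see :func:`size_factors`); otherwise plain library-size CPM.
    """
    cpm = normalize_cpm_robust(counts) if robust else normalize_cpm(counts)
    table = cpm.rename(columns=lambda c: f"cpm_{c}")
    use = contrasts if contrasts is not None else CONTRASTS
    for name, (a, b) in use.items():
        if a in cpm.columns and b in cpm.columns:
            table[f"log2fc_{name}"] = log2_fold_change(cpm[a], cpm[b], pseudocount)
    table["rna_class"] = [classes.get(t, "novel") for t in table.index]
    return table


@dataclass(frozen=True)
class ClassSummary:
    rna_class: str
    n: int
    whisker_min: float
    q1: float
    median: float
    q3: float
    whisker_max: float


def summarize_by_class(
    expr: pd.DataFrame, column: str = "log2fc_hypoxia"
) -> dict[str, ClassSummary]:
    """Box-and-whisker statistics (median, quartiles by linear
    interpolation, full range) of a fold-change column per RNA class."""
    out: dict[str, ClassSummary] = {}
    for cls, grp in expr.groupby("rna_class"):
        vals = grp[column].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[cls] = ClassSummary(cls, int(vals.size), float(vals.min()),
                                float(q1), float(med), float(q3), float(vals.max()))
    return out


def rank_by_induction(
    expr: pd.DataFrame,
    classes: list[str] | None = None,
    column: str = "log2fc_hypoxia",
    abundance_samples: tuple[str, str] = ("normoxia", "hypoxia"),
) -> pd.DataFrame:
    """Transcripts ordered by descending hypoxic induction.

    Ties break toward the transcript with the higher mean abundance across
    the contrast samples, then lexicographic id, so the order is fully
    deterministic.
    """
    df = expr if classes is None else expr[expr["rna_class"].isin(classes)]
    abun = df[[f"cpm_{s}" for s in abundance_samples]].mean(axis=1)
    order = pd.DataFrame({
        "score": df[column], "abundance": abun, "id": df.index,
    }).sort_values(["score", "abundance", "id"], ascending=[False, False, True])
    return order[["score", "abundance"]]


@dataclass
class SirnaMatrix:
    """Fold-regulation of HIF-binding transcripts by hypoxia and by each
    HIF siRNA, with a per-row HIF-dependence call."""

    table: pd.DataFrame  # columns: log2fc_hypoxia, log2fc_siHIF1a, log2fc_siHIF2a, log2fc_siBoth, call


def call_dependence(si1: float, si2: float, delta: float = 0.5) -> str:
    """HIF1 if knockdown of HIF-1a (but not HIF-2a) suppresses the
    transcript by at least ``delta`` log2 units; HIF2 mirrored; both if
    both do; none otherwise."""
    d1 = si1 <= -delta
    d2 = si2 <= -delta
    if d1 and d2:
        return "both"
    if d1:
        return "HIF1"
    if d2:
        return "HIF2"
    return "none"


def sirna_matrix(
    expr: pd.DataFrame,
    hif_targets: list[str],
    class_filter: list[str] | None = None,
    delta: float = 0.5,
) -> SirnaMatrix:
    """Rows are peak-assigned (HIF-binding) transcripts, optionally
    restricted by class; values are the contrast log2FCs."""
    needed = ["log2fc_hypoxia", "log2fc_siHIF1a", "log2fc_siHIF2a", "log2fc_siBoth"]
    missing = [c for c in needed if c not in expr.columns]
    if missing:
        raise ValueError(f"expression table lacks contrasts {missing}")
    rows = [t for t in hif_targets if t in expr.index]
    df = expr.loc[rows, needed + ["rna_class"]].copy()
    if class_filter is not None:
        df = df[df["rna_class"].isin(class_filter)]
    df["call"] = [
        call_dependence(r["log2fc_siHIF1a"], r["log2fc_siHIF2a"], delta)
        for _, r in df.iterrows()
    ]
    return SirnaMatrix(df.sort_index())


def platform_concordance(norm_x: pd.Series, norm_y: pd.Series) -> float:
    """Spearman rho between two platforms' abundances over shared
    transcripts (average ranks for ties)."""
    shared = norm_x.index.intersection(norm_y.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared transcripts")
    rx = stats.rankdata(norm_x.loc[shared].to_numpy())
    ry = stats.rankdata(norm_y.loc[shared].to_numpy())
    return float(np.corrcoef(rx, ry)[0, 1])
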