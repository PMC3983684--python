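"""Assemble unexplained stranded expression signal into novel transcript
candidates, split them into intergenic vs antisense, and annotate promoter
CpG islands, coding potential, and sense/antisense co-regulation."""

import pandas as pd

from common import STUDY_DIR, study_config
from hypoxrna.pipeline import run_pipeline

run_pipeline(study_config("novel"))
nv = pd.read_csv(STUDY_DIR / "novel.tsv", sep="\t")
n_ig = (nv["category"] == "intergenic").sum()
n_as = (nv["category"] == "antisense").sum()
pct_cpg = 100.0 * nv["cpg_within_1kb"].mean()
print(f"novel transcripts: {len(nv)} = {n_ig} intergenic + {n_as} antisense")
print(f"CpG island within 1 kb of the putative promoter: "
      f"{nv['cpg_within_1kb'].sum()} ({pct_cpg:.0f}%)")
cp = pd.to_numeric(nv["coding_potential"], errors="coerce")
print(f"low coding potential (<0.3): {(cp < 0.3).sum()}/{cp.notna().sum()}")
print("antisense regulation vs overlapping sense transcript:")
print(nv.loc[nv["category"] == "antisense", "regulation_pair"]
      .value_counts().to_string())
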