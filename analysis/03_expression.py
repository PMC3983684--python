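"""Normalize to CPM, compute hypoxia and siRNA log2 fold-changes, and
summarize regulation per RNA class (box-whisker statistics): coding and
long non-coding classes shift up in hypoxia, the structural small-RNA
classes shift down."""

import pandas as pd

from common import STUDY_DIR, study_config
from hypoxrna.pipeline import run_pipeline

run_pipeline(study_config("express"))
cs = pd.read_csv(STUDY_DIR / "class_summary.tsv", sep="\t")
print(cs.to_string(index=False))
up = cs.loc[cs["median"] > 0, "rna_class"].tolist()
down = cs.loc[cs["median"] < 0, "rna_class"].tolist()
print(f"\nglobally up in hypoxia: {up}")
print(f"globally down in hypoxia: {down}")
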