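"""Assign every annotated feature to one RNA class by priority, divert
ribosomal features, and drop low-abundance transcripts with class-specific
thresholds (higher for the long RNA classes)."""

import pandas as pd

from common import STUDY_DIR, study_config
from hypoxrna.pipeline import run_pipeline

run_pipeline(study_config("classify"))
summary = pd.read_csv(STUDY_DIR / "class_filter_summary.tsv", sep="\t")
print(summary.to_string(index=False))
kept = summary["n_retained"].sum()
print(f"\nretained {kept} non-ribosomal transcripts after abundance filtering")
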