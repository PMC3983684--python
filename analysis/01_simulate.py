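"""Generate the synthetic hypoxia study: genome, multi-class annotation,
condition count matrices, HIF peaks, and coverage tracks, with the planted
truth written alongside for later comparison."""

import pandas as pd

from common import STUDY_DIR, study_config
from hypoxrna.pipeline import run_pipeline

run_pipeline(study_config("simulate"))
truth = pd.read_csv(STUDY_DIR / "truth.tsv", sep="\t")
public = truth[truth["novel_category"] == "."]
novel = truth[truth["novel_category"] != "."]
print(f"wrote study to {STUDY_DIR}")
print(f"public transcripts: {len(public)} "
      f"({public['rna_class'].value_counts().to_dict()})")
print(f"planted novel loci: {len(novel)} "
      f"({novel['novel_category'].value_counts().to_dict()})")
print(f"HIF-dependent transcripts: {(truth['hif_label'] != 'none').sum()} "
      f"(de novo recruitment: {truth['de_novo'].sum()})")
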