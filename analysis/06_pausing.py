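"""RNA polymerase II pausing: metagene profiles around the TSS of the 100
most hypoxia-induced transcripts, the promoter-proximal pause summit,
travelling-ratio shifts for direct HIF targets vs distal controls, and
pause-release vs de novo recruitment calls."""

import json

import pandas as pd

from common import STUDY_DIR, study_config
from hypoxrna.pipeline import run_pipeline

run_pipeline(study_config("pausing"))
mg = pd.read_csv(STUDY_DIR / "metagene.tsv", sep="\t")
pol2 = mg[(mg["mark"] == "RNApol2") & (mg["condition"] == "hypoxia")]
summit = pol2.loc[pol2["value"].idxmax(), "bin_centre"]
print(f"RNApol2 pause summit: {summit:+.0f} bp from the TSS")
shift = json.loads((STUDY_DIR / "tr_shift.json").read_text())
print(f"travelling-ratio shift (hypoxia vs normoxia): "
      f"direct HIF targets median {shift['medians']['direct']:+.2f} log2, "
      f"distal controls {shift['medians']['distal']:+.2f} log2, "
      f"rank-sum p={shift['p_value']:.2e}")
tr = pd.read_csv(STUDY_DIR / "travelling_ratio.tsv", sep="\t")
print("hypoxic induction modes:")
print(tr["mode"].value_counts().to_string())
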