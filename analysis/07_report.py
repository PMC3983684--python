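"""Aggregate all stage outputs into figure-equivalent summary tables."""

import json

from common import STUDY_DIR, study_config
from hypoxrna.pipeline import run_pipeline

run_pipeline(study_config("report"))
report = json.loads((STUDY_DIR / "report.json").read_text())
print(json.dumps(report, indent=2, sort_keys=True))
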