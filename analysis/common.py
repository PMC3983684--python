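"""Shared configuration for the numbered analysis drivers.

Every driver writes into the same study directory (results/study) and can
be rerun independently from its predecessors' on-disk outputs.
"""

from pathlib import Path

from hypoxrna.pipeline import PipelineConfig

STUDY_DIR = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 7


def study_config(*stages: str) -> PipelineConfig:
    cfg = PipelineConfig(outdir=str(STUDY_DIR), seed=SEED)
    if stages:
        cfg.stages = tuple(stages)
    return cfg
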