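"""Shared driver plumbing: one pipeline run reused by the numbered scripts."""

import logging
from pathlib import Path

from cccnet.pipeline import PipelineConfig, run_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def get_run(stages, seed: int = 0):
    logging.basicConfig(level=logging.WARNING)
    cfg = PipelineConfig(out_dir=str(RESULTS), seed=seed)
    return run_pipeline(cfg, stages=stages)
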