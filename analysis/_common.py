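"""Shared configuration for the numbered analysis drivers.

All drivers operate on one pipeline working directory under ``results/``;
each ensures the stages it needs are computed (earlier stages are reused via
the pipeline's stage markers, so the scripts can be run in order or
individually) and prints what it found.
"""

from pathlib import Path

from omicnet.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(outdir=str(RESULTS / "pipeline"), seed=SEED)
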