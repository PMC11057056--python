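"""Shared plumbing for the numbered analysis drivers: one pipeline working
directory under results/, run incrementally (stage outputs are cached, so
each driver only computes its own stage)."""

from pathlib import Path

from sawselect.pipeline import STAGES, PipelineConfig, run_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results"
WORKDIR = RESULTS / "pipeline"


def run_through(stage: str, seed: int = 1) -> PipelineConfig:
    """Run the pipeline up to and including ``stage`` on the shared workdir."""
    upto = STAGES[: STAGES.index(stage) + 1]
    cfg = PipelineConfig(workdir=str(WORKDIR), seed=seed, stages=list(upto))
    report = run_pipeline(cfg)
    done = ", ".join(report.completed) or "(all cached)"
    print(f"stages computed: {done}")
    return cfg
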