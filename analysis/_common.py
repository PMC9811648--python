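"""Shared run configuration for the numbered analysis scripts."""

from pathlib import Path

from vocaldistress.pipeline import PipelineConfig

RUN_DIR = Path(__file__).resolve().parents[1] / "results" / "run"


def config(**overrides) -> PipelineConfig:
    base = dict(out_dir=str(RUN_DIR), seed=0, n_boot=500)
    base.update(overrides)
    return PipelineConfig(**base)
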