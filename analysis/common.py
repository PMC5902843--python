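"""Shared run configuration for the numbered analysis drivers.

All drivers operate on the same pipeline output directory under results/;
each one ensures the stages it depends on are present (up-to-date stages
are skipped by checksum, so re-running a later driver is cheap).
"""

from pathlib import Path

from splicemark.pipeline import RunConfig, run_pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results"
RUN_DIR = RESULTS / "pipeline_run"

RAW_CONFIG = {
    "outdir": str(RUN_DIR),
    "seed": 7,
    "simulate": {"n_genes": 200, "n_celltypes": 6},
    "som": {"nx": 12, "ny": 8, "epochs": 100, "n_perm": 2000},
}


def ensure_stages(*stages: str) -> RunConfig:
    cfg = RunConfig.from_dict({**RAW_CONFIG, "stages": list(stages)})
    run_pipeline(cfg)
    return cfg
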