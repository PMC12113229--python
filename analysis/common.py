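"""Shared plumbing for the numbered analysis scripts.

Every script drives the library through the bundled demo configuration,
writes stage artifacts under ``outputs/`` and publishes result tables
under ``results/``. Pass ``--config`` to use a different YAML.
"""

import argparse
from pathlib import Path

from ecoreserve.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
DEFAULT_CONFIG = ROOT / "src" / "ecoreserve" / "data" / "demo.yaml"
RESULTS = ROOT / "results"


def load_config(argv=None) -> PipelineConfig:
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", type=Path, default=DEFAULT_CONFIG)
    args = ap.parse_args(argv)
    cfg = PipelineConfig.from_yaml(args.config)
    if not Path(cfg.output_dir).is_absolute():
        cfg.output_dir = str(ROOT / cfg.output_dir)
    RESULTS.mkdir(exist_ok=True)
    return cfg
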