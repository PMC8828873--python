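"""Shared paths and configuration for the numbered analysis scripts.

Small derived tables (rankings, diagnostics, group labels, statistics) go to
results/synthetic_study; bulky simulated matrices go to scratch/ (regenerable
from the seed). Every script takes ``--seed`` (default 1); run them in order
from the repository root.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from sig32.config import AnalysisConfig

OUTDIR = Path("results/synthetic_study")  # small tables, kept
BULK = Path("scratch/synthetic_study")  # simulated matrices, regenerable


def get_config() -> AnalysisConfig:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    OUTDIR.mkdir(parents=True, exist_ok=True)
    BULK.mkdir(parents=True, exist_ok=True)
    return AnalysisConfig(seed=args.seed, outdir=OUTDIR)
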