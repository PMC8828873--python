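"""Pipeline configuration: a strictly validated YAML-backed schema.

Every stage parameter lives here; there are no hidden defaults elsewhere.
Library functions keep the literature defaults (1000 permutations, 10,000
bootstrap resamples); the pipeline defaults below are the scaled synthetic
study sizes documented in the methods note.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .synthetic import SimulationDesign

_ICI_PROPORTIONS = (21 / 90, 24 / 90, 14 / 90, 31 / 90)


class AnalysisConfig(BaseModel):
    """All knobs of the end-to-end synthetic analysis."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    outdir: Path = Path("scratch/pipeline")

    # synthetic design overrides (field name -> value in SimulationDesign)
    design: dict = Field(default_factory=dict)

    # pathway discovery
    lambdas: tuple[float, float, float] = (1.0, 1.0, 10.0)
    n_perm: int = 200
    trifactor_max_iter: int = 300
    perm_max_iter: int = 150
    tol: float = 1e-6
    top_n: int = 3
    fdr_cutoff: float = 0.05

    # preprocessing
    coverage_floor: float = 0.8

    # subtype discovery
    k_min: int = 2
    k_max: int = 7
    n_runs: int = 30
    nmf_max_iter: int = 300
    write_consensus: bool = False

    # classifier / risk model
    svm_C: float = 1.0

    # survival layer
    bootstrap_B: int = 200
    ici_n: int = 90
    ici_proportions: tuple[float, float, float, float] = _ICI_PROPORTIONS

    def make_design(self) -> SimulationDesign:
        return SimulationDesign(seed=self.seed, **self.design)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        payload = self.model_dump(mode="json")
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
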