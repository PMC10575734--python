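"""Analysis configuration: the handful of thresholds the pipeline pivots on.

Defaults follow the study conventions this toolkit implements: marker-positive
cells are called at normalized CD36 >= 2.2, the starved-like melanoma cell
(SMC) signature gate sits at an AUCell score >= 0.05, differential lipid
species require fold change >= 1.5 at p <= 0.05, and patients are high risk at
a risk score >= 2 (low risk at <= 1).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    cd36_threshold: float = 2.2
    smc_aucell_threshold: float = 0.05
    aucell_top_fraction: float = 0.05
    fc_cutoff: float = 1.5
    p_cutoff: float = 0.05
    z_high_threshold: float = 0.0
    risk_high_min: int = 2
    risk_low_max: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.aucell_top_fraction < 1:
            raise ValueError("aucell_top_fraction must be in (0, 1)")
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must be > 1")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")
        if self.risk_low_max >= self.risk_high_min:
            raise ValueError("risk_low_max must be < risk_high_min")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
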