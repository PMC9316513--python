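"""Per-variable metadata for mixed questionnaire cohorts.

Each node of the network is either a continuous patient-reported outcome
measure (PROM total score, or a demographic measurement) with a bounded
scale, or a binary demographic variable.  The default variable set models a
post-COVID pain cohort: 13 continuous variables and gender as the single
binary node (coded 0 = male, 1 = female, so that a positive network edge to
gender reads "higher in females").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["VariableMeta", "default_variables", "load_sidecar", "save_sidecar"]


@dataclass(frozen=True)
class VariableMeta:
    """Marginal description of one cohort variable.

    Parameters
    ----------
    name : str
        Variable label (network node name).
    kind : {"continuous", "binary"}
    scale_min, scale_max : float
        Instrument scale bounds; observed values are clipped into them.
    mean, sd : float
        Target marginal moments (continuous variables only).
    positive_rate : float
        P(value == 1) for binary variables.
    decimals : int
        Rounding resolution of the instrument (0 for integer Likert totals).
    """

    name: str
    kind: str
    scale_min: float = 0.0
    scale_max: float = 1.0
    mean: float = 0.0
    sd: float = 1.0
    positive_rate: float = 0.5
    decimals: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"{self.name}: kind must be continuous or binary")
        if not self.scale_min < self.scale_max:
            raise ValueError(f"{self.name}: scale_min must be < scale_max")
        if self.kind == "continuous" and not self.sd > 0:
            raise ValueError(f"{self.name}: sd must be > 0")
        if self.kind == "binary" and not 0 < self.positive_rate < 1:
            raise ValueError(f"{self.name}: positive_rate must be in (0, 1)")

    @property
    def is_binary(self) -> bool:
        return self.kind == "binary"


def default_variables() -> list[VariableMeta]:
    """The 14 default nodes with their reported cohort marginals.

    Gender carries positive_rate 0.532 = P(female) because females are coded 1;
    the male share is 46.8%.  PainDETECT's instrument range starts at -1.
    """
    c = VariableMeta
    return [
        c("age", "continuous", 18, 95, 57.3, 11.7, decimals=0),
        c("gender", "binary", 0, 1, positive_rate=1 - 0.468),
        c("weight", "continuous", 35, 200, 81.8, 17.0, decimals=0),
        c("height", "continuous", 1.30, 2.10, 1.65, 0.10, decimals=2),
        c("duration", "continuous", 3, 36, 18.8, 1.8, decimals=0),
        c("eq5d5l", "continuous", 0, 1, 0.8, 0.2, decimals=3),
        c("paindetect", "continuous", -1, 38, 7.0, 6.2, decimals=0),
        c("slanss", "continuous", 0, 24, 7.5, 8.5, decimals=0),
        c("csi", "continuous", 0, 100, 33.9, 17.2, decimals=0),
        c("hads_a", "continuous", 0, 21, 5.2, 4.2, decimals=0),
        c("hads_d", "continuous", 0, 21, 4.9, 4.3, decimals=0),
        c("pcs", "continuous", 0, 52, 12.3, 12.0, decimals=0),
        c("tsk11", "continuous", 0, 44, 24.0, 8.6, decimals=0),
        c("psqi", "continuous", 0, 21, 8.0, 4.2, decimals=0),
    ]


def save_sidecar(metas: list[VariableMeta], path: str | Path) -> None:
    """Write variable metadata as a YAML (or JSON, by extension) sidecar."""
    path = Path(path)
    payload = {"variables": [asdict(m) for m in metas]}
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_sidecar(path: str | Path) -> list[VariableMeta]:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return [VariableMeta(**entry) for entry in payload["variables"]]
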