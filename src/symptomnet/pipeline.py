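"""End-to-end analysis orchestration with a declarative configuration.

A single :class:`AnalysisConfig` drives cohort input (CSV or synthetic),
estimation, centrality and stability, and every artifact lands under one
output directory:

* ``cohort.csv`` (+ metadata sidecar, synthetic runs only)
* ``correlations.csv`` — the mixed correlation matrix
* ``network.graphml`` / ``adjacency.csv`` — the selected network
* ``centrality.csv`` — raw and scaled indices
* ``stability.json`` — bootstrap CIs, case-dropping summary, CS values
* ``report.json`` — the machine-readable analysis report with a provenance
  block (config hash, seed, package version)

Reports carry no timestamps, so identical config + seed reproduces
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .model import SymptomNetworkModel
from .simulate import DEFAULT_N, generate_cohort, CohortTable
from .stability import DEFAULT_DROP_GRID, StabilityReport, cs_coefficient


class ConfigError(ValueError):
    """Invalid analysis configuration (CLI exit code 2)."""


@dataclass
class AnalysisConfig:
    seed: int | None = None
    input_csv: str | None = None  # None -> synthetic cohort
    sidecar: str | None = None
    synthetic_n: int = DEFAULT_N
    correlation: str = "mixed"
    gamma: float = 0.5
    grid_size: int = 100
    min_ratio: float = 0.01
    run_stability: bool = True
    b_edges: int = 1000
    b_drop: int = 250
    proportions: tuple[float, ...] = DEFAULT_DROP_GRID
    cs_threshold: float = 0.7
    cs_confidence: float = 0.95
    output_dir: str = "symptomnet_out"

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory: every stochastic step must be seeded")
        if self.correlation not in ("mixed", "pearson"):
            raise ConfigError("correlation must be 'mixed' or 'pearson'")
        if not 0 <= self.gamma <= 1:
            raise ConfigError("gamma must be in [0, 1]")
        if self.grid_size < 2:
            raise ConfigError("grid_size must be >= 2")
        if not 0 < self.min_ratio < 1:
            raise ConfigError("min_ratio must be in (0, 1)")
        if self.b_edges < 1 or self.b_drop < 1:
            raise ConfigError("bootstrap replicate counts must be >= 1")
        if any(not 0 < q < 1 for q in self.proportions):
            raise ConfigError("drop proportions must lie in (0, 1)")
        if self.synthetic_n < 2:
            raise ConfigError("synthetic_n must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "proportions" in raw:
            raw["proportions"] = tuple(raw["proportions"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    config: dict
    provenance: dict
    dropped_cases: int
    selected_lambda: float
    ebic: float
    edges: list[dict]
    top_nodes: dict
    centrality: list[dict]
    stability: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True, default=float))


def _load_cohort(config: AnalysisConfig, out: Path) -> CohortTable:
    if config.input_csv is not None:
        return CohortTable.from_csv(config.input_csv, config.sidecar)
    table = generate_cohort(n=config.synthetic_n, seed=config.seed)
    table.to_csv(out / "cohort.csv")
    return table


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute cohort → filter → correlations → network → centrality →
    stability and write every artifact under ``config.output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = _load_cohort(config, out)
    model = SymptomNetworkModel(table, correlation=config.correlation)
    results = model.fit(
        gamma=config.gamma, grid_size=config.grid_size, min_ratio=config.min_ratio
    )

    results.corr.to_csv(out / "correlations.csv")
    results.network.to_graphml(out / "network.graphml")
    results.network.to_adjacency_csv(out / "adjacency.csv")
    cent = results.centrality()
    cent.to_csv(out / "centrality.csv")

    stability_dict: dict = {}
    if config.run_stability:
        edge_boot = results.bootstrap_edges(B=config.b_edges, seed=config.seed)
        drop = results.case_dropping(
            proportions=config.proportions, B=config.b_drop, seed=config.seed
        )
        cs = cs_coefficient(drop, config.cs_threshold, config.cs_confidence)
        report = StabilityReport(edges=edge_boot, case_drop=drop, cs=cs)
        report.to_json(out / "stability.json")
        stability_dict = report.to_dict()

    report = AnalysisReport(
        config=asdict(config),
        provenance={
            "config_hash": config.hash(),
            "seed": config.seed,
            "package": "symptomnet",
            "version": __version__,
        },
        dropped_cases=results.dropped_cases,
        selected_lambda=results.lambda_,
        ebic=float(results.network.ebic_),
        edges=[
            {"a": a, "b": b, "weight": w, "sign_class": s}
            for a, b, w, s in results.network.edges()
        ],
        top_nodes=results.top_nodes(),
        centrality=cent.reset_index().to_dict(orient="records"),
        stability=stability_dict,
    )
    report.to_json(out / "report.json")
    return report
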