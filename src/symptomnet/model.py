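"""Model/Results interface over the network-estimation pipeline.

``SymptomNetworkModel`` holds a cohort (after listwise complete-case
filtering) plus the estimator configuration; ``fit`` runs mixed-correlation
assembly and EBIC-glasso selection and returns a ``SymptomNetworkResults``
carrying the network, the model-selection path, centralities and the
bootstrap stability machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stability as _stability
from .centrality import centrality_table
from .correlations import CorrelationMatrix, complete_case_filter, mixed_matrix
from .glasso import EbicPath, PartialCorrelationNetwork, select_network
from .metadata import VariableMeta, default_variables
from .simulate import CohortTable

__all__ = ["SymptomNetworkModel", "SymptomNetworkResults"]


class SymptomNetworkModel:
    """Regularized partial-correlation network model for a mixed cohort.

    Parameters
    ----------
    table : CohortTable
        Patient-by-variable data with metadata; rows with missing cells are
        removed at construction (the count is kept as ``dropped_cases``).
    correlation : {"mixed", "pearson"}
        "mixed" uses polyserial correlations for binary–continuous pairs,
        "pearson" treats binary codes as numeric (sensitivity mode).
    """

    def __init__(self, table: CohortTable, correlation: str = "mixed"):
        if correlation not in ("mixed", "pearson"):
            raise ValueError("correlation must be 'mixed' or 'pearson'")
        self.table, self.dropped_cases = complete_case_filter(table)
        self.correlation = correlation

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        metas: list[VariableMeta] | None = None,
        correlation: str = "mixed",
    ) -> "SymptomNetworkModel":
        """Build from a DataFrame; defaults to the 14-node variable set."""
        if metas is None:
            metas = [m for m in default_variables() if m.name in data.columns]
        return cls(CohortTable(data[[m.name for m in metas]], metas), correlation)

    @classmethod
    def from_csv(cls, path, sidecar=None, correlation: str = "mixed") -> "SymptomNetworkModel":
        return cls(CohortTable.from_csv(path, sidecar), correlation)

    @property
    def nobs(self) -> int:
        return self.table.n

    @property
    def binary_labels(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.table.metas if m.is_binary)

    def fit(
        self,
        gamma: float = 0.5,
        grid_size: int = 100,
        min_ratio: float = 0.01,
    ) -> "SymptomNetworkResults":
        corr = mixed_matrix(self.table, mode=self.correlation)
        net, path = select_network(
            corr,
            n=self.nobs,
            gamma=gamma,
            grid_size=grid_size,
            min_ratio=min_ratio,
            binary_labels=self.binary_labels,
        )
        settings = {"gamma": gamma, "grid_size": grid_size, "min_ratio": min_ratio}
        return SymptomNetworkResults(self, corr, net, path, settings)


@dataclass
class SymptomNetworkResults:
    """Fitted network plus diagnostics and resampling methods."""

    model: SymptomNetworkModel
    corr: CorrelationMatrix
    network: PartialCorrelationNetwork
    path: EbicPath
    settings: dict

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def dropped_cases(self) -> int:
        return self.model.dropped_cases

    @property
    def lambda_(self) -> float:
        return self.network.lambda_

    def centrality(self) -> pd.DataFrame:
        return centrality_table(self.network)

    def top_nodes(self) -> dict[str, str]:
        """Highest-ranking node per centrality index."""
        tab = self.centrality()
        return {idx: str(tab[idx].idxmax()) for idx in ("strength", "closeness", "betweenness")}

    def bootstrap_edges(self, B: int = 1000, seed: int = 0) -> _stability.EdgeBootstrapResult:
        return _stability.bootstrap_edges(
            self.model.table, B=B, seed=seed, mode=self.model.correlation, **self.settings
        )

    def case_dropping(
        self,
        proportions: tuple[float, ...] = _stability.DEFAULT_DROP_GRID,
        B: int = 250,
        seed: int = 0,
    ) -> _stability.CaseDropResult:
        return _stability.case_dropping(
            self.model.table,
            proportions=proportions,
            B=B,
            seed=seed,
            mode=self.model.correlation,
            **self.settings,
        )

    def cs_coefficient(
        self, result: _stability.CaseDropResult, cor_threshold: float = 0.7,
        confidence: float = 0.95,
    ) -> _stability.CSCoefficient:
        return _stability.cs_coefficient(result, cor_threshold, confidence)

    def plot_stability(self, result: _stability.CaseDropResult, ax=None):
        """Band plot: mean correlation per drop proportion with the
        2.5–97.5% quantile area, one line per centrality index."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        summary = result.summary_frame()
        for name, grp in summary.groupby("index"):
            ax.plot(grp["dropped"], grp["mean"], label=name)
            ax.fill_between(grp["dropped"], grp["q025"], grp["q975"], alpha=0.2)
        ax.set_xlabel("proportion of cases dropped")
        ax.set_ylabel("correlation with full-sample centrality")
        ax.set_ylim(-1.05, 1.05)
        ax.legend()
        return ax

    def summary(self) -> str:
        """Plain-text report: fit header, edge list, centrality ranking."""
        lines = [
            "Regularized Partial Correlation Network",
            "=" * 48,
            f"nodes:              {self.network.p}",
            f"observations:       {self.nobs} (dropped {self.dropped_cases} incomplete)",
            f"correlation mode:   {self.model.correlation}",
            f"selected lambda:    {self.lambda_:.5f}",
            f"EBIC (gamma={self.settings['gamma']}): {self.network.ebic_:.2f}",
            f"edges:              {len(self.network.edges())}",
            "",
            f"{'edge':<28} {'weight':>8}  sign",
            "-" * 48,
        ]
        for a, b, w, sign in sorted(self.network.edges(), key=lambda e: -abs(e[2])):
            lines.append(f"{a + ' -- ' + b:<28} {w:>8.3f}  {sign}")
        tops = self.top_nodes()
        lines += ["", "highest centrality:"]
        for idx, node in tops.items():
            lines.append(f"  {idx:<12} {node}")
        return "\n".join(lines)
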