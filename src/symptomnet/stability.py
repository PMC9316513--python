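"""Bootstrap accuracy and stability of the estimated network.

Two resampling schemes, both re-running the full estimation pipeline
(mixed correlation matrix → EBIC-glasso selection) per replicate:

* nonparametric edge bootstrap — B resamples of n rows with replacement;
  percentile (2.5/97.5) intervals per edge quantify edge-weight accuracy;
* case-dropping (subset) bootstrap — for each drop proportion q, B
  subsamples of ⌈(1−q)·n⌉ rows without replacement; the Pearson correlation
  between each subsample's centrality vector and the full-sample one
  measures how far the sample could shrink before centrality conclusions
  change.

The correlation-stability coefficient summarizes the latter: CS(cor=0.7) is
the largest q such that, at every proportion up to q, at least 95% of
replicates keep that correlation ≥ 0.7.  Values below 0.25 are conventionally
read as unstable, above 0.5 as stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .centrality import betweenness, closeness, strength
from .correlations import mixed_matrix
from .glasso import select_network
from .simulate import CohortTable

__all__ = [
    "EdgeBootstrapResult",
    "CaseDropResult",
    "CSCoefficient",
    "StabilityReport",
    "bootstrap_edges",
    "case_dropping",
    "cs_coefficient",
    "DEFAULT_DROP_GRID",
]

DEFAULT_DROP_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))
INDICES = ("strength", "closeness", "betweenness")


@dataclass(frozen=True)
class EdgeBootstrapResult:
    labels: tuple[str, ...]
    point: np.ndarray  # full-sample edge weights (p × p)
    replicates: np.ndarray  # (B_ok, p, p) weight matrices
    ci_low: np.ndarray
    ci_high: np.ndarray
    B: int
    n_failed: int
    seed: int

    def edge_frame(self) -> pd.DataFrame:
        """One row per node pair: point estimate and bootstrap 95% CI."""
        rows = []
        p = len(self.labels)
        for i in range(p):
            for j in range(i + 1, p):
                rows.append(
                    {
                        "a": self.labels[i],
                        "b": self.labels[j],
                        "weight": self.point[i, j],
                        "ci_low": self.ci_low[i, j],
                        "ci_high": self.ci_high[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CaseDropResult:
    proportions: tuple[float, ...]
    correlations: dict[str, np.ndarray]  # index name -> (len(grid), B); NaN = failed
    B: int
    seed: int

    def summary_frame(self) -> pd.DataFrame:
        """Mean and 2.5/97.5% quantiles of the correlations per proportion."""
        rows = []
        for name in INDICES:
            arr = self.correlations[name]
            for qi, q in enumerate(self.proportions):
                vals = arr[qi][np.isfinite(arr[qi])]
                rows.append(
                    {
                        "index": name,
                        "dropped": q,
                        "mean": vals.mean() if len(vals) else np.nan,
                        "q025": np.quantile(vals, 0.025) if len(vals) else np.nan,
                        "q975": np.quantile(vals, 0.975) if len(vals) else np.nan,
                        "n_ok": len(vals),
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CSCoefficient:
    values: dict[str, float]
    cor_threshold: float = 0.7
    confidence: float = 0.95


@dataclass
class StabilityReport:
    edges: EdgeBootstrapResult | None = None
    case_drop: CaseDropResult | None = None
    cs: CSCoefficient | None = None
    n_failed_drop: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {}
        if self.edges is not None:
            out["edge_bootstrap"] = {
                "B": self.edges.B,
                "n_failed": self.edges.n_failed,
                "seed": self.edges.seed,
                "edges": self.edges.edge_frame().to_dict(orient="records"),
            }
        if self.case_drop is not None:
            out["case_dropping"] = {
                "B": self.case_drop.B,
                "seed": self.case_drop.seed,
                "proportions": list(self.case_drop.proportions),
                "summary": self.case_drop.summary_frame().to_dict(orient="records"),
            }
        if self.cs is not None:
            out["cs_coefficient"] = {
                "cor_threshold": self.cs.cor_threshold,
                "confidence": self.cs.confidence,
                "values": self.cs.values,
            }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


def _fit_weights(table: CohortTable, mode: str, n: int, **settings) -> np.ndarray:
    S = mixed_matrix(table, mode=mode)
    binary = tuple(m.name for m in table.metas if m.is_binary)
    net, _ = select_network(S, n=n, binary_labels=binary, **settings)
    return net.weights


def bootstrap_edges(
    table: CohortTable,
    B: int = 1000,
    seed: int = 0,
    mode: str = "mixed",
    **settings,
) -> EdgeBootstrapResult:
    """Nonparametric bootstrap of the edge weights (percentile 95% CIs).

    Replicates on which estimation fails (e.g. a constant column after
    resampling) are recorded as failed and excluded from the percentiles.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if table.data.isna().any().any():
        raise ValueError("bootstrap requires a complete table; filter first")
    n = table.n
    point = _fit_weights(table, mode, n, **settings)
    rng = np.random.default_rng(seed)
    reps, failed = [], 0
    for _ in range(B):
        rows = rng.integers(0, n, size=n)
        sub = CohortTable(table.data.iloc[rows].reset_index(drop=True), list(table.metas))
        try:
            reps.append(_fit_weights(sub, mode, n, **settings))
        except (ValueError, np.linalg.LinAlgError, RuntimeError):
            failed += 1
    if not reps:
        raise RuntimeError("all bootstrap replicates failed")
    stack = np.stack(reps)
    return EdgeBootstrapResult(
        labels=tuple(table.labels),
        point=point,
        replicates=stack,
        ci_low=np.quantile(stack, 0.025, axis=0),
        ci_high=np.quantile(stack, 0.975, axis=0),
        B=B,
        n_failed=failed,
        seed=seed,
    )


def _centrality_vectors(weights: np.ndarray, labels, lambda_=0.0):
    from .glasso import PartialCorrelationNetwork

    sign = np.empty(weights.shape, dtype=object)
    sign[:] = ""
    net = PartialCorrelationNetwork(tuple(labels), weights, sign, lambda_, float("nan"))
    return {
        "strength": strength(net),
        "closeness": closeness(net),
        "betweenness": betweenness(net),
    }


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan  # constant centrality vector: correlation undefined
    return float(np.corrcoef(a, b)[0, 1])


def case_dropping(
    table: CohortTable,
    proportions: tuple[float, ...] = DEFAULT_DROP_GRID,
    B: int = 250,
    seed: int = 0,
    mode: str = "mixed",
    **settings,
) -> CaseDropResult:
    """Participant-dropping subset bootstrap of the centrality indices.

    For each proportion q the pipeline is re-run on B subsamples of
    ⌈(1−q)·n⌉ rows drawn without replacement; the stored statistic is the
    Pearson correlation between subsample and full-sample raw centralities.
    """
    if table.data.isna().any().any():
        raise ValueError("case_dropping requires a complete table; filter first")
    n = table.n
    p = len(table.metas)
    full = _centrality_vectors(_fit_weights(table, mode, n, **settings), table.labels)
    rng = np.random.default_rng(seed)
    corrs = {name: np.full((len(proportions), B), np.nan) for name in INDICES}
    for qi, q in enumerate(proportions):
        keep = int(np.ceil((1.0 - q) * n))
        if keep < p + 1:
            continue  # subset smaller than the variable count: skipped, left NaN
        for b in range(B):
            rows = rng.choice(n, size=keep, replace=False)
            sub = CohortTable(
                table.data.iloc[rows].reset_index(drop=True), list(table.metas)
            )
            try:
                vecs = _centrality_vectors(
                    _fit_weights(sub, mode, keep, **settings), table.labels
                )
            except (ValueError, np.linalg.LinAlgError, RuntimeError):
                continue
            for name in INDICES:
                corrs[name][qi, b] = _safe_pearson(vecs[name], full[name])
    return CaseDropResult(tuple(proportions), corrs, B, seed)


def cs_coefficient(
    result: CaseDropResult,
    cor_threshold: float = 0.7,
    confidence: float = 0.95,
) -> CSCoefficient:
    """Correlation-stability coefficient per centrality index.

    CS = the largest grid proportion q such that at *every* proportion ≤ q
    at least ``confidence`` of the (non-failed) replicates correlate with the
    full-sample centralities at ≥ ``cor_threshold``; 0 if none qualifies.
    """
    values: dict[str, float] = {}
    for name in INDICES:
        arr = result.correlations[name]
        cs = 0.0
        for qi, q in enumerate(result.proportions):
            vals = arr[qi][np.isfinite(arr[qi])]
            if len(vals) == 0:
                break
            if np.mean(vals >= cor_threshold) >= confidence:
                cs = q
            else:
                break
        values[name] = cs
    return CSCoefficient(values, cor_threshold, confidence)
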