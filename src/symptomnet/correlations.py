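"""Correlation substrate for mixed continuous/binary cohorts.

The graphical lasso consumes a valid (positive semi-definite, unit-diagonal)
correlation matrix.  For a cohort with a single binary node the matrix is
assembled entrywise: Pearson for continuous–continuous pairs and polyserial
for continuous–binary pairs, the latter recovering the latent-scale
correlation under the assumption that the binary variable arises by
thresholding a latent normal.  Point-biserial (Pearson on 0/1 codes)
attenuates that correlation by the factor φ(τ)/√(π₀π₁) — about 0.80 at a
balanced split — which is why the mixed matrix is load-bearing for
recovering edges incident to the binary node.

Rows with any missing cell are removed up front (listwise complete-case
deletion); pairwise handling is deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_ndtr
from statsmodels.stats.correlation_tools import corr_nearest
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .simulate import CohortTable

__all__ = [
    "CorrelationMatrix",
    "complete_case_filter",
    "pearson",
    "polyserial",
    "mixed_matrix",
    "nearest_pd",
]

PSD_EIG_FLOOR = 1e-8
PSD_MAX_ITER = 200


@dataclass(frozen=True)
class CorrelationMatrix:
    """Labeled symmetric correlation matrix with per-entry estimator tags."""

    labels: tuple[str, ...]
    values: np.ndarray
    method: np.ndarray  # dtype=object, entries in {"pearson", "polyserial", ""}

    @property
    def p(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def complete_case_filter(table: CohortTable) -> tuple[CohortTable, int]:
    """Drop every row containing at least one missing cell.

    Returns the filtered table (row order preserved, index reset) and the
    number of rows removed.  Raises if nothing survives.
    """
    keep = table.data.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped == table.n:
        raise ValueError("empty cohort: every record contains a missing cell")
    filtered = table.data.loc[keep].reset_index(drop=True)
    return CohortTable(filtered, list(table.metas)), dropped


def pearson(x: np.ndarray, y: np.ndarray, name_x: str = "x", name_y: str = "y") -> float:
    """Pearson product-moment correlation with explicit degenerate-input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson requires two equal-length vectors of length >= 3")
    for v, name in ((x, name_x), (y, name_y)):
        if np.ptp(v) == 0:
            raise ValueError(f"variable {name!r} is constant; correlation undefined")
    return float(np.clip(stats.pearsonr(x, y).statistic, -1.0, 1.0))


def polyserial(
    x: np.ndarray, y: np.ndarray, name_x: str = "x", name_y: str = "y", tol: float = 1e-6
) -> float:
    """Two-step maximum-likelihood polyserial correlation.

    Step 1 fixes the latent threshold τ = Φ⁻¹(P(y = 0)) from the binary
    marginal.  Step 2 maximizes the conditional log-likelihood
    Σ log P(y_i | x_i; ρ) over ρ ∈ (−0.999, 0.999), with
    P(y=1 | x) = Φ((ρ z − τ)/√(1−ρ²)) and z the standardized x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("polyserial requires two equal-length vectors")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError(
            f"binary variable {name_y!r} must contain both classes coded 0/1, "
            f"found values {classes.tolist()}"
        )
    if np.ptp(x) == 0:
        raise ValueError(f"variable {name_x!r} is constant; correlation undefined")

    z = (x - x.mean()) / x.std(ddof=0)
    tau = stats.norm.ppf(1.0 - y.mean())
    sgn = np.where(y == 1, 1.0, -1.0)  # P(y_i | x_i) = Φ(±(ρz−τ)/√(1−ρ²))

    def negloglik(rho: float) -> float:
        a = (rho * z - tau) / np.sqrt(1.0 - rho * rho)
        return -float(log_ndtr(sgn * a).sum())

    res = optimize.minimize_scalar(
        negloglik, bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)


def _tagged(labels, values, method) -> CorrelationMatrix:
    return CorrelationMatrix(tuple(labels), values, method)


def mixed_matrix(table: CohortTable, mode: str = "mixed") -> CorrelationMatrix:
    """Assemble the correlation matrix feeding the graphical lasso.

    mode="mixed" uses polyserial for binary–continuous pairs; mode="pearson"
    treats the binary 0/1 codes as numeric everywhere (sensitivity mode).
    The assembled matrix is projected to the nearest correlation matrix
    whenever its smallest eigenvalue falls below the PSD floor, which can
    happen because polyserial entries are not jointly constrained.
    """
    if mode not in ("mixed", "pearson"):
        raise ValueError("mode must be 'mixed' or 'pearson'")
    if table.data.isna().any().any():
        raise ValueError("mixed_matrix requires a complete table; filter first")
    p = len(table.metas)
    method = np.empty((p, p), dtype=object)
    method[:] = ""
    cols = [table.data[m.name].to_numpy(dtype=float) for m in table.metas]
    for j, meta in enumerate(table.metas):
        if np.ptp(cols[j]) == 0:
            raise ValueError(f"variable {meta.name!r} is constant; correlation undefined")
    # Pearson for the whole matrix in one pass, then overwrite the
    # binary-continuous entries with polyserial estimates in mixed mode.
    values = np.clip(np.corrcoef(np.column_stack(cols), rowvar=False), -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    for i in range(p):
        for j in range(i + 1, p):
            method[i, j] = method[j, i] = "pearson"
    if mode == "mixed":
        for i, mi in enumerate(table.metas):
            if not mi.is_binary:
                continue
            for j, mj in enumerate(table.metas):
                if mj.is_binary:
                    continue
                r = polyserial(cols[j], cols[i], mj.name, mi.name)
                values[i, j] = values[j, i] = r
                method[i, j] = method[j, i] = "polyserial"
    eigmin = float(np.linalg.eigvalsh(values)[0])
    if eigmin < PSD_EIG_FLOOR:
        values = nearest_pd(values)
    return _tagged([m.name for m in table.metas], values, method)


def nearest_pd(m: np.ndarray) -> np.ndarray:
    """Nearest correlation matrix (Frobenius norm) by alternating projections.

    Unit diagonal is enforced and the smallest eigenvalue is floored at 1e−8;
    inputs already satisfying the floor are returned unchanged.  Raises on
    non-convergence with the residual eigenvalue in the message.
    """
    m = np.asarray(m, dtype=float)
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("nearest_pd requires a symmetric matrix")
    if float(np.linalg.eigvalsh(m)[0]) >= PSD_EIG_FLOOR and np.allclose(
        np.diag(m), 1.0, atol=1e-12
    ):
        return m.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IterationLimitWarning)
        repaired = corr_nearest(m, threshold=PSD_EIG_FLOOR, n_fact=PSD_MAX_ITER)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    eigmin = float(np.linalg.eigvalsh(repaired)[0])
    if eigmin < PSD_EIG_FLOOR * 0.5:
        raise RuntimeError(
            f"nearest correlation projection did not converge: min eigenvalue {eigmin:.3e}"
        )
    return repaired
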