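"""Synthetic cohorts from a planted partial-correlation network.

The generator turns a ground-truth Gaussian graphical model into
questionnaire-like data in three stages:

1. ``sample_latent`` draws i.i.d. multivariate-normal rows whose precision
   matrix has unit diagonal and off-diagonal entries −ρ_ij, so the planted
   values ρ_ij are exactly the model's partial correlations.
2. ``realize_cohort`` maps each latent column onto its instrument: affine
   rescale to the target mean/SD, clip to the scale bounds, round to the
   instrument resolution; the binary variable is produced by thresholding its
   latent column at the empirical quantile that yields the target positive
   rate.  A "continuous" mode skips clipping/rounding/thresholding so that
   all pairwise correlations of the latent draw are preserved exactly.
3. ``inject_missingness`` blanks a fixed number of cells per variable,
   uniformly at random (missing completely at random).

Estimation, centrality and stability stages can then be judged against the
planted network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metadata import VariableMeta, default_variables, load_sidecar, save_sidecar

__all__ = [
    "GroundTruthNetwork",
    "MissingnessSpec",
    "CohortTable",
    "build_ground_truth",
    "default_network",
    "default_missingness",
    "sample_latent",
    "realize_cohort",
    "inject_missingness",
    "generate_cohort",
    "DEFAULT_EDGES",
    "DEFAULT_N",
]

#: The reported eight-edge network over the 14 default nodes: the two
#: neuropathic questionnaires correlate with each other and with central
#: sensitization; sensitization links to anxiety, kinesiophobia and female
#: gender; anxiety to depression; kinesiophobia to catastrophizing; and worse
#: sleep quality to lower quality of life (the single negative edge).
DEFAULT_EDGES: list[tuple[str, str, float]] = [
    ("paindetect", "slanss", 0.388),
    ("paindetect", "csi", 0.207),
    ("csi", "hads_a", 0.269),
    ("csi", "tsk11", 0.165),
    ("csi", "gender", 0.413),
    ("hads_a", "hads_d", 0.598),
    ("tsk11", "pcs", 0.405),
    ("psqi", "eq5d5l", -0.162),
]

#: Default cohort size before complete-case filtering.
DEFAULT_N = 146


class InfeasibleNetworkError(ValueError):
    """The implied precision matrix of a planted network is not positive definite."""


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A planted partial-correlation structure over named nodes."""

    labels: tuple[str, ...]
    partials: np.ndarray  # symmetric, zero diagonal, entries in (-1, 1)

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def precision(self) -> np.ndarray:
        """Implied precision: unit diagonal, off-diagonal κ_ij = −ρ_ij."""
        return np.eye(self.p) - self.partials

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def edge_weight(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.partials[i, j])


@dataclass(frozen=True)
class MissingnessSpec:
    """MCAR missingness: per-variable absolute counts or probabilities."""

    counts: dict[str, int] = field(default_factory=dict)
    probabilities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative missing count for {name}")
        for name, q in self.probabilities.items():
            if not 0 <= q <= 1:
                raise ValueError(f"missing probability for {name} outside [0, 1]")
        overlap = set(self.counts) & set(self.probabilities)
        if overlap:
            raise ValueError(f"variables given both a count and a probability: {overlap}")


@dataclass
class CohortTable:
    """A patient-by-variable table plus its per-variable metadata.

    Missing cells are NaN in the underlying DataFrame.
    """

    data: pd.DataFrame
    metas: list[VariableMeta]

    def __post_init__(self) -> None:
        if list(self.data.columns) != [m.name for m in self.metas]:
            raise ValueError("DataFrame columns do not match metadata names/order")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the cohort as CSV (empty cell = missing) plus a metadata sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False, na_rep="")
        if sidecar is None:
            sidecar = path.with_suffix(".meta.yaml")
        save_sidecar(self.metas, sidecar)

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "CohortTable":
        path = Path(path)
        if sidecar is None:
            sidecar = path.with_suffix(".meta.yaml")
        metas = load_sidecar(sidecar)
        df = pd.read_csv(path)
        return cls(df[[m.name for m in metas]], metas)


def build_ground_truth(
    edges: list[tuple[str, str, float]],
    labels: list[str] | tuple[str, ...],
) -> GroundTruthNetwork:
    """Assemble a planted network from an edge list and verify feasibility.

    Raises
    ------
    InfeasibleNetworkError
        If the implied precision matrix (unit diagonal, −ρ off-diagonal) is
        not positive definite; the message reports the offending spectrum.
    """
    labels = tuple(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("node labels must be distinct")
    index = {lab: i for i, lab in enumerate(labels)}
    p = len(labels)
    partials = np.zeros((p, p))
    seen: set[frozenset[str]] = set()
    for a, b, rho in edges:
        if a not in index or b not in index:
            raise ValueError(f"edge ({a}, {b}) references an unknown label")
        if a == b:
            raise ValueError(f"self-edge on {a}")
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate edge ({a}, {b})")
        seen.add(key)
        if not abs(rho) < 1:
            raise ValueError(f"edge ({a}, {b}): |rho| must be < 1, got {rho}")
        partials[index[a], index[b]] = partials[index[b], index[a]] = rho
    eigvals = np.linalg.eigvalsh(np.eye(p) - partials)
    if eigvals[0] <= 0:
        raise InfeasibleNetworkError(
            "infeasible network: implied precision not positive definite "
            f"(eigenvalues {np.round(eigvals, 4).tolist()})"
        )
    return GroundTruthNetwork(labels, partials)


def default_network() -> GroundTruthNetwork:
    """The eight-edge ground truth over the 14 default nodes."""
    return build_ground_truth(DEFAULT_EDGES, [m.name for m in default_variables()])


def default_missingness() -> MissingnessSpec:
    """Three missing PainDETECT cells and three missing S-LANSS cells."""
    return MissingnessSpec(counts={"paindetect": 3, "slanss": 3})


def sample_latent(gt: GroundTruthNetwork, n: int, seed: int) -> np.ndarray:
    """Draw n i.i.d. multivariate-normal rows with the planted partial structure.

    Mean zero, covariance equal to the inverse of the implied precision.
    Bitwise reproducible for a fixed seed (Cholesky factorization).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(
        np.zeros(gt.p), gt.covariance, size=n, method="cholesky"
    )


def realize_cohort(
    latent: np.ndarray,
    metas: list[VariableMeta],
    mode: str = "questionnaire",
) -> CohortTable:
    """Map latent Gaussian columns onto instrument scales.

    mode="questionnaire" rescales each continuous column to the target
    mean/SD, clips to the scale bounds and rounds to the instrument
    resolution; binary columns are thresholded at the empirical quantile
    giving the target positive rate.  mode="continuous" applies only the
    affine rescale (no clipping, rounding or thresholding), which preserves
    every pairwise Pearson correlation of the latent matrix exactly.
    """
    if mode not in ("questionnaire", "continuous"):
        raise ValueError("mode must be 'questionnaire' or 'continuous'")
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[1] != len(metas):
        raise ValueError(
            f"latent has {latent.shape[1] if latent.ndim == 2 else '?'} columns "
            f"but {len(metas)} variables are described"
        )
    cols: dict[str, np.ndarray] = {}
    for j, meta in enumerate(metas):
        z = latent[:, j]
        z = (z - z.mean()) / z.std(ddof=0)
        if meta.is_binary and mode == "questionnaire":
            cut = np.quantile(z, 1 - meta.positive_rate)
            cols[meta.name] = (z > cut).astype(float)
            continue
        x = meta.mean + meta.sd * z
        if mode == "questionnaire":
            x = np.clip(x, meta.scale_min, meta.scale_max)
            x = np.round(x, meta.decimals)
        cols[meta.name] = x
    return CohortTable(pd.DataFrame(cols), list(metas))


def inject_missingness(
    table: CohortTable, spec: MissingnessSpec, seed: int
) -> CohortTable:
    """Blank cells MCAR: exact per-variable counts (or Binomial draws for
    probability entries), uniformly at random within each column."""
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    n = len(df)
    counts = dict(spec.counts)
    for name, q in spec.probabilities.items():
        counts[name] = int(rng.binomial(n, q))
    for name, count in counts.items():
        if name not in df.columns:
            raise ValueError(f"unknown variable in missingness spec: {name}")
        if count > n:
            raise ValueError(f"missing count for {name} exceeds cohort size {n}")
        rows = rng.choice(n, size=count, replace=False)
        df.iloc[rows, df.columns.get_loc(name)] = np.nan
    return CohortTable(df, list(table.metas))


def generate_cohort(
    n: int = DEFAULT_N,
    seed: int = 0,
    network: GroundTruthNetwork | None = None,
    metas: list[VariableMeta] | None = None,
    missingness: MissingnessSpec | None = None,
    mode: str = "questionnaire",
) -> CohortTable:
    """One-call generator: latent draw → instrument realization → MCAR blanks.

    Defaults emulate the study cohort: 146 records over the 14 default nodes
    with the eight-edge planted network and 3 + 3 missing cells in the two
    neuropathic questionnaires.  Sub-seeds for the latent draw and the
    missingness pattern are derived from ``seed``.
    """
    network = default_network() if network is None else network
    metas = default_variables() if metas is None else metas
    if tuple(m.name for m in metas) != network.labels:
        raise ValueError("metadata names/order do not match network labels")
    missingness = default_missingness() if missingness is None else missingness
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    latent = sample_latent(network, n, int(seeds[0]))
    table = realize_cohort(latent, metas, mode=mode)
    return inject_missingness(table, missingness, int(seeds[1]))


def sample_partial_correlations(x: np.ndarray) -> np.ndarray:
    """Sample partial-correlation matrix from the inverse sample covariance.

    Diagnostic helper used by recovery checks: ρ_ij = −κ_ij/√(κ_ii κ_jj)
    with κ the inverse of the empirical covariance of ``x``.
    """
    k = np.linalg.inv(np.cov(x, rowvar=False))
    d = 1.0 / np.sqrt(np.diag(k))
    r = -k * np.outer(d, d)
    np.fill_diagonal(r, 0.0)
    return r
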