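# Methods

## Model

The cohort is modeled as a Gaussian graphical model (GGM): p = 14 variables
per patient, of which 13 are continuous questionnaire totals or demographic
measurements and one (gender) is binary. Conditional dependence between two
variables given all others is encoded by the precision matrix K = Σ⁻¹: the
partial correlation is ρ_ij = −κ_ij/√(κ_ii κ_jj), and ρ_ij = 0 exactly when
the two variables are conditionally independent. The estimated network's
nodes are the variables and its edge weights the regularized partial
correlations.

The binary node is treated as a thresholded latent normal: an unobserved
continuous trait crosses a cutpoint τ to produce the 0/1 code. Under this
assumption the latent-scale correlation with a continuous variable is
estimable by the polyserial estimator, whereas Pearson on the 0/1 codes
(point-biserial) is attenuated by the factor φ(τ)/√(π₀π₁) ≈ 0.80 at a
balanced split. Edges incident to the binary node are reported with an
"unsigned-categorical" class because the observed-scale direction of a
categorical association is not defined; the numeric weight keeps the
latent-scale sign (gender is coded 0 = male, 1 = female, so a positive
weight reads "higher in females").

## Estimation

1. **Complete-case filter.** Records with any missing cell are removed
   listwise; the dropped count is reported. No imputation or pairwise
   deletion is offered — the modeled workflow drops records.
2. **Correlation matrix.** Pearson for continuous–continuous pairs,
   two-step polyserial for continuous–binary pairs: the threshold is fixed
   at τ = Φ⁻¹(P(y = 0)) from the binary marginal, then the conditional
   log-likelihood Σ log Φ(±(ρz−τ)/√(1−ρ²)) is maximized over
   ρ ∈ (−0.999, 0.999) (bounded scalar minimization, tolerance 1e−6).
   Because the polyserial entries are not jointly constrained with the
   Pearson block, the assembled matrix can fail positive semi-definiteness;
   if its smallest eigenvalue is below 1e−8 it is replaced by the nearest
   correlation matrix (alternating projections via statsmodels
   `corr_nearest`, eigenvalue floor 1e−8, max 200 iterations; failures
   raise). A `pearson`-only mode treats the binary codes as numeric for
   sensitivity analysis.
3. **Graphical lasso.** K̂ maximizes log det K − tr(SK) − λΣ_{i≠j}|K_ij|
   with the diagonal unpenalized. Solver: blockwise coordinate descent on
   the working covariance W (one inner lasso per column, coordinate descent
   with soft-thresholding), convergence when the maximum absolute change in
   K per sweep is < 1e−6, at most 500 sweeps; the inner lasso iterates to
   1e−8. Exact zeros come from the soft-threshold operator; the two column
   solves are averaged and the zero pattern kept symmetric. The whole λ-path
   is solved in a single numba-compiled kernel with warm starts, which is
   what makes the case-dropping bootstrap (thousands of path refits)
   tractable on one CPU.
4. **Model selection.** λ is chosen on a 100-point log-spaced grid from
   λ_max = max_{i≠j}|S_ij| down to 0.01·λ_max by minimizing
   EBIC = −n(log det K − tr(SK)) + E log n + 4γE log p, with E the number
   of upper-triangle nonzeros and γ = 0.5 (the conventional default; the
   likelihood constant convention is irrelevant to selection and tests
   assert invariance to additive shifts). Ties break toward the larger λ
   (sparser model). No post-hoc thresholding is applied beyond the
   penalty's own zeros; consequently at very large n the selected model can
   retain noise-scale edges of order 1/√n — the recovery tests bound these
   at |w| ≤ 0.03 rather than demanding exact support recovery.

## Centrality

Edge length is 1/|w| (strong associations are short); all indices are
sign-blind. Strength is Σ_j |w_ij|. Closeness is 1/Σ_j d(i,j) with the sum
over *reachable* nodes only and 0 for isolated nodes — this keeps values
finite on disconnected networks without switching to harmonic centrality.
Betweenness is the endpoint-excluded Brandes count with fractional credit
for tied shortest paths, normalized by (p−1)(p−2)/2 to a fraction of pairs.
Shortest paths and betweenness use networkx's Dijkstra-based routines
(closeness is summed manually because networkx's closeness implements the
Wasserman–Faust variant, not the 1/Σd rule); the test suite checks both
against an independent exhaustive path-enumeration oracle on networks with
up to 7 nodes. For reporting, each index is min–max scaled to [0, 1]
(an all-equal vector maps to zeros by convention); raw values are always
exported alongside.

## Stability

* **Edge bootstrap** — B = 1000 (default) resamples of n rows with
  replacement; the full pipeline (correlation assembly → EBIC-glasso) is
  re-run per resample and percentile 2.5/97.5 intervals are formed per edge.
  Heavily shrunk edges can have point estimates outside their interval;
  this is reported, not hidden.
* **Case-dropping bootstrap** — for each drop proportion
  q ∈ {0.05, 0.10, …, 0.75}, B subsamples of ⌈(1−q)n⌉ rows *without*
  replacement; the statistic is the Pearson correlation between subsample
  and full-sample raw centrality vectors, per index. B defaults to 250
  (config-exposed up to 1000); the replicate count for this scheme is a
  package choice — only the 1000-iteration edge bootstrap is prescribed by
  the modeled workflow.
* **CS-coefficient** — CS(cor = 0.7) is the largest grid proportion q such
  that at every proportion ≤ q at least 95% of replicates keep the
  correlation ≥ 0.7; 0 if none qualifies. This follows the verbal
  definition directly (maximum droppable proportion retaining > 0.7
  correlation with stated confidence). Replicates on which estimation fails
  (e.g. a constant column after resampling, or a constant centrality vector
  on an empty network) are excluded from the passing fraction with a logged
  count rather than retried, preserving seed determinism.

Both bootstraps are driven by a single numpy `Generator` seeded from the
configuration, so identical config + seed reproduces results exactly
(reports are byte-identical; they carry no timestamps).

## Synthetic cohorts

The generator makes the estimation problem self-validating by planting the
ground truth. A planted network (labels, symmetric ρ matrix) implies the
precision K = I − ρ (unit diagonal, κ_ij = −ρ_ij); construction fails with
the offending spectrum if K is not positive definite rather than silently
repairing it — the default eight-edge network was verified feasible (minimum
eigenvalue 0.285). Because K has unit diagonal, the planted ρ_ij are exactly
the model's partial correlations, so recovery error is directly
interpretable.

Latent rows are i.i.d. N(0, K⁻¹) (Cholesky-based sampling, bitwise
reproducible under a seed). Realization maps each latent column onto its
instrument: affine rescale to the target mean/SD, clip to the scale bounds,
round to the instrument resolution (integers for Likert-type totals; the
quality-of-life index keeps 3 decimals); the binary column is thresholded at
the empirical quantile matching the target positive rate. A *continuous*
mode skips clipping/rounding/thresholding, preserving all pairwise
correlations exactly — recovery tests use it to isolate estimator error
from discretization error. Missingness is MCAR with exact per-variable
counts (default: 3 cells in each of the two neuropathic questionnaires over
146 records, so the complete-case filter typically drops 5–6 records).

Defaults emulate the modeled cohort: n = 146; marginals such as a central
sensitization score of 33.9 ± 17.2 on a 0–100 scale and a 46.8% male share;
the eight planted edges (0.388, 0.207, 0.269, 0.165, 0.413, 0.598, 0.405,
−0.162) spanning the sensory–psychological cluster, the gender–sensitization
link and the single negative sleep-quality–quality-of-life association.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real questionnaire data: marginal skew and
floor effects (truncated Gaussians stand in for genuinely skewed PROM
distributions, so a bounded scale with mean near its floor realizes with a
biased mean), item-level structure, informative missingness, and any
non-Gaussian dependence; only the second-order (partial-correlation)
structure is planted and recovered.

## Problem sizes and numerical choices

Recovery targets use n = 20,000 — large enough that sampling noise
(≈ 1/√n ≈ 0.007) is well inside the ±0.03 tolerance, while the remaining
gap to the planted values is the lasso's shrinkage bias at the selected
λ ≈ 0.02 (all recovered weights sit slightly below the planted magnitudes).
Oracle-equivalence checks run 20 random 3-node penalized-likelihood
problems (brute-force enumeration of sign/zero patterns) and 200 random
≤ 7-node centrality problems (exhaustive path enumeration). The stability
ordering check uses 20 simulated cohorts of n = 141 with B = 100 subsamples
per drop proportion, matching the study scale; strength is expected to be
the most stable index there, and the worked example reproduces the
qualitative pattern (strength CS ≈ 0.3–0.5, closeness/betweenness ≈ 0).

Degenerate inputs: constant columns raise with the offending variable
named; single-class binary columns raise; an all-missing cohort raises
"empty cohort"; λ ≥ λ_max yields the exactly-diagonal precision (the lasso's
full-shrinkage property); an all-equal centrality vector min–max scales to
zeros; subsets smaller than p + 1 rows in the case-dropping scheme are
skipped and logged.

## Known limitations

* Only one binary variable is supported by design; binary–binary pairs fall
  back to Pearson (no polychoric estimator) and ordinal variables are not
  modeled.
* Polyserial entries are estimated marginally, so the assembled matrix
  occasionally needs PSD repair; repair perturbs all entries slightly.
* The EBIC/glasso combination at γ = 0.5 is the conventional default, not a
  statement that the original analysis used exactly these tuning choices;
  γ, grid size and ratio are config-exposed.
* CS-coefficients are grid-valued (resolution 0.05) and depend on the
  replicate budget; values near a grid boundary can move by one step
  between seeds.
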