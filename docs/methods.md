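# Methods

## The marginal model

`trdens` models tract-year retailer counts through a marginal (population-
averaged) specification rather than a joint likelihood: a mean model, a
variance function, and a working correlation.

**Mean.** `mu_it = (pop_it/1000) · exp(x_it' beta_t)`. The offset
`log(pop/1000)` makes `exp(x' beta)` the expected density in retailers per
1000 residents, the scale on which disparities are discussed. Every term is
year-specific (two design columns per covariate, one active per year), so
cross-year change in any group contrast is testable as a linear contrast of
the joint coefficient vector. The licensing indicator, when included,
enters the second year only: no local licensing policy existed at baseline,
so a baseline column would be identically zero.

**Variance.** `mu (1 + alpha·mu)`, the quadratic (NB2) overdispersion
family. It nests Poisson at `alpha = 0`, which keeps the degenerate path
exactly equivalent to an independence Poisson GLM — a property the test
suite checks to 1e-8 against a standard IRLS fit.

**Correlation.** Separable: `R = R_AR(phi) ⊗ R_space(gamma)` over rows
ordered year-major. The spatial factor is a proper CAR structure: precision
`Q = D − gamma·W` on the tract adjacency graph, with the covariance
`Q^{-1}` rescaled to unit diagonal so `gamma` only shapes correlation, not
scale. Writing `Q = D^{1/2}(I − gamma·B)D^{1/2}` with
`B = D^{-1/2} W D^{-1/2}`, whose eigenvalues lie in [−1, 1], gives positive
definiteness for every |gamma| < 1 and, after one eigendecomposition of
`B`, O(n²) access to variances, determinants and correlation factors at any
`gamma`. Isolated tracts receive unit variance and zero correlation. With
two timepoints the AR(1) factor reduces to a single lag-one correlation
`phi`; the five-year gap is one lag.

## Estimation

1. Initialise `beta` at the independence Poisson GLM (statsmodels, offset
   included).
2. Update `alpha` by the moment estimator
   `max(0, Σ((y−mu)² − mu)/mu² / (N − p))`.
3. Update `(gamma, phi)` by maximising the profile Gaussian
   pseudo-log-likelihood of the Pearson residuals under `R(gamma, phi)`
   (variance profiled out), over a 5×5 coarse grid followed by bounded
   L-BFGS-B on (−0.99, 0.99)². The grid guards against local optima; all
   evaluations reuse the cached spectral decomposition and the sparse
   precision, so each costs O(n²).
4. Update `beta` by one Fisher-scoring step of the weighted estimating
   equation with `V = A^{1/2} R A^{1/2}`; the Kronecker identity
   `R^{-1} = R_AR^{-1} ⊗ (S Q S)` (diagonal `S`) means no dense 2n×2n
   matrix is ever formed.
5. Iterate 2-4 until the relative coefficient step falls below 1e-6, with a
   cap of 100 iterations; non-convergence returns a flagged result with a
   warning rather than raising, so callers can inspect the trajectory.

Any of `alpha`, `gamma`, `phi` can be pinned instead of estimated, which is
how the degenerate-equivalence check and structured sensitivity analyses
are run.

**Coefficient covariance.** The analysis treats the whole state as a single
correlated cluster. The textbook robust (sandwich) covariance needs the
outer product of cluster-level scores as its meat, but with one cluster
that outer product is identically zero at the solution, so the empirical
meat is degenerate. The package therefore plugs the estimated working
covariance of the response, `A^{1/2} R(γ̂, φ̂) A^{1/2}`, into the meat,
which collapses the sandwich to the bread inverse `(D' V^{-1} D)^{-1}`
evaluated at the estimated `(alpha, gamma, phi)`. This is exact when the
working structure matches the data-generating covariance and is the
estimator whose calibration the recovery study measures: across 100
replicates at the generating conditions, 95% intervals cover each true
coefficient at close to nominal rate (aggregate ≈ 94-95%). Uncertainty in
the nuisance parameters is not propagated; at ~6300 observations per fit
its contribution is small.

**Inference.** Wald tests throughout: single contrasts report a signed z;
multi-contrast tests are chi-square. Backward elimination drops, one at a
time, the least significant candidate interaction whose joint (2-df,
both year columns) Wald p-value exceeds 0.05, refitting after each drop;
ties break lexicographically; main effects are never candidates. Rate
ratios are `exp(beta)` with `exp(beta ± 1.96·SE)` intervals, reported to
two decimals. Group predictions use the delta method on the log scale and
test the cross-year log-density difference with the joint covariance.

## The synthetic-state generator

The generator emulates the study frame the analysis was designed for: a
statewide system of ~3149 tracts (default 47×67 rook lattice), median
tract population 3535 (log-normal, log-sd 0.45 — only the median is
anchored; the spread is a plausibility choice), group prevalences
26.7% / 4.1% / 31.7% / 42.9% for high-African American / Hispanic /
children / poverty tracts, an urban/suburban/rural split of
31.0 / 45.1 / 23.9, licensing covering 13.7% of tracts in 13 contiguous
urban/suburban "cities", and generating coefficients equal to the fitted
two-year model (gamma 0.3, phi 0.4, alpha 0.3).

* **Covariate clustering.** Each indicator thresholds a graph-smoothed
  Gaussian field (one pass of self-plus-neighbour averaging) at the target
  quantile, so neighbours are positively associated and the empirical
  prevalence equals its target to within 1/n. The smoothing strength is
  fixed: making it tunable would let users silently break the prevalence
  calibration. Percentage columns are a monotone logistic transform of the
  same field anchored so the classification cutoff reproduces the flag
  exactly, keeping the flags auditable from the percentages.
* **Counts via a Gaussian copula.** The analysis model specifies margins
  and correlation, not a conditional data-generating story; the copula is
  the minimal mechanism that imposes exactly the NB2 margins together with
  the separable latent correlation, and it is invertible for testing (the
  latent normals can be returned and checked directly). The NB quantile
  degenerates continuously to the Poisson quantile as `alpha → 0`. Note
  the count-scale correlation is somewhat attenuated relative to the
  latent correlation, so the fitted `(gamma, phi)` estimate the
  count-scale dependence — which is what the working correlation needs —
  rather than the latent values.
* **Licensing cities.** Seeds are drawn in urban/suburban tracts and grown
  by round-robin breadth-first expansion over the urban/suburban subgraph
  until the target coverage is hit, mirroring the observation that
  licensing localities were urban or suburban. Unreachable coverage warns
  and saturates. Licensing flags apply to the second year only.
* **What it does not emulate.** Real tract geography (the lattice has no
  county structure, so rurality is a clustered field rather than a county
  attribute), year-to-year covariate drift (covariates and populations are
  held fixed across the two years), retailer point locations, and
  tract-boundary changes between census vintages. Passing tests therefore
  demonstrate correctness of the statistical machinery under the assumed
  structure, not robustness to real-data artefacts such as geocoding error
  or boundary harmonisation.

## Preparation rules

High/low classification uses ≥15% (African American, Hispanic), ≥25%
(under-18), and strictly >15.4% (poverty — the baseline state poverty
rate; the comparator is deliberately strict where the others are
inclusive, and the boundary behaviour is tested). NCHS county levels map
1 → urban, 2-3 → suburban, 4-6 → rural. Tracts with population below 500,
zero population, or missing poverty in either year are excluded from both
years (single-year exclusion would break the paired design), with one
logged reason per tract in the priority order zero population → below
minimum → missing poverty. Retailer points on a shared tract boundary are
assigned to the lowest tract id — deterministic and order-independent —
and unassigned points are counted, never dropped. A tract is licensed if
contained in a city polygon or if at least half its area (inclusive at
exactly one half) intersects one; overlap is area-weighted, computed with
shapely on planar coordinates.

## Numerical choices and problem sizes

Medians are the midpoint of the two central order statistics. Percent
change is undefined (NaN, "not applicable") at a zero base. Statewide
change is a ratio of aggregate counts to aggregate populations, not a mean
of tract-level changes — the two differ by an order of magnitude on
realistic data. Correlation parameters are bounded at ±0.99; the
dispersion floors at 0. The test and acceptance studies use a 15×15 state
for structural checks, 20×20 / 30×30 states for elimination and recovery
studies (100 replicates), and the full 47×67 = 3149-tract frame for
generator calibration and retention checks — sizes at which each stage's
Monte-Carlo error is small relative to the tolerances being asserted.

## Known limitations

Two timepoints only are exercised end-to-end (the AR machinery is written
for the general lag structure, but nothing else is). Standard errors are
not a reproduction surface: the reference analysis's exact CAR
parameterisation and SE construction are not public, so only point
estimates, significance patterns, and transform arithmetic are anchored.
The one-cluster covariance assumes the working correlation family is rich
enough to capture the true dependence; gross misspecification of the CAR
form would leak into coverage. Dichotomised covariates inherit the usual
loss of information relative to continuous modelling.
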