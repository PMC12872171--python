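"""Marginal negative-binomial model with CAR x AR working correlation.

The model is specified through its first two moments and a working
correlation rather than a joint likelihood.  For tract i in year t, the
retailer count has mean

    mu_it = (pop_it / 1000) * exp(x_it' beta_t)

(so coefficients live on the log TRD-per-1000 scale via the offset
log(pop/1000)), variance mu_it (1 + alpha mu_it) (quadratic
negative-binomial overdispersion, Poisson at alpha = 0), and working
correlation R = R_AR(phi) (x) R_space(gamma): a proper-CAR structure over
the tract adjacency graph crossed with AR(1) over the two years.
Coefficients are year-specific (every covariate effect is allowed to
differ across years); an optional licensing indicator enters the 2022 year
only.

Fitting alternates (i) a moment update of the overdispersion alpha,
(ii) Gaussian pseudo-likelihood maximisation for (gamma, phi) on the
Pearson residuals, and (iii) a Fisher-scoring step for beta solving the
weighted estimating equation with working covariance
V = A^{1/2} R A^{1/2}, A = diag(mu (1 + alpha mu)).  The coefficient
covariance is the one-cluster sandwich with the plug-in working covariance
as the meat, which collapses to the bread inverse (D' V^-1 D)^-1 evaluated
at the estimated (alpha, gamma, phi); see docs/methods.md for why the
empirical one-cluster meat is degenerate.

All linear algebra exploits the Kronecker structure of R, so no dense
2n x 2n matrix is ever formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .correlation import CarStructure

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "FitResult",
    "WaldResult",
    "PredictionRow",
    "RateRatio",
    "build_design",
    "estimate_dispersion",
    "fit_marginal_nb",
    "wald_test",
    "wald_z",
    "simplify_model",
    "rate_ratio",
    "predict_groups",
    "default_prediction_combos",
]

YEARS = (2017, 2022)
DEFAULT_TERMS = (
    "intercept",
    "high_aa",
    "high_hisp",
    "suburban",
    "rural",
    "high_children",
    "high_poverty",
    "poverty_x_children",
)


@dataclass(frozen=True)
class ModelSpec:
    """Covariate layout with year-specific coefficients.

    ``terms`` are shared across years; each term gets one design column per
    year.  ``licensing=True`` (the policy model) adds a licensing main
    effect active in 2022 rows only.  ``interaction_candidates`` lists the
    terms eligible for backward elimination; main effects are never
    dropped.
    """

    terms: tuple = DEFAULT_TERMS
    interaction_candidates: tuple = ("poverty_x_children",)
    licensing: bool = False

    def __post_init__(self):
        unknown = set(self.interaction_candidates) - set(self.terms)
        if unknown:
            raise ValueError(f"interaction candidates not among terms: {sorted(unknown)}")

    @property
    def columns(self) -> tuple:
        cols = [f"{t}:{y}" for y in YEARS for t in self.terms]
        if self.licensing:
            cols.append("licensing:2022")
        return tuple(cols)

    def drop_term(self, term: str) -> "ModelSpec":
        return replace(
            self,
            terms=tuple(t for t in self.terms if t != term),
            interaction_candidates=tuple(t for t in self.interaction_candidates if t != term),
        )


def _term_values(block: pd.DataFrame, term: str) -> np.ndarray:
    if term == "intercept":
        return np.ones(len(block))
    if term == "suburban":
        return (block["rurality"] == "suburban").to_numpy(float)
    if term == "rural":
        return (block["rurality"] == "rural").to_numpy(float)
    if term == "poverty_x_children":
        return (
            block["high_poverty"].astype(bool) & block["high_children"].astype(bool)
        ).to_numpy(float)
    if term == "licensing":
        return block["licensing"].to_numpy(float)
    if term not in block.columns:
        raise ValueError(f"table is missing the flag column for term {term!r}")
    return block[term].to_numpy(float)


@dataclass(frozen=True)
class DesignMatrix:
    """Stacked two-year design with offset and response.

    Rows are ordered year-major (all tracts in 2017, then the same tracts
    in the same order for 2022); ``tracts`` records that order.
    """

    X: np.ndarray
    offset: np.ndarray
    y: np.ndarray
    tracts: tuple
    columns: tuple


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Assemble the stacked design block, offset and response.

    Each term contributes two columns (one active per year); the offset is
    log(population/1000); the response is the retailer count.
    """
    needed = {"tract_id", "year", "population", "retailer_count", "rurality"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    df = table.sort_values(["year", "tract_id"], ignore_index=True)
    tracts = tuple(sorted(df["tract_id"].unique()))
    n = len(tracts)
    blocks = {}
    for year in YEARS:
        block = df[df["year"] == year]
        if len(block) != n or tuple(block["tract_id"]) != tracts:
            raise ValueError(f"every tract must appear exactly once in year {year}")
        blocks[year] = block

    cols = []
    names = list(spec.columns)
    zeros = np.zeros(n)
    for year in YEARS:
        for term in spec.terms:
            v = _term_values(blocks[year], term)
            cols.append(np.concatenate([v, zeros]) if year == 2017 else np.concatenate([zeros, v]))
    if spec.licensing:
        cols.append(np.concatenate([zeros, _term_values(blocks[2022], "licensing")]))
    # reorder produced columns to match spec.columns ordering
    X = np.column_stack(cols)

    pops = np.concatenate([blocks[y]["population"].to_numpy(float) for y in YEARS])
    if np.any(pops <= 0):
        raise ValueError("populations must be positive (filter the table first)")
    offset = np.log(pops / 1000.0)
    y = np.concatenate([blocks[yr]["retailer_count"].to_numpy(float) for yr in YEARS])
    return DesignMatrix(X=X, offset=offset, y=y, tracts=tracts, columns=tuple(names))


def estimate_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int = 0) -> float:
    """Moment estimator of the quadratic overdispersion alpha.

    ``alpha_hat = max(0, sum(((y-mu)^2 - mu)/mu^2) / (N - p))`` under the
    variance model mu (1 + alpha mu); floors at zero.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("means must be strictly positive")
    dof = len(y) - n_params
    if dof <= 0:
        raise ValueError("nonpositive residual degrees of freedom")
    return max(0.0, float(np.sum(((y - mu) ** 2 - mu) / mu**2) / dof))


def _ar_inverse(phi: float) -> np.ndarray:
    return np.array([[1.0, -phi], [-phi, 1.0]]) / (1.0 - phi**2)


def _kron_rinv_apply(car: CarStructure, gamma: float, phi: float, M: np.ndarray) -> np.ndarray:
    """Apply R^{-1} = R_AR^{-1} (x) R_space^{-1} to a (2n, k) matrix."""
    Q, s = car.correlation_inverse_parts(gamma)
    Tinv = _ar_inverse(phi)
    n = car.n
    squeeze = M.ndim == 1
    M2 = M.reshape(2, n, -1)
    SinvM = np.stack([s[:, None] * (Q @ (s[:, None] * M2[t])) for t in range(2)])
    out = np.stack([Tinv[t, 0] * SinvM[0] + Tinv[t, 1] * SinvM[1] for t in range(2)])
    out = out.reshape(M.shape if not squeeze else (2 * n, 1))
    return out.ravel() if squeeze else out


def _profile_pseudo_nll(resid: np.ndarray, car: CarStructure, gamma: float, phi: float) -> float:
    """Negative profile Gaussian pseudo-log-likelihood of Pearson residuals."""
    n2 = resid.size
    quad = float(resid @ _kron_rinv_apply(car, gamma, phi, resid))
    if quad <= 0:
        return np.inf
    logdet = car.n * np.log1p(-phi**2) + 2.0 * car.logdet_correlation(gamma)
    return 0.5 * (n2 * np.log(quad / n2) + logdet)


def _fit_correlation(resid: np.ndarray, car: CarStructure,
                     bound: float = 0.99) -> tuple[float, float]:
    """Maximise the Gaussian pseudo-likelihood over (gamma, phi).

    Coarse grid start, then bounded quasi-Newton refinement on
    (-0.99, 0.99)^2.
    """
    grid = np.array([-0.6, -0.3, 0.0, 0.3, 0.6])
    best, best_val = (0.0, 0.0), np.inf
    for g in grid:
        for p in grid:
            val = _profile_pseudo_nll(resid, car, g, p)
            if val < best_val:
                best, best_val = (g, p), val
    res = optimize.minimize(
        lambda th: _profile_pseudo_nll(resid, car, th[0], th[1]),
        x0=np.array(best),
        method="L-BFGS-B",
        bounds=[(-bound, bound), (-bound, bound)],
    )
    g, p = (res.x if res.fun <= best_val else np.array(best))
    return float(g), float(p)


@dataclass
class FitResult:
    """Fitted marginal model: coefficients, covariance, and nuisance parameters."""

    spec: ModelSpec
    columns: tuple
    beta: np.ndarray
    cov: np.ndarray
    alpha: float
    gamma: float
    phi: float
    n_iterations: int
    converged: bool
    n_tracts: int
    tracts: tuple = field(repr=False, default=())

    def index(self, term: str, year: int) -> int:
        name = f"{term}:{year}"
        if name not in self.columns:
            raise ValueError(f"no design column {name!r}")
        return self.columns.index(name)

    def coef(self, term: str, year: int) -> float:
        return float(self.beta[self.index(term, year)])

    def se(self, term: str, year: int) -> float:
        return float(np.sqrt(self.cov[self.index(term, year), self.index(term, year)]))

    @property
    def beta_2017(self) -> np.ndarray:
        idx = [i for i, c in enumerate(self.columns) if c.endswith(":2017")]
        return self.beta[idx]

    @property
    def beta_2022(self) -> np.ndarray:
        idx = [i for i, c in enumerate(self.columns) if c.endswith(":2022")]
        return self.beta[idx]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for i, col in enumerate(self.columns):
            term, year = col.rsplit(":", 1)
            se = float(np.sqrt(self.cov[i, i]))
            rows.append(
                {
                    "term": term,
                    "year": int(year),
                    "coefficient": float(self.beta[i]),
                    "se": se,
                    "z": float(self.beta[i]) / se if se > 0 else np.nan,
                    "significant": bool(abs(self.beta[i]) > 1.96 * se),
                }
            )
        return pd.DataFrame(rows)


def _poisson_init(design: DesignMatrix) -> np.ndarray:
    fit = sm.GLM(
        design.y, design.X, family=sm.families.Poisson(), offset=design.offset
    ).fit(tol=1e-12)
    return np.asarray(fit.params)


def fit_marginal_nb(
    table: pd.DataFrame,
    graph: nx.Graph,
    spec: ModelSpec | None = None,
    *,
    alpha: float | None = None,
    gamma: float | None = None,
    phi: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    car: CarStructure | None = None,
) -> FitResult:
    """Fit the marginal NB model by iterated estimating equations.

    ``alpha``, ``gamma``, ``phi`` may each be fixed (pass a value) or
    estimated (pass ``None``, the default).  Iterates to a relative
    coefficient change below ``tol`` or ``max_iter`` outer iterations;
    non-convergence returns a result flagged ``converged=False`` with a
    warning rather than raising.  Pass a prebuilt ``car`` structure to
    amortise the graph eigendecomposition across repeated fits on the same
    adjacency (replicated simulations, backward elimination).
    """
    spec = spec or ModelSpec()
    design = build_design(table, spec)
    if car is None:
        car = CarStructure(graph, nodes=list(design.tracts))
    elif tuple(car.nodes) != design.tracts:
        raise ValueError("prebuilt CarStructure node order does not match the table")
    if car.n != len(design.tracts):
        raise ValueError("graph does not match the tract set of the table")

    n_params = design.X.shape[1]
    beta = _poisson_init(design)
    alpha_hat = 0.0 if alpha is None else float(alpha)
    gamma_hat = 0.0 if gamma is None else float(gamma)
    phi_hat = 0.0 if phi is None else float(phi)

    converged = False
    it = 0
    B = None
    for it in range(1, max_iter + 1):
        mu = np.exp(design.X @ beta + design.offset)
        if alpha is None:
            alpha_hat = estimate_dispersion(design.y, mu, n_params)
        a_var = mu * (1.0 + alpha_hat * mu)
        resid = (design.y - mu) / np.sqrt(a_var)
        if gamma is None or phi is None:
            g_est, p_est = _fit_correlation(resid, car)
            if gamma is None:
                gamma_hat = g_est
            if phi is None:
                phi_hat = p_est
        # Fisher-scoring step on the weighted estimating equation
        inv_sd = 1.0 / np.sqrt(a_var)
        M = (mu * inv_sd)[:, None] * design.X  # A^{-1/2} dmu/dbeta
        RinvM = _kron_rinv_apply(car, gamma_hat, phi_hat, M)
        B = M.T @ RinvM
        u = RinvM.T @ (inv_sd * (design.y - mu))
        try:
            step = np.linalg.solve(B, u)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular working information matrix; the CAR x AR working "
                f"covariance at gamma={gamma_hat:.3f}, phi={phi_hat:.3f} is degenerate"
            ) from exc
        beta = beta + step
        if np.linalg.norm(step) < tol * max(1.0, np.linalg.norm(beta)):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"marginal model did not converge in {max_iter} iterations", stacklevel=2
        )

    # covariance at the final parameter values (one-cluster sandwich with
    # plug-in meat = bread inverse; see module docstring)
    mu = np.exp(design.X @ beta + design.offset)
    a_var = mu * (1.0 + alpha_hat * mu)
    inv_sd = 1.0 / np.sqrt(a_var)
    M = (mu * inv_sd)[:, None] * design.X
    RinvM = _kron_rinv_apply(car, gamma_hat, phi_hat, M)
    B = M.T @ RinvM
    cov = np.linalg.inv(B)
    cov = 0.5 * (cov + cov.T)

    return FitResult(
        spec=spec,
        columns=design.columns,
        beta=beta,
        cov=cov,
        alpha=alpha_hat,
        gamma=gamma_hat,
        phi=phi_hat,
        n_iterations=it,
        converged=converged,
        n_tracts=car.n,
        tracts=design.tracts,
    )


@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: int
    p_value: float
    significant: bool
    z: float | None = None  # signed, single-contrast case only


def wald_test(fit: FitResult, contrast) -> WaldResult:
    """Wald test of ``C beta = 0`` for one or more linear contrasts.

    ``contrast`` is a vector (single contrast) or matrix with one row per
    contrast.  The statistic is ``(C b)' (C Cov C')^{-1} (C b)`` referred to
    chi-square; single contrasts also report the signed z value.
    """
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    if C.shape[1] != len(fit.beta):
        raise ValueError(f"contrast has {C.shape[1]} entries, expected {len(fit.beta)}")
    cb = C @ fit.beta
    mid = C @ fit.cov @ C.T
    if np.linalg.matrix_rank(mid) < mid.shape[0]:
        raise np.linalg.LinAlgError("contrast covariance C Cov C' is rank deficient")
    stat = float(cb @ np.linalg.solve(mid, cb))
    df = C.shape[0]
    p = float(stats.chi2.sf(stat, df))
    z = float(cb[0] / np.sqrt(mid[0, 0])) if df == 1 else None
    return WaldResult(statistic=stat, df=df, p_value=p, significant=p < 0.05, z=z)


def wald_z(coefficient: float, se: float) -> WaldResult:
    """Single-coefficient Wald test from a point estimate and its SE."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    if se == 0:
        z = 0.0 if coefficient == 0 else np.inf * np.sign(coefficient)
    else:
        z = coefficient / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return WaldResult(statistic=float(z**2), df=1, p_value=p, significant=p < 0.05, z=float(z))


def _term_contrasts(fit: FitResult, term: str) -> np.ndarray:
    rows = []
    for year in YEARS:
        name = f"{term}:{year}"
        if name in fit.columns:
            c = np.zeros(len(fit.beta))
            c[fit.columns.index(name)] = 1.0
            rows.append(c)
    if not rows:
        raise ValueError(f"term {term!r} not in the fitted model")
    return np.vstack(rows)


def simplify_model(
    table: pd.DataFrame,
    graph: nx.Graph,
    full_spec: ModelSpec,
    *,
    threshold: float = 0.05,
    **fit_kwargs,
) -> ModelSpec:
    """Backward elimination of interaction terms by joint Wald tests.

    Fits the full model, tests each candidate interaction jointly across
    its year-specific columns, drops the least significant nonsignificant
    one (ties broken lexicographically by term name), refits, and repeats
    until every retained candidate is significant.  Main effects are never
    dropped.
    """
    spec = full_spec
    while spec.interaction_candidates:
        fit = fit_marginal_nb(table, graph, spec, **fit_kwargs)
        pvals = {
            term: wald_test(fit, _term_contrasts(fit, term)).p_value
            for term in spec.interaction_candidates
        }
        worst = max(sorted(pvals), key=lambda t: pvals[t])
        if pvals[worst] <= threshold:
            break
        spec = spec.drop_term(worst)
    return spec


@dataclass(frozen=True)
class RateRatio:
    point: float
    lower: float
    upper: float

    def rounded(self, ndigits: int = 2) -> tuple:
        return (round(self.point, ndigits), round(self.lower, ndigits), round(self.upper, ndigits))


def rate_ratio(coefficient: float, se: float) -> RateRatio:
    """Exponentiated coefficient with a 95% Wald interval.

    The multiplicative difference in expected TRD between groups;
    conventionally reported to two decimals.
    """
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    half = 1.96 * se
    return RateRatio(
        point=float(np.exp(coefficient)),
        lower=float(np.exp(coefficient - half)),
        upper=float(np.exp(coefficient + half)),
    )


@dataclass(frozen=True)
class PredictionRow:
    combo: dict
    year: int
    trd: float
    lower: float
    upper: float
    change_significant: bool


def _combo_vector(fit: FitResult, combo: dict, year: int) -> np.ndarray:
    known = {
        "high_aa",
        "high_hisp",
        "high_children",
        "high_poverty",
        "rurality",
        "licensing",
    }
    unknown = set(combo) - known
    if unknown:
        raise ValueError(f"unknown combo keys: {sorted(unknown)}")
    rurality = combo.get("rurality", "urban")
    if rurality not in ("urban", "suburban", "rural"):
        raise ValueError(f"invalid rurality {rurality!r}")
    values = {
        "intercept": 1.0,
        "high_aa": float(combo.get("high_aa", False)),
        "high_hisp": float(combo.get("high_hisp", False)),
        "suburban": float(rurality == "suburban"),
        "rural": float(rurality == "rural"),
        "high_children": float(combo.get("high_children", False)),
        "high_poverty": float(combo.get("high_poverty", False)),
        "poverty_x_children": float(
            combo.get("high_poverty", False) and combo.get("high_children", False)
        ),
        "licensing": float(combo.get("licensing", False)),
    }
    if combo.get("licensing", False) and not fit.spec.licensing:
        raise ValueError("combo requests licensing but the fitted model has no licensing term")
    x = np.zeros(len(fit.beta))
    for i, col in enumerate(fit.columns):
        term, col_year = col.rsplit(":", 1)
        if int(col_year) == year:
            x[i] = values[term]
    return x


def predict_groups(fit: FitResult, combos) -> list[PredictionRow]:
    """Model-predicted TRD per 1000 for covariate combinations, by year.

    Point prediction exp(x' beta_year); 95% interval by the delta method on
    the log scale; the change-significant flag is a Wald test of the
    2022-vs-2017 log-TRD difference using the joint coefficient covariance.
    Licensing in a combo contributes to 2022 only (no policy existed at
    baseline).
    """
    rows = []
    for combo in combos:
        xs = {year: _combo_vector(fit, combo, year) for year in YEARS}
        diff = xs[2022] - xs[2017]
        change = wald_test(fit, diff)
        for year in YEARS:
            x = xs[year]
            eta = float(x @ fit.beta)
            se = float(np.sqrt(x @ fit.cov @ x))
            rows.append(
                PredictionRow(
                    combo=dict(combo),
                    year=year,
                    trd=float(np.exp(eta)),
                    lower=float(np.exp(eta - 1.96 * se)),
                    upper=float(np.exp(eta + 1.96 * se)),
                    change_significant=change.significant,
                )
            )
    return rows


def default_prediction_combos(licensing_model: bool = True) -> list[dict]:
    """Covariate combinations for the group-prediction comparison.

    Children fixed at low prevalence; race/ethnicity collapsed to
    low-AA/low-Hispanic vs high-AA/high-Hispanic; crossed with poverty,
    urban/suburban, and (for the policy model) licensing status.
    """
    combos = []
    lic_levels = (False, True) if licensing_model else (False,)
    for rurality in ("urban", "suburban"):
        for poverty in (False, True):
            for minority in (False, True):
                for lic in lic_levels:
                    combos.append(
                        {
                            "rurality": rurality,
                            "high_poverty": poverty,
                            "high_aa": minority,
                            "high_hisp": minority,
                            "high_children": False,
                            "licensing": lic,
                        }
                    )
    return combos
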