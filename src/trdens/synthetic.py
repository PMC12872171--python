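"""Synthetic tract-system generator.

Generates a state's worth of census-tract data with the statistical
structure the downstream analysis assumes: a rook-contiguity tract
adjacency graph, spatially clustered sociodemographic indicators calibrated
to target prevalences, contiguous licensing "cities" confined to
urban/suburban tracts, and negative-binomial retailer counts for two years
whose log-mean follows the marginal model and whose dependence is a
Gaussian copula with separable CAR (space) x AR(1) (time) correlation.

Default parameter values are the fitted study conditions for Ohio
(~3149 tracts, median tract population ~3535, licensing covering ~13.7%
of tracts in 13 cities); see :class:`SimConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

from .correlation import CarStructure, _check_gamma, _check_phi

__all__ = [
    "SimConfig",
    "make_lattice",
    "sample_covariates",
    "assign_cities",
    "simulate_counts",
    "simulate_state",
    "DEFAULT_PREVALENCE",
    "BETA_2017",
    "BETA_2022",
    "BETA_LICENSING_2022",
]

YEARS = (2017, 2022)

# Fitted Model 1 coefficient columns used as the generating truth
# (order: intercept, high_aa, high_hisp, suburban, rural,
#  high_children, high_poverty, poverty x children).
BETA_2017 = (-0.244, 0.138, 0.221, 0.070, 0.264, -0.325, 0.443, 0.165)
BETA_2022 = (-0.233, 0.101, 0.175, 0.092, 0.306, -0.355, 0.376, 0.248)
# Model 2 licensing main effect (2022 only).
BETA_LICENSING_2022 = -0.104

# Statewide tract prevalences at baseline: fraction of tracts classified
# high for each group, and the urban/suburban/rural split.
DEFAULT_PREVALENCE = {
    "african_american": 0.267,
    "hispanic": 0.041,
    "children": 0.317,
    "poverty": 0.429,
    "urban": 0.310,
    "suburban": 0.451,
    "rural": 0.239,
}

# Classification cutoffs (percent of tract population) used to back out
# percentage columns consistent with the generated flags.
_CUTOFFS = {"african_american": 15.0, "hispanic": 15.0, "children": 25.0, "poverty": 15.4}
_PCT_COLUMNS = {
    "african_american": "pct_african_american",
    "hispanic": "pct_hispanic",
    "children": "pct_under18",
    "poverty": "pct_poverty",
}
_FLAG_COLUMNS = {
    "african_american": "high_aa",
    "hispanic": "high_hisp",
    "children": "high_children",
    "poverty": "high_poverty",
}
_NCHS_FOR_RURALITY = {"urban": 1, "suburban": 2, "rural": 5}


@dataclass(frozen=True)
class SimConfig:
    """All generator knobs.

    Parameters
    ----------
    lattice_rows, lattice_cols
        Dimensions of the rook-contiguity lattice standing in for the tract
        adjacency graph.  47 x 67 = 3149 tracts, the study frame size.
    prevalence_targets
        Target fraction of tracts in each high/low or rurality class.
        Must contain the four group keys plus urban/suburban/rural
        (the latter three summing to 1).
    beta_2017, beta_2022
        Generating coefficients on the log TRD-per-1000 scale, one per
        design term (intercept, high_aa, high_hisp, suburban, rural,
        high_children, high_poverty, poverty x children).
    beta_licensing
        Optional 2022-only licensing main effect; ``None`` leaves licensing
        out of the count model (the licensing flags are still assigned).
    gamma_spatial, phi_temporal
        CAR spatial dependence and AR(1) temporal correlation of the
        latent Gaussian copula, both strictly inside (-1, 1).
    dispersion
        Negative-binomial overdispersion alpha >= 0 in the variance
        mu * (1 + alpha * mu); 0 degenerates to Poisson.
    licensing_coverage
        Target fraction of tracts carrying a local licensing policy (2022
        only; none existed at baseline).
    n_cities
        Number of contiguous licensing patches.
    population_median
        Median tract population of the log-normal population draw
        (log-scale sd fixed at 0.45).
    seed
        Base seed; every generator operation derives its stream from it.
    """

    lattice_rows: int = 47
    lattice_cols: int = 67
    prevalence_targets: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    beta_2017: tuple = BETA_2017
    beta_2022: tuple = BETA_2022
    beta_licensing: float | None = None
    gamma_spatial: float = 0.3
    phi_temporal: float = 0.4
    dispersion: float = 0.3
    licensing_coverage: float = 0.137
    n_cities: int = 13
    population_median: float = 3535.0
    seed: int = 0

    def __post_init__(self):
        if self.lattice_rows < 1 or self.lattice_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        _check_gamma(self.gamma_spatial)
        _check_phi(self.phi_temporal)
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if not 0 <= self.licensing_coverage <= 1:
            raise ValueError("licensing_coverage must be in [0, 1]")
        for key, value in self.prevalence_targets.items():
            if not 0 <= value <= 1:
                raise ValueError(f"prevalence target {key!r}={value} outside [0, 1]")
        missing = (set(_CUTOFFS) | {"urban", "suburban", "rural"}) - set(self.prevalence_targets)
        if missing:
            raise ValueError(f"prevalence_targets missing keys: {sorted(missing)}")
        rsum = sum(self.prevalence_targets[k] for k in ("urban", "suburban", "rural"))
        if abs(rsum - 1.0) > 1e-6:
            raise ValueError(f"urban+suburban+rural targets must sum to 1, got {rsum}")
        if len(self.beta_2017) != 8 or len(self.beta_2022) != 8:
            raise ValueError("beta vectors must have 8 entries (one per design term)")
        if self.n_cities < 1:
            raise ValueError("n_cities must be positive")
        if self.population_median <= 0:
            raise ValueError("population_median must be positive")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # each stage gets its own derived stream so adding a stage never
    # perturbs the draws of another
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def make_lattice(rows: int, cols: int) -> nx.Graph:
    """Rook-contiguity graph on a rows x cols lattice.

    Nodes are zero-padded string ids in row-major order; the edge count is
    ``2*rows*cols - rows - cols``.
    """
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")
    width = max(5, len(str(rows * cols - 1)))

    def tid(r, c):
        return f"T{r * cols + c:0{width}d}"

    g = nx.Graph()
    g.add_nodes_from(tid(r, c) for r in range(rows) for c in range(cols))
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                g.add_edge(tid(r, c), tid(r, c + 1))
            if r + 1 < rows:
                g.add_edge(tid(r, c), tid(r + 1, c))
    return g


def _smooth(graph_csr, values: np.ndarray, degree: np.ndarray) -> np.ndarray:
    # one-pass neighbourhood average (self plus neighbours) -> positive
    # spatial association of whatever gets thresholded downstream
    return (values + graph_csr @ values) / (1.0 + degree)


def _clustered_field(car: CarStructure, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(car.n)
    degree = np.asarray(car.W.sum(axis=1)).ravel()
    return _smooth(car.W, z, degree)


def _pct_from_field(field_vals: np.ndarray, k_high: int, cutoff_pct: float,
                    scale: float = 1.2) -> np.ndarray:
    """Monotone map of a latent field to percentages such that exactly
    ``k_high`` tracts exceed ``cutoff_pct``."""
    n = field_vals.size
    order = np.argsort(field_vals)[::-1]
    if k_high <= 0:
        thresh = field_vals.max() + 1.0
    elif k_high >= n:
        thresh = field_vals.min() - 1.0
    else:
        thresh = 0.5 * (field_vals[order[k_high - 1]] + field_vals[order[k_high]])
    sd = field_vals.std()
    if sd == 0:
        sd = 1.0
    logit_cut = special.logit(cutoff_pct / 100.0)
    return 100.0 * special.expit(logit_cut + scale * (field_vals - thresh) / sd)


def sample_covariates(n_tracts: int, config: SimConfig, graph: nx.Graph | None = None) -> pd.DataFrame:
    """Draw spatially clustered sociodemographic covariates for both years.

    Each indicator comes from thresholding a graph-smoothed Gaussian field
    at the target quantile, so neighbours are positively associated and the
    empirical prevalence equals the target to within rounding (1/n).
    Percentage columns are a monotone transform of the same field, so the
    classification cutoffs reproduce the flags exactly.  Covariates and
    populations are held fixed across the two years (rurality is
    county-level and time-constant by construction; the sociodemographic
    drift over five years is small relative to the cross-sectional
    contrasts being modelled).

    Returns a tract-year table (two rows per tract) with populations,
    percentage columns, high/low flags, NCHS level and rurality; licensing
    and retailer counts are filled by later stages.
    """
    if n_tracts < 1:
        raise ValueError("n_tracts must be positive")
    if graph is None:
        if config.lattice_rows * config.lattice_cols != n_tracts:
            raise ValueError(
                f"n_tracts={n_tracts} does not match lattice "
                f"{config.lattice_rows}x{config.lattice_cols}; pass a graph explicitly"
            )
        graph = make_lattice(config.lattice_rows, config.lattice_cols)
    elif graph.number_of_nodes() != n_tracts:
        raise ValueError("graph size does not match n_tracts")

    car = CarStructure(graph)
    rng = _rng(config, stage=0)
    n = car.n

    pct = {}
    for group in ("african_american", "hispanic", "children", "poverty"):
        target = config.prevalence_targets[group]
        fvals = _clustered_field(car, rng)
        k = int(round(target * n))
        pct[group] = _pct_from_field(fvals, k, _CUTOFFS[group])

    # rurality: one clustered field cut at the target quantiles
    # (high end = urban core, low end = rural periphery)
    rural_field = _clustered_field(car, rng)
    k_urban = int(round(config.prevalence_targets["urban"] * n))
    k_rural = int(round(config.prevalence_targets["rural"] * n))
    k_rural = min(k_rural, n - k_urban)
    order = np.argsort(rural_field)[::-1]
    rurality = np.full(n, "suburban", dtype=object)
    rurality[order[:k_urban]] = "urban"
    if k_rural > 0:
        rurality[order[n - k_rural:]] = "rural"

    population = np.maximum(
        1,
        np.round(
            np.exp(np.log(config.population_median) + 0.45 * rng.standard_normal(n))
        ).astype(int),
    )

    base = pd.DataFrame({"tract_id": car.nodes, "population": population})
    for group, col in _PCT_COLUMNS.items():
        base[col] = pct[group]
        cutoff = _CUTOFFS[group]
        strict = group == "poverty"  # poverty cutoff is strict ">"
        base[_FLAG_COLUMNS[group]] = (
            base[col] > cutoff if strict else base[col] >= cutoff
        )
    base["rurality"] = rurality
    base["nchs_level"] = base["rurality"].map(_NCHS_FOR_RURALITY).astype(int)

    rows = []
    for year in YEARS:
        block = base.copy()
        block.insert(1, "year", year)
        rows.append(block)
    table = pd.concat(rows, ignore_index=True)
    table["licensing"] = False
    table["retailer_count"] = 0
    return table.sort_values(["year", "tract_id"], ignore_index=True)


def assign_cities(table: pd.DataFrame, graph: nx.Graph, config: SimConfig) -> pd.DataFrame:
    """Flag contiguous licensing "cities" grown inside urban/suburban tracts.

    ``n_cities`` seeds are placed in urban or suburban tracts and grown by
    round-robin breadth-first expansion over the urban/suburban subgraph
    until the flagged fraction reaches ``licensing_coverage``.  Licensing
    applies to the 2022 rows only (no local licensing existed at baseline).
    If the target coverage exceeds the urban+suburban share, a warning is
    issued and every eligible tract is flagged.
    """
    if "rurality" not in table.columns:
        raise ValueError("rurality must be assigned before licensing cities")
    rng = _rng(config, stage=1)
    tracts = sorted(table["tract_id"].unique())
    if set(tracts) != set(graph.nodes):
        raise ValueError("graph nodes do not match table tracts")
    n = len(tracts)
    rural_by_tract = (
        table.drop_duplicates("tract_id").set_index("tract_id")["rurality"]
    )
    eligible = {t for t in tracts if rural_by_tract[t] != "rural"}
    target_k = int(round(config.licensing_coverage * n))

    flagged: set = set()
    if target_k > 0:
        if target_k > len(eligible):
            warnings.warn(
                f"licensing coverage {config.licensing_coverage:.3f} unreachable: only "
                f"{len(eligible)}/{n} tracts are urban/suburban; flagging all of them",
                stacklevel=2,
            )
            target_k = len(eligible)
        pool = sorted(eligible)
        n_seeds = min(config.n_cities, target_k, len(pool))
        seeds = list(rng.choice(pool, size=n_seeds, replace=False))
        frontiers = []
        for s in seeds:
            flagged.add(s)
            frontiers.append([s])
        # round-robin growth keeps city sizes comparable and each patch
        # contiguous within the urban/suburban subgraph
        active = list(range(len(seeds)))
        while len(flagged) < target_k:
            progressed = False
            for ci in list(active):
                if len(flagged) >= target_k:
                    break
                frontier = frontiers[ci]
                grown = False
                while frontier and not grown:
                    candidates = [
                        v
                        for v in graph.neighbors(frontier[0])
                        if v in eligible and v not in flagged
                    ]
                    if candidates:
                        pick = candidates[int(rng.integers(len(candidates)))]
                        flagged.add(pick)
                        frontier.append(pick)
                        grown = True
                        progressed = True
                    else:
                        frontier.pop(0)
                if not frontier and not grown:
                    active.remove(ci)
            if not progressed:
                # all patches exhausted their components; reseed if possible
                remaining = sorted(eligible - flagged)
                if not remaining:
                    warnings.warn(
                        "licensing coverage unreachable with the available "
                        f"urban/suburban tracts; achieved {len(flagged) / n:.3f}",
                        stacklevel=2,
                    )
                    break
                s = remaining[int(rng.integers(len(remaining)))]
                flagged.add(s)
                frontiers.append([s])
                active.append(len(frontiers) - 1)

    out = table.copy()
    out["licensing"] = (out["tract_id"].isin(flagged)) & (out["year"] == 2022)
    return out


def _design_row_values(block: pd.DataFrame) -> np.ndarray:
    """Per-tract design matrix for the 8 generator terms (single year)."""
    x = np.column_stack(
        [
            np.ones(len(block)),
            block["high_aa"].to_numpy(float),
            block["high_hisp"].to_numpy(float),
            (block["rurality"] == "suburban").to_numpy(float),
            (block["rurality"] == "rural").to_numpy(float),
            block["high_children"].to_numpy(float),
            block["high_poverty"].to_numpy(float),
            (block["high_poverty"] & block["high_children"]).to_numpy(float),
        ]
    )
    return x


def _nb_ppf(u: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Quantile of the count margin with mean mu, variance mu(1+alpha*mu).

    Continuous in alpha: degenerates to the Poisson quantile at alpha = 0.
    """
    if alpha < 1e-12:
        return stats.poisson.ppf(u, mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return stats.nbinom.ppf(u, size, p)


def simulate_counts(
    table: pd.DataFrame,
    graph: nx.Graph,
    config: SimConfig,
    return_latent: bool = False,
):
    """Fill retailer counts for both years via a Gaussian copula.

    A zero-mean Gaussian vector with separable correlation
    ``R_AR(phi) (x) R_space(gamma)`` is pushed through the standard normal
    CDF and the negative-binomial quantile with mean
    ``mu_it = (pop_it / 1000) * exp(x_it' beta_t)`` and variance
    ``mu_it (1 + alpha mu_it)``, so the margins are exactly those of the
    fitted marginal model while the dependence mirrors its working
    correlation.

    With ``return_latent=True`` also returns the (n_tracts, 2) latent
    normal draw, which is useful for validating the copula itself.
    """
    gamma = _check_gamma(config.gamma_spatial)
    phi = _check_phi(config.phi_temporal)
    tracts = sorted(table["tract_id"].unique())
    if set(tracts) != set(graph.nodes):
        raise ValueError("graph nodes do not match table tracts")
    required = {"high_aa", "high_hisp", "high_children", "high_poverty", "rurality", "population"}
    if not required <= set(table.columns):
        raise ValueError(f"table missing covariate columns: {sorted(required - set(table.columns))}")

    car = CarStructure(graph, nodes=tracts)
    rng = _rng(config, stage=2)
    n = car.n

    out = table.sort_values(["year", "tract_id"], ignore_index=True)
    blocks = {year: out[out["year"] == year] for year in YEARS}
    for year in YEARS:
        if len(blocks[year]) != n:
            raise ValueError(f"expected one row per tract for year {year}")

    betas = {2017: np.asarray(config.beta_2017), 2022: np.asarray(config.beta_2022)}
    mus = {}
    for year in YEARS:
        block = blocks[year]
        eta = _design_row_values(block) @ betas[year]
        if config.beta_licensing is not None and year == 2022:
            eta = eta + config.beta_licensing * block["licensing"].to_numpy(float)
        mus[year] = (block["population"].to_numpy(float) / 1000.0) * np.exp(eta)

    # latent normals: Z = F_space @ E @ L_ar', giving cov R_AR (x) R_space
    F = car.correlation_factor(gamma)
    E = rng.standard_normal((n, 2))
    L_ar = np.array([[1.0, 0.0], [phi, np.sqrt(1.0 - phi**2)]])
    Z = (F @ E) @ L_ar.T

    counts = np.empty((n, 2))
    for j, year in enumerate(YEARS):
        u = stats.norm.cdf(Z[:, j])
        counts[:, j] = _nb_ppf(u, mus[year], config.dispersion)

    out.loc[out["year"] == 2017, "retailer_count"] = counts[:, 0].astype(int)
    out.loc[out["year"] == 2022, "retailer_count"] = counts[:, 1].astype(int)
    if return_latent:
        return out, Z
    return out


def simulate_state(config: SimConfig):
    """Run the full generator chain: lattice -> covariates -> cities -> counts.

    Returns ``(table, graph)`` ready for the preparation and modelling
    stages.
    """
    graph = make_lattice(config.lattice_rows, config.lattice_cols)
    table = sample_covariates(graph.number_of_nodes(), config, graph=graph)
    table = assign_cities(table, graph, config)
    table = simulate_counts(table, graph, config)
    return table, graph
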