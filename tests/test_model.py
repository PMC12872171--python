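"""Marginal NB model: design, dispersion, fitting, Wald inference, predictions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import trdens as td
from trdens.correlation import CarStructure
from trdens.model import ModelSpec, _term_contrasts, build_design


def _intercept_table(counts, pops):
    rows = []
    for year in (2017, 2022):
        for i, (c, p) in enumerate(zip(counts, pops)):
            rows.append(
                {"tract_id": f"t{i}", "year": year, "population": p, "retailer_count": c,
                 "high_aa": False, "high_hisp": False, "high_children": False,
                 "high_poverty": False, "rurality": "urban", "licensing": False}
            )
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_reference_tract_row(self, state_15x15):
        table, _, _ = state_15x15
        design = build_design(table, ModelSpec())
        i = design.tracts.index(table["tract_id"].iloc[0])
        # find a reference tract: urban, all flags low
        block = table[table["year"] == 2017].sort_values("tract_id").reset_index(drop=True)
        ref = block[(block["rurality"] == "urban") & ~block["high_aa"] & ~block["high_hisp"]
                    & ~block["high_children"] & ~block["high_poverty"]]
        assert len(ref) > 0
        i = ref.index[0]
        row = design.X[i]
        cols = list(design.columns)
        assert row[cols.index("intercept:2017")] == 1.0
        assert row.sum() == 1.0  # nothing else set

    def test_interaction_column_is_product(self, state_15x15):
        table, _, _ = state_15x15
        design = build_design(table, ModelSpec())
        cols = list(design.columns)
        pov = design.X[:, cols.index("high_poverty:2017")]
        kid = design.X[:, cols.index("high_children:2017")]
        inter = design.X[:, cols.index("poverty_x_children:2017")]
        np.testing.assert_array_equal(inter, pov * kid)

    def test_offset_is_log_pop_per_1000(self):
        table = _intercept_table([1, 2], [1000, 2000])
        design = build_design(table, ModelSpec(terms=("intercept",), interaction_candidates=()))
        assert design.offset[0] == 0.0
        assert design.offset[1] == pytest.approx(np.log(2.0))

    def test_licensing_column_2022_only(self, state_15x15):
        table, _, _ = state_15x15
        design = build_design(table, ModelSpec(licensing=True))
        n = len(design.tracts)
        lic = design.X[:, list(design.columns).index("licensing:2022")]
        assert lic[:n].sum() == 0.0
        assert lic[n:].sum() > 0

    def test_missing_flags_rejected(self, state_15x15):
        table, _, _ = state_15x15
        with pytest.raises(ValueError):
            build_design(table.drop(columns=["high_aa"]), ModelSpec())


class TestEstimateDispersion:
    def test_exact_fit_gives_zero(self):
        mu = np.linspace(0.5, 5, 50)
        assert td.estimate_dispersion(mu.copy(), mu, 3) == 0.0

    def test_poisson_null_near_zero(self):
        rng = np.random.default_rng(5)
        mu = np.full(10_000, 2.0)
        y = rng.poisson(mu)
        assert abs(td.estimate_dispersion(y, mu, 1)) < 0.02

    def test_nb_alpha_recovery(self):
        rng = np.random.default_rng(8)
        alpha = 0.5
        mu = np.full(10_000, 3.0)
        size = 1.0 / alpha
        y = rng.negative_binomial(size, size / (size + mu))
        assert td.estimate_dispersion(y, mu, 1) == pytest.approx(alpha, abs=0.1)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            td.estimate_dispersion(np.ones(3), np.array([1.0, 0.0, 1.0]))


class TestFit:
    def test_intercept_only_closed_form(self):
        table = _intercept_table([2, 0, 4], [1000, 2000, 1000])
        graph = td.make_lattice(1, 3)
        mapping = dict(zip(sorted(table["tract_id"].unique()), sorted(graph.nodes)))
        table["tract_id"] = table["tract_id"].map(mapping)
        spec = ModelSpec(terms=("intercept",), interaction_candidates=())
        fit = td.fit_marginal_nb(table, graph, spec, alpha=0.0, gamma=0.0, phi=0.0)
        # score equation solution: beta0 = log(sum y / sum pop/1000) per year
        assert fit.coef("intercept", 2017) == pytest.approx(np.log(6 / 4), abs=1e-8)
        assert fit.coef("intercept", 2022) == pytest.approx(np.log(6 / 4), abs=1e-8)

    def test_degenerate_matches_poisson_glm(self, state_15x15):
        table, graph, _ = state_15x15
        spec = ModelSpec()
        fit = td.fit_marginal_nb(table, graph, spec, alpha=0.0, gamma=0.0, phi=0.0)
        design = build_design(table, spec)
        oracle = sm.GLM(design.y, design.X, family=sm.families.Poisson(),
                        offset=design.offset).fit(tol=1e-12)
        np.testing.assert_allclose(fit.beta, oracle.params, atol=1e-8)

    def test_estimated_structure_parameters_in_range(self, state_15x15):
        table, graph, config = state_15x15
        fit = td.fit_marginal_nb(table, graph)
        assert fit.converged
        assert abs(fit.gamma) < 1 and abs(fit.phi) < 1 and fit.alpha >= 0
        cov = fit.cov
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_graph_mismatch_rejected(self, state_15x15):
        table, _, _ = state_15x15
        with pytest.raises(ValueError):
            td.fit_marginal_nb(table, td.make_lattice(4, 4))


class TestWald:
    def test_z_from_printed_estimates(self):
        w = td.wald_z(0.138, 0.045)
        assert w.z == pytest.approx(3.07, abs=0.01)
        assert w.significant
        w2 = td.wald_z(-0.104, 0.060)
        assert w2.z == pytest.approx(-1.73, abs=0.01)
        assert not w2.significant

    def test_zero_coefficient(self):
        w = td.wald_z(0.0, 0.2)
        assert w.z == 0.0 and w.p_value == 1.0 and not w.significant

    def test_joint_contrast_on_fit(self, state_15x15):
        table, graph, _ = state_15x15
        fit = td.fit_marginal_nb(table, graph, alpha=0.0, gamma=0.0, phi=0.0)
        C = _term_contrasts(fit, "high_poverty")
        w = td.wald_test(fit, C)
        assert w.df == 2 and w.statistic >= 0 and 0 <= w.p_value <= 1

    def test_rank_deficient_contrast_rejected(self, state_15x15):
        table, graph, _ = state_15x15
        fit = td.fit_marginal_nb(table, graph, alpha=0.0, gamma=0.0, phi=0.0)
        c = np.zeros(len(fit.beta))
        c[0] = 1.0
        with pytest.raises(np.linalg.LinAlgError):
            td.wald_test(fit, np.vstack([c, c]))

    def test_contrast_dimension_checked(self, state_15x15):
        table, graph, _ = state_15x15
        fit = td.fit_marginal_nb(table, graph, alpha=0.0, gamma=0.0, phi=0.0)
        with pytest.raises(ValueError):
            td.wald_test(fit, np.ones(3))


class TestRateRatio:
    @pytest.mark.parametrize("coef,expected", [(0.138, 1.15), (0.0, 1.00), (0.306, 1.36)])
    def test_point_estimates(self, coef, expected):
        assert round(td.rate_ratio(coef, 0.05).point, 2) == expected

    def test_interval(self):
        rr = td.rate_ratio(0.1, 0.05)
        assert rr.lower == pytest.approx(np.exp(0.1 - 1.96 * 0.05))
        assert rr.upper == pytest.approx(np.exp(0.1 + 1.96 * 0.05))
        assert rr.lower <= rr.point <= rr.upper

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            td.rate_ratio(0.1, -0.1)


class TestSimplify:
    def test_empty_candidates_unchanged(self, state_15x15):
        table, graph, _ = state_15x15
        spec = ModelSpec(interaction_candidates=())
        assert td.simplify_model(table, graph, spec) == spec

    def test_null_interaction_dropped(self):
        # no true interaction: candidate should be eliminated ~95% of runs
        graph = td.make_lattice(20, 20)
        car = CarStructure(graph)
        beta17 = list(td.synthetic.BETA_2017)
        beta22 = list(td.synthetic.BETA_2022)
        beta17[7] = beta22[7] = 0.0
        dropped = 0
        reps = 20
        for rep in range(reps):
            config = td.SimConfig(
                lattice_rows=20, lattice_cols=20, seed=500 + rep,
                beta_2017=tuple(beta17), beta_2022=tuple(beta22),
            )
            table = td.sample_covariates(400, config, graph=graph)
            table = td.assign_cities(table, graph, config)
            table = td.simulate_counts(table, graph, config)
            spec = td.simplify_model(table, graph, ModelSpec(), car=car)
            if "poverty_x_children" not in spec.terms:
                dropped += 1
        assert dropped >= int(0.8 * reps)

    def test_true_interaction_retained_at_frame_size(self):
        # at the study's tract count the interaction is well powered
        graph = td.make_lattice(47, 67)
        car = CarStructure(graph)
        retained = 0
        reps = 3
        for rep in range(reps):
            config = td.SimConfig(seed=900 + rep)
            table = td.sample_covariates(3149, config, graph=graph)
            table = td.assign_cities(table, graph, config)
            table = td.simulate_counts(table, graph, config)
            spec = td.simplify_model(table, graph, ModelSpec(), car=car)
            if "poverty_x_children" in spec.terms:
                retained += 1
        assert retained >= reps - 1


class TestPredict:
    def test_reference_combo_is_exp_intercept(self, state_15x15):
        table, graph, _ = state_15x15
        fit = td.fit_marginal_nb(table, graph)
        rows = td.predict_groups(fit, [{"rurality": "urban"}])
        for row in rows:
            b0 = fit.coef("intercept", row.year)
            se = fit.se("intercept", row.year)
            assert row.trd == pytest.approx(np.exp(b0))
            assert row.lower == pytest.approx(np.exp(b0 - 1.96 * se))
            assert row.upper == pytest.approx(np.exp(b0 + 1.96 * se))
            assert row.lower <= row.trd <= row.upper

    def test_poverty_gradient_propagates(self, state_15x15):
        # generating poverty effect is positive, so predictions must order
        table, graph, _ = state_15x15
        fit = td.fit_marginal_nb(table, graph)
        combos = [{"high_poverty": False, "high_children": False},
                  {"high_poverty": True, "high_children": False}]
        rows = td.predict_groups(fit, combos)
        by = {(r.combo["high_poverty"], r.year): r.trd for r in rows}
        for year in (2017, 2022):
            assert by[(True, year)] > by[(False, year)]

    def test_no_change_flag_for_identical_years(self, state_15x15):
        table, graph, _ = state_15x15
        fit = td.fit_marginal_nb(table, graph)
        # force identical coefficients across years with zero cross-covariance
        half = len(fit.beta) // 2
        fit.beta[half:] = fit.beta[:half]
        fit.cov[:half, half:] = 0.0
        fit.cov[half:, :half] = 0.0
        fit.cov[half:, half:] = fit.cov[:half, :half]
        rows = td.predict_groups(fit, [{"high_poverty": True}])
        assert not any(r.change_significant for r in rows)

    def test_unknown_combo_key_rejected(self, state_15x15):
        table, graph, _ = state_15x15
        fit = td.fit_marginal_nb(table, graph)
        with pytest.raises(ValueError):
            td.predict_groups(fit, [{"wealth": True}])

    def test_licensing_combo_needs_licensing_model(self, state_15x15):
        table, graph, _ = state_15x15
        fit = td.fit_marginal_nb(table, graph)  # model without licensing term
        with pytest.raises(ValueError):
            td.predict_groups(fit, [{"licensing": True}])

    def test_default_combos_fix_children_and_pair_race(self):
        combos = td.default_prediction_combos(licensing_model=True)
        assert len(combos) == 16
        assert all(not c["high_children"] for c in combos)
        assert all(c["high_aa"] == c["high_hisp"] for c in combos)
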