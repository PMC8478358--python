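"""GLS engine, profile-ML lambda, OLS and species-mean aggregation."""

import numpy as np
import pandas as pd
import pytest

import whalebrain as wb
from whalebrain.errors import FitError
from whalebrain.pgls import profile_loglik, _pagel
from whalebrain.phylo import PhyloCovariance
from whalebrain.synthetic import SimulationSpec, simulate_allometric_traits, \
    simulate_yule_tree


def _identity_cov(taxa):
    return PhyloCovariance(tuple(taxa), np.eye(len(taxa)), 1.0)


def brute_force_gls(X, y, V):
    """Independent oracle: explicit normal equations with matrix inversion."""
    Vi = np.linalg.inv(V)
    beta = np.linalg.inv(X.T @ Vi @ X) @ (X.T @ Vi @ y)
    resid = y - X @ beta
    sigma2 = (resid @ Vi @ resid) / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(np.linalg.inv(X.T @ Vi @ X)) * sigma2)
    return beta, se


class TestFitGLS:
    def test_perfect_line_identity_covariance(self):
        tab = pd.DataFrame({"taxon": list("ABC"), "x": [1., 2., 3.], "y": [1., 2., 3.]})
        fit = wb.fit_gls(tab, _identity_cov("ABC"), log10=False)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_perfect_fit_independent_of_covariance(self, toy_tree):
        cov = toy_tree.covariance(1.0)
        tab = pd.DataFrame({"taxon": list(cov.taxa), "x": [1., 2., 3.],
                            "y": [1., 2., 3.]})
        fit = wb.fit_gls(tab, cov, log10=False)
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_normal_equations(self):
        tree = wb.parse_newick("((A:1,B:1):2,(C:2,D:2):1):0;")
        cov = tree.covariance(1.0)
        y = np.array([1.3, 0.9, 2.4, 2.0])
        x = np.array([1.0, 0.8, 2.2, 1.9])
        tab = pd.DataFrame({"taxon": list(cov.taxa), "x": x, "y": y})
        fit = wb.fit_gls(tab, cov, log10=False)
        X = np.column_stack([np.ones(4), x])
        beta, se = brute_force_gls(X, y, cov.matrix)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert fit.intercept_se == pytest.approx(se[0], abs=1e-10)
        assert fit.slope_se == pytest.approx(se[1], abs=1e-10)

    def test_identity_covariance_reproduces_ols(self, random_loglog_pairs):
        tab = pd.DataFrame(random_loglog_pairs, columns=["x", "y"])
        tab.insert(0, "taxon", [f"t{i}" for i in range(len(tab))])
        gls = wb.fit_gls(tab, _identity_cov(tab["taxon"]), log10=True)
        ols = wb.fit_ols_loglog(random_loglog_pairs)
        assert gls.slope == pytest.approx(ols.slope, abs=1e-10)
        assert gls.intercept == pytest.approx(ols.intercept, abs=1e-10)
        assert gls.adjusted_r2 == pytest.approx(ols.adjusted_r2, abs=1e-10)

    def test_mismatched_taxa_rejected(self, toy_tree):
        cov = toy_tree.covariance(1.0)
        tab = pd.DataFrame({"taxon": ["A", "C", "B"], "x": [1., 2., 3.],
                            "y": [1., 2., 3.]})
        with pytest.raises(FitError, match="identical taxa"):
            wb.fit_gls(tab, cov, log10=False)

    def test_rank_deficient_design_rejected(self):
        tab = pd.DataFrame({"taxon": list("ABC"), "x": [2., 2., 2.],
                            "y": [1., 2., 3.]})
        with pytest.raises(FitError):
            wb.fit_gls(tab, _identity_cov("ABC"), log10=False)


class TestOLSLogLog:
    def test_exact_power_law(self):
        fit = wb.fit_ols_loglog([(1, 2), (10, 2000), (100, 2_000_000)])
        assert fit.slope == pytest.approx(3.0, abs=1e-12)
        assert fit.intercept == pytest.approx(np.log10(2), abs=1e-12)

    def test_constant_response_gives_zero_slope(self):
        fit = wb.fit_ols_loglog([(1, 5), (10, 5), (100, 5)])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels(self, random_loglog_pairs):
        sm = pytest.importorskip("statsmodels.api")
        fit = wb.fit_ols_loglog(random_loglog_pairs)
        x = np.log10([p[0] for p in random_loglog_pairs])
        y = np.log10([p[1] for p in random_loglog_pairs])
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-10)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-10)
        assert fit.adjusted_r2 == pytest.approx(ref.rsquared_adj, abs=1e-10)
        assert fit.slope_se == pytest.approx(ref.bse[1], abs=1e-10)

    @pytest.mark.parametrize("pairs", [
        [(1, 2), (10, 20)],              # too few
        [(1, 2), (10, 20), (-1, 5)],     # non-positive x
        [(1, 2), (10, 20), (100, 0)],    # non-positive y
    ])
    def test_invalid_inputs_rejected(self, pairs):
        with pytest.raises(FitError):
            wb.fit_ols_loglog(pairs)


class TestProfileLambda:
    def test_returned_lambda_beats_every_grid_point(self):
        spec = SimulationSpec(n_tips=30, slope=1.0, intercept=0.0,
                              sigma2=0.05, lam=0.6, seed=11)
        tree = simulate_yule_tree(spec)
        traits = simulate_allometric_traits(tree, spec)
        fit = wb.fit_pgls_ml_lambda(traits, tree)
        base = tree.covariance(1.0).subset(list(traits["taxon"]))
        ll_hat = profile_loglik(traits, base, fit.lam)
        for g in np.linspace(0, 1, 101):
            assert ll_hat >= profile_loglik(traits, base, g) - 1e-9

    def test_star_phylogeny_reduces_to_ols(self, star_tree, rng):
        x = rng.uniform(1, 100, 10)
        y = 2 * x**1.5 * np.exp(rng.normal(0, 0.1, 10))
        tab = pd.DataFrame({"taxon": star_tree.tip_labels, "x": x, "y": y})
        pgls = wb.fit_pgls_ml_lambda(tab, star_tree)
        ols = wb.fit_ols_loglog(list(zip(x, y)))
        assert pgls.slope == pytest.approx(ols.slope, abs=1e-8)
        assert pgls.intercept == pytest.approx(ols.intercept, abs=1e-8)

    def test_noiseless_data_recovered_exactly(self):
        spec = SimulationSpec(n_tips=20, slope=0.933, intercept=0.088,
                              sigma2=0.0, lam=0.5, seed=2)
        tree = simulate_yule_tree(spec)
        traits = simulate_allometric_traits(tree, spec)
        fit = wb.fit_pgls_ml_lambda(traits, tree)
        assert fit.slope == pytest.approx(0.933, abs=1e-8)
        assert fit.intercept == pytest.approx(0.088, abs=1e-8)

    def test_loglik_invariant_to_branch_rescaling(self):
        spec = SimulationSpec(n_tips=15, sigma2=0.05, lam=0.7, seed=9)
        tree = simulate_yule_tree(spec)
        traits = simulate_allometric_traits(tree, spec)
        cov = tree.covariance(1.0).subset(list(traits["taxon"]))
        scaled = PhyloCovariance(cov.taxa, cov.matrix * 7.3, cov.lam)
        for lam in (0.0, 0.5, 1.0):
            a = profile_loglik(traits, cov, lam)
            b = profile_loglik(traits, scaled, lam)
            assert b == pytest.approx(a, rel=1e-6)

    def test_too_few_taxa_rejected(self, toy_tree):
        tab = pd.DataFrame({"taxon": list(toy_tree.tip_labels),
                            "x": [1., 2., 3.], "y": [1., 2., 3.]})
        with pytest.raises(FitError):
            wb.fit_pgls_ml_lambda(tab, toy_tree)

    def test_pagel_helper_touches_only_off_diagonal(self, toy_tree):
        base = toy_tree.covariance(1.0)
        half = _pagel(base, 0.5)
        assert np.allclose(np.diag(half.matrix), np.diag(base.matrix))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(half.matrix[off], 0.5 * base.matrix[off])


class TestAggregation:
    def test_mean_on_natural_scale(self, specimen_records):
        table, report = wb.aggregate_species_means(
            specimen_records, "ocw_mm", "body_mass_kg", adults_only=False)
        aa = table.set_index("taxon").loc["Aa"]
        assert aa["x"] == pytest.approx(np.mean([100, 200, 80]))

    def test_adult_filter_excludes_subadult_and_unknown(self, specimen_records):
        table, report = wb.aggregate_species_means(
            specimen_records, "ocw_mm", "body_mass_kg", adults_only=True)
        # only Aa has adult records complete in both traits
        assert list(table["taxon"]) == ["Aa"]
        assert table.iloc[0]["x"] == pytest.approx(150.0)  # mean(100, 200)
        assert "Bb" in report["species_without_eligible_records"]
        assert "Cc" in report["species_without_eligible_records"]

    def test_row_count_equals_species_with_complete_records(self, specimen_records):
        table, report = wb.aggregate_species_means(
            specimen_records, "ocw_mm", "body_mass_kg", adults_only=False)
        complete = specimen_records.dropna(subset=["ocw_mm", "body_mass_kg"])
        assert report["n_species"] == complete["taxon"].nunique()
        assert len(table) == report["n_species"]

    def test_mean_of_logs_switch(self, specimen_records):
        table, _ = wb.aggregate_species_means(
            specimen_records, "ocw_mm", "body_mass_kg",
            adults_only=False, mean_of_logs=True)
        aa = table.set_index("taxon").loc["Aa"]
        assert aa["x"] == pytest.approx(10 ** np.mean(np.log10([100, 200, 80])))
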