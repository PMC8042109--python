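"""GLS estimation, profile likelihood, AIC selection, sequential tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleobrain.errors import FitError, ValidationError
from paleobrain.pgls import (
    CovModelSpec,
    RegressionSpec,
    build_design,
    gls_fit,
    group_design,
    phylo_residual_diagnostic,
    profile_fit,
    select_model,
    sequential_pvalues,
)
from paleobrain.phylo_core import model_covariance, shared_path_matrix
from paleobrain.synthetic import SynthConfig, simulate_dataset

from conftest import random_tree


class TestBuildDesign:
    def test_formula_a_has_six_columns(self, default_dataset):
        d = build_design(default_dataset.traits, RegressionSpec("1.EB", "a"))
        assert d.X.shape[1] == 6
        assert list(d.X.columns[:2]) == ["intercept", "pred1"]

    def test_formula_b_has_ten_columns(self, default_dataset):
        d = build_design(default_dataset.traits, RegressionSpec("1.EB", "b"))
        assert d.X.shape[1] == 10

    def test_missing_response_rows_dropped(self, default_dataset):
        d = build_design(default_dataset.traits, RegressionSpec("1.PB", "a"))
        n_total = len(default_dataset.traits.table)
        n_missing = default_dataset.traits.table.petrosal_lobule_volume.isna().sum()
        assert len(d.y) == n_total - n_missing == 37

    def test_log10_units(self, default_dataset):
        d = build_design(default_dataset.traits, RegressionSpec("1.EB", "a"))
        raw = default_dataset.traits.column("endocranial_volume")
        assert d.y.loc[d.species[0]] == pytest.approx(np.log10(raw.loc[d.species[0]]))


class TestGlsFit:
    def test_identity_covariance_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(30), rng.normal(size=30), rng.normal(size=30)])
        y = X @ [1.0, 2.0, -0.5] + rng.normal(size=30)
        fit = gls_fit(y, X, np.eye(30))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.params.to_numpy(), beta_ols, atol=1e-10)
        # ML log-likelihood of OLS, computed directly
        resid = y - X @ beta_ols
        s2 = resid @ resid / 30
        ll = -0.5 * (30 * np.log(2 * np.pi * s2) + 30)
        assert fit.loglik == pytest.approx(ll, abs=1e-8)
        assert fit.aic == pytest.approx(-2 * ll + 2 * fit.k, abs=1e-8)

    def test_intercept_only_identity_gives_mean(self):
        y = np.array([1.0, 4.0, 7.0])
        fit = gls_fit(y, np.ones((3, 1)), np.eye(3))
        assert fit.params.iloc[0] == pytest.approx(y.mean())

    def test_three_tip_matrix_inversion_oracle(self, three_tip_tree):
        V = shared_path_matrix(three_tip_tree)
        y = np.array([1.0, 2.0, 3.0])
        fit = gls_fit(y, np.ones((3, 1)), V)
        Vi = np.linalg.inv(V)
        one = np.ones(3)
        expected = (one @ Vi @ y) / (one @ Vi @ one)
        assert fit.params.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_rank_deficiency_reported(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(FitError, match="rank"):
            gls_fit(np.arange(10.0), X, np.eye(10))


class TestProfileFit:
    def test_matches_fine_grid(self):
        rng = np.random.default_rng(1)
        tree = random_tree(rng, 40, height=1.0)
        V = model_covariance(tree, CovModelSpec("lambda", 0.6))
        y = rng.multivariate_normal(np.zeros(40), 0.1 * V)
        X = np.ones((40, 1))
        fit = profile_fit(y, X, tree, "lambda")
        grid = np.linspace(0, 1, 1001)
        lls = [
            gls_fit(y, X, model_covariance(tree, CovModelSpec("lambda", g))).loglik
            for g in grid
        ]
        best = int(np.argmax(lls))
        assert abs(fit.cov_spec.parameter - grid[best]) < 0.01
        assert fit.loglik >= lls[best] - 0.01

    def test_lambda_recovery_under_brownian(self):
        """Data simulated at lambda=1 on a large tree: estimates near 1."""
        rng = np.random.default_rng(2)
        tree = random_tree(rng, 200, height=1.0)
        C = shared_path_matrix(tree)
        X = np.ones((200, 1))
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            y = rng.multivariate_normal(np.zeros(200), C, method="cholesky")
            fit = profile_fit(y, X, tree, "lambda", grid_points=15)
            hits += fit.cov_spec.parameter > 0.9
        assert hits >= 0.9 * n_rep

    def test_brownian_has_no_free_parameter(self, three_tip_tree):
        fit = profile_fit(
            np.array([1.0, 2.0, 3.0]), np.ones((3, 1)), three_tip_tree, "brownian"
        )
        assert fit.cov_spec.parameter is None
        assert fit.k == 2  # intercept + sigma^2


class TestSelectModel:
    def test_interaction_detected_when_strong(self):
        """Simulated slope differences 3x the residual SD select formula b."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 30
        tree = random_tree(rng, 40, height=1.0)
        order = tree.labels
        for _ in range(n_rep):
            x = rng.uniform(0, 2, size=40)
            g = np.array(["p", "q"] * 20)
            sd = 0.3
            slope = np.where(g == "p", 1.0, 1.0 + 3 * sd)
            y = 0.5 + slope * x + rng.normal(0, sd, size=40)
            da = group_design(y, x, g, names=order)
            db = group_design(y, x, g, names=order, interaction=True)
            best, trace = select_model(da, db, tree)
            hits += "interaction" in best.design.term_slices
        assert hits >= 0.9 * n_rep

    def test_trace_has_eight_fits_and_consistent_aic(self, default_dataset):
        traits = default_dataset.traits
        tree = default_dataset.tree
        da = build_design(traits, RegressionSpec("1.EB", "a"))
        db = build_design(traits, RegressionSpec("1.EB", "b"))
        best, trace = select_model(da, db, tree)
        assert len(trace) == 8
        ok = trace[trace.error == ""]
        assert np.allclose(ok.aic, -2 * ok.loglik + 2 * ok.k)
        assert best.aic == pytest.approx(ok.aic.min())

    def test_tie_broken_toward_formula_a(self):
        rng = np.random.default_rng(4)
        tree = random_tree(rng, 20, height=1.0)
        y = rng.normal(size=20)
        x = rng.normal(size=20)
        g = np.array(["p", "q"] * 10)
        da = group_design(y, x, g, names=tree.labels)
        best, _ = select_model(da, da, tree)  # identical designs: exact AIC tie
        assert "interaction" not in best.design.term_slices


class TestSequentialPvalues:
    def test_identity_covariance_matches_classical_anova(self):
        """Balanced one-way layout: F and p equal hand-computed sums of squares."""
        rng = np.random.default_rng(5)
        g = np.repeat(["p", "q", "r"], 10)
        y = rng.normal(size=30) + np.repeat([0.0, 1.0, 2.0], 10)
        x = rng.normal(size=30)
        design = group_design(y, x, g)
        fit = gls_fit(design.y, design.X, np.eye(30), design=design)
        pv = sequential_pvalues(fit)
        # classical sequential ANOVA via explicit RSS computations
        X1 = design.X.to_numpy()[:, :2]
        X2 = design.X.to_numpy()

        def rss(M):
            b, *_ = np.linalg.lstsq(M, y, rcond=None)
            r = y - M @ b
            return r @ r

        num = (rss(X1) - rss(X2)) / 2
        den = rss(X2) / (30 - 4)
        p_expected = stats.f.sf(num / den, 2, 26)
        assert pv["locomotion"] == pytest.approx(p_expected, abs=1e-10)

    def test_orthogonal_group_term_has_p_near_one(self):
        n = 40
        y = np.linspace(0, 1, n)
        x = y.copy()  # pred1 explains y exactly
        g = np.array(["p", "q"] * (n // 2))
        design = group_design(y + 0.0, x, g)
        # add tiny noise so the full model is not a perfect fit
        rng = np.random.default_rng(6)
        design.y.iloc[:] = y + rng.normal(0, 1e-6, size=n)
        fit = gls_fit(design.y, design.X, np.eye(n), design=design)
        pv = sequential_pvalues(fit)
        assert pv["pred1"] < 1e-12
        assert pv["locomotion"] > 0.05


class TestResidualDiagnostic:
    def test_constant_residuals_score_zero_no_flag(self, default_dataset):
        tree = default_dataset.tree
        resid = pd.Series(1.0, index=tree.labels)
        diag = phylo_residual_diagnostic(resid, tree, n_permutations=99)
        assert diag.score == 0.0
        assert not diag.use_pgls
        assert diag.p_value == 1.0

    def test_type_one_error_calibrated(self, default_dataset):
        """I.i.d. residuals should be flagged at roughly the nominal 5% rate."""
        tree = default_dataset.tree
        rng = np.random.default_rng(7)
        flags = 0
        n_rep = 400
        for i in range(n_rep):
            resid = pd.Series(rng.normal(size=tree.n_tips), index=tree.labels)
            d = phylo_residual_diagnostic(resid, tree, n_permutations=99, seed=i)
            flags += d.use_pgls
        assert 0.02 <= flags / n_rep <= 0.09

    def test_brownian_residuals_flagged(self, default_dataset):
        """Strongly heritable residuals are detected most of the time."""
        tree = default_dataset.tree
        C = shared_path_matrix(tree)
        rng = np.random.default_rng(8)
        flags = 0
        n_rep = 200
        for i in range(n_rep):
            resid = pd.Series(
                rng.multivariate_normal(np.zeros(tree.n_tips), C, method="cholesky"),
                index=tree.labels,
            )
            d = phylo_residual_diagnostic(resid, tree, n_permutations=99, seed=i)
            flags += d.use_pgls
        assert flags / n_rep >= 0.8


class TestRegressionSpec:
    def test_unknown_regression_rejected(self):
        with pytest.raises(ValidationError):
            RegressionSpec("3.XX", "a")

    def test_missing_level_reported(self, default_dataset):
        df = default_dataset.traits.table.copy()
        df = df[df.locomotion != "glider"]
        from paleobrain.traits import TraitTable

        with pytest.raises(ValidationError, match="glider"):
            build_design(TraitTable.from_frame(df), RegressionSpec("1.EB", "a"))
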