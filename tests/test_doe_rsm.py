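"""Box-Behnken design, quadratic fitting, partial-SS ANOVA, box optimization."""

import numpy as np
import pytest
from scipy import stats

from sccbb import (
    FactorDef,
    QuadraticModel,
    QuadraticResponseSurface,
    anova_partial,
    detect_aliasing,
    fit_quadratic,
    generate_bbd,
    optimize_box,
    predict,
)
from sccbb.doe_rsm import build_model_matrix, full_quadratic_terms
from sccbb.synthetic_data import SurfaceSimConfig, simulate_responses


class TestGenerateBBD:
    def test_centerless_structure(self, bbd_factors):
        design = generate_bbd(bbd_factors, n_center=0)
        assert design.n_runs == 12
        nonzero = (design.coded != 0).sum(axis=1)
        assert (nonzero == 2).all()

    def test_quadratic_column_identity(self, bbd_factors):
        """Every centerless run satisfies x1^2 + x2^2 + x3^2 = 2."""
        coded = generate_bbd(bbd_factors, n_center=0).coded
        assert np.allclose((coded**2).sum(axis=1), 2.0)

    def test_center_replicates(self, bbd_factors):
        design = generate_bbd(bbd_factors, n_center=3)
        assert design.n_runs == 15
        assert (design.coded[12:] == 0).all()

    def test_only_three_factors_supported(self, bbd_factors):
        with pytest.raises(ValueError):
            generate_bbd(bbd_factors[:2])

    def test_natural_levels_decode_to_factor_ranges(self, bbd_factors):
        design = generate_bbd(bbd_factors)
        nat = design.natural()
        assert nat[:, 0].min() == pytest.approx(2.0)
        assert nat[:, 0].max() == pytest.approx(3.0)
        assert sorted(set(nat[:, 2])) == [120.0, 126.0, 132.0]


class TestDetectAliasing:
    def test_centerless_rank_deficiency(self, bbd_factors):
        """Full quadratic matrix on the centerless design has rank 9, not 10."""
        design = generate_bbd(bbd_factors, n_center=0)
        M = build_model_matrix(
            design.coded, design.factor_names, full_quadratic_terms(design.factor_names)
        )
        assert M.shape[1] == 10
        assert np.linalg.matrix_rank(M) == 9

    def test_drops_last_factor_quadratic_by_default(self, bbd_factors):
        design = generate_bbd(bbd_factors, n_center=0)
        kept, dropped = detect_aliasing(design)
        assert dropped == ["E^2"]
        assert "B^2" in kept and "C^2" in kept

    def test_named_drop_override(self, bbd_factors):
        design = generate_bbd(bbd_factors, n_center=0)
        kept, dropped = detect_aliasing(design, drop=["B^2"])
        assert dropped == ["B^2"]

    def test_center_point_restores_estimability(self, bbd_factors):
        design = generate_bbd(bbd_factors, n_center=1)
        kept, dropped = detect_aliasing(design)
        assert dropped == []
        assert len(kept) == 9

    def test_linear_model_never_dropped(self, bbd_factors):
        design = generate_bbd(bbd_factors, n_center=0)
        kept, dropped = detect_aliasing(design, terms=list(design.factor_names))
        assert dropped == [] and kept == list(design.factor_names)


class TestFitQuadratic:
    def test_round_trip_recovery_at_zero_noise(self, bbd_factors, published_surface):
        """Responses generated from the surface refit to it exactly."""
        design = generate_bbd(bbd_factors, n_center=0)
        y = simulate_responses(
            SurfaceSimConfig(true_model=published_surface, design=design, noise_sd=0.0)
        )
        model = fit_quadratic(design, y)
        assert model.intercept == pytest.approx(8.21, abs=1e-10)
        for term, value in published_surface.linear.items():
            assert model.linear[term] == pytest.approx(value, abs=1e-10)
        for term, value in published_surface.interaction.items():
            assert model.interaction[term] == pytest.approx(value, abs=1e-10)
        for term, value in published_surface.quadratic.items():
            assert model.quadratic[term] == pytest.approx(value, abs=1e-10)
        assert "E" not in model.quadratic

    def test_constant_responses(self, bbd_factors):
        design = generate_bbd(bbd_factors, n_center=0)
        model = fit_quadratic(design, np.full(12, 4.2))
        assert model.intercept == pytest.approx(4.2, abs=1e-10)
        assert np.allclose(list(model.linear.values()), 0.0, atol=1e-10)
        assert np.allclose(list(model.interaction.values()), 0.0, atol=1e-10)

    def test_coefficient_sampling_matches_ls_covariance(self, bbd_factors, published_surface):
        """Over 500 noisy sims the coefficient spread matches OLS theory."""
        design = generate_bbd(bbd_factors, n_center=0)
        sigma = 0.07
        M = build_model_matrix(design.coded, design.factor_names,
                               [t for t in full_quadratic_terms(design.factor_names)
                                if t != "E^2"])
        cov = sigma**2 * np.linalg.inv(M.T @ M)
        se_b = np.sqrt(cov[1, 1])  # first linear coefficient
        vals = []
        for i in range(500):
            y = simulate_responses(SurfaceSimConfig(
                true_model=published_surface, design=design, noise_sd=sigma, seed=i))
            vals.append(fit_quadratic(design, y).linear["B"])
        vals = np.asarray(vals)
        assert vals.mean() == pytest.approx(-0.4175, abs=4 * se_b / np.sqrt(500))
        assert vals.std() == pytest.approx(se_b, rel=0.2)

    def test_estimator_sklearn_interface(self, bbd_factors, published_surface):
        from sklearn.base import clone

        design = generate_bbd(bbd_factors, n_center=0)
        y = simulate_responses(
            SurfaceSimConfig(true_model=published_surface, design=design, noise_sd=0.0)
        )
        est = QuadraticResponseSurface()
        assert clone(est).get_params()["alias_drop"] == "last"
        est.fit(design, y)
        assert est.dropped_terms_ == ["E^2"]
        assert np.allclose(est.predict(design), y, atol=1e-9)
        assert est.r2_ == pytest.approx(1.0, abs=1e-12)


class TestAnovaPartial:
    @pytest.fixture()
    def noisy_fit(self, bbd_factors, published_surface):
        design = generate_bbd(bbd_factors, n_center=0)
        y = simulate_responses(SurfaceSimConfig(
            true_model=published_surface, design=design, noise_sd=0.07, seed=5))
        return design, y

    def test_published_f_to_p(self, anova_published_f):
        """Upper F tail reproduces the published ANOVA p-values to 5e-4."""
        for f, d1, d2, p in anova_published_f:
            assert stats.f.sf(f, d1, d2) == pytest.approx(p, abs=5e-4)

    def test_ss_decomposition(self, noisy_fit):
        design, y = noisy_fit
        table = anova_partial(design, y)
        ss_model = table["Model"]["ss"]
        ss_resid = table["Residual"]["ss"]
        ss_total = table["Cor Total"]["ss"]
        assert ss_model + ss_resid == pytest.approx(ss_total, rel=1e-9)
        assert table["Model"]["df"] == 8
        assert table["Residual"]["df"] == 3
        assert table["Cor Total"]["df"] == 11

    def test_aliased_term_reported_with_zero_df(self, noisy_fit):
        design, y = noisy_fit
        table = anova_partial(design, y)
        row = table["E^2"]
        assert row["df"] == 0 and row["ss"] == 0.0
        assert np.isnan(row["F"]) and np.isnan(row["p"])

    def test_partial_ss_matches_statsmodels_refit(self, noisy_fit):
        """Each term's extra SS equals the SSE difference of two OLS fits."""
        import statsmodels.api as sm

        design, y = noisy_fit
        names = design.factor_names
        terms = [t for t in full_quadratic_terms(names) if t != "E^2"]
        table = anova_partial(design, y)
        M_full = build_model_matrix(design.coded, names, terms)
        sse_full = sm.OLS(y, M_full).fit().ssr
        for term in terms:
            reduced = [t for t in terms if t != term]
            M_red = build_model_matrix(design.coded, names, reduced)
            expected = sm.OLS(y, M_red).fit().ssr - sse_full
            assert table[term]["ss"] == pytest.approx(expected, rel=1e-8, abs=1e-12)

    def test_interpolating_fit_rejected(self, bbd_factors, published_surface):
        design = generate_bbd(bbd_factors, n_center=0)
        y = simulate_responses(SurfaceSimConfig(
            true_model=published_surface, design=design, noise_sd=0.0))
        with pytest.raises(ValueError):
            anova_partial(design, y)

    def test_ss_identity_over_many_noisy_sims(self, bbd_factors, published_surface):
        """SS_model + SS_residual = SS_total across 500 noisy simulations."""
        design = generate_bbd(bbd_factors, n_center=0)
        for i in range(500):
            y = simulate_responses(SurfaceSimConfig(
                true_model=published_surface, design=design, noise_sd=0.2, seed=1000 + i))
            t = anova_partial(design, y)
            assert t["Model"]["ss"] + t["Residual"]["ss"] == pytest.approx(
                t["Cor Total"]["ss"], rel=1e-9
            )


class TestPredict:
    def test_published_surface_values(self, published_surface):
        assert predict(published_surface, [0, 0, 0]) == pytest.approx(8.21)
        assert predict(published_surface, [1, 0, 0]) == pytest.approx(
            8.21 - 0.4175 - 1.15, abs=1e-12
        )

    def test_zero_model(self):
        model = QuadraticModel(factor_names=("a", "b"), intercept=0.0)
        assert predict(model, [0.3, -0.7]) == 0.0

    def test_json_round_trip(self, published_surface, tmp_path):
        path = tmp_path / "model.json"
        published_surface.to_json(path)
        back = QuadraticModel.from_json(path)
        x = [0.2, -0.4, 0.9]
        assert back.predict(x) == pytest.approx(published_surface.predict(x), abs=1e-12)
        assert back.coding == published_surface.coding


class TestOptimizeBox:
    def test_published_surface_optimum(self, published_surface):
        """Maximizer lands at (-0.190, -0.385, +1) in coded space."""
        opt = optimize_box(published_surface)
        assert opt.coded[0] == pytest.approx(-0.190, abs=2e-3)
        assert opt.coded[1] == pytest.approx(-0.385, abs=2e-3)
        assert opt.coded[2] == pytest.approx(1.0, abs=1e-12)
        assert opt.at_boundary == (False, False, True)

    def test_published_surface_decoded_optimum(self, published_surface):
        opt = optimize_box(published_surface)
        rounded = opt.natural_rounded(decimals=1)
        assert rounded[0] == pytest.approx(2.4)  # NaNO3 g/L
        assert rounded[1] == pytest.approx(23.3)  # PO4^3- g/L
        assert rounded[2] == pytest.approx(132.0)  # time h
        assert 8.29 <= opt.predicted <= 8.32  # consistent with printed 8.30

    def test_agrees_with_dense_grid_oracle(self, published_surface):
        """0.001-resolution grid search agrees with face enumeration."""
        grid = np.arange(-1, 1 + 1e-12, 0.001)
        best = -np.inf
        best_bc = None
        for e in (-1.0, 1.0):  # surface is linear in E: optimum at a face
            B, C = np.meshgrid(grid, grid, indexing="ij")
            Y = (8.21 - 0.4175 * B - 0.125 * C + 0.03 * e + 0.0325 * B * C
                 - 0.0075 * B * e - 0.0075 * C * e - 1.15 * B**2 - 0.18 * C**2)
            idx = np.unravel_index(np.argmax(Y), Y.shape)
            if Y[idx] > best:
                best = Y[idx]
                best_bc = (grid[idx[0]], grid[idx[1]], e)
        opt = optimize_box(published_surface)
        assert opt.predicted == pytest.approx(best, abs=1e-6)
        assert np.allclose(opt.coded, best_bc, atol=2e-3)

    def test_concave_interior_optimum(self):
        model = QuadraticModel(
            factor_names=("B",), intercept=0.0, quadratic={"B": -1.0}
        )
        opt = optimize_box(model)
        assert opt.coded[0] == pytest.approx(0.0, abs=1e-12)
        assert opt.predicted == pytest.approx(0.0, abs=1e-12)
        assert opt.at_boundary == (False,)

    def test_convex_model_picks_vertex(self):
        model = QuadraticModel(
            factor_names=("a", "b"), intercept=0.0,
            linear={"a": 0.1}, quadratic={"a": 1.0, "b": 1.0},
        )
        opt = optimize_box(model)
        assert opt.predicted == pytest.approx(2.1, abs=1e-12)
        assert np.allclose(np.abs(opt.coded), 1.0)

    def test_never_below_random_box_points(self, published_surface):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1, 1, size=(100_000, 3))
        values = published_surface.predict(pts)
        opt = optimize_box(published_surface)
        assert opt.predicted >= values.max() - 1e-9

    def test_parameter_recovery_bias_bounded(self, bbd_factors):
        """Random surfaces refit from noisy data: mean bias < 2 se."""
        design = generate_bbd(bbd_factors, n_center=1)
        names = design.factor_names
        terms = full_quadratic_terms(names)
        M = build_model_matrix(design.coded, names, terms)
        rng = np.random.default_rng(2024)
        for sigma in (0.05, 0.2):
            XtX_inv = np.linalg.inv(M.T @ M)
            se = sigma * np.sqrt(np.diag(XtX_inv))
            beta_true = rng.uniform(-2, 2, size=M.shape[1])
            n_sims = 500
            est = np.empty((n_sims, M.shape[1]))
            for i in range(n_sims):
                y = M @ beta_true + rng.normal(0, sigma, M.shape[0])
                est[i], _, _, _ = np.linalg.lstsq(M, y, rcond=None)
            bias = est.mean(axis=0) - beta_true
            assert np.all(np.abs(bias) < 2 * se / np.sqrt(n_sims) + 5e-3)


class TestCoding:
    def test_decode_center_and_step(self, published_surface):
        assert np.allclose(published_surface.decode([0, 0, 0]), [2.5, 23.75, 126.0])
        assert published_surface.decode([0, 0, 1])[2] == pytest.approx(132.0)

    def test_encode_decode_round_trip(self, published_surface):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.uniform(-1, 1, 3)
            assert np.allclose(published_surface.encode(published_surface.decode(x)), x)

    def test_missing_coding_raises(self):
        model = QuadraticModel(factor_names=("a",), intercept=1.0)
        with pytest.raises(ValueError):
            model.decode([0.5])
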