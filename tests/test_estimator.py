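"""Sharp-RDD estimator: side fits, pooled fits, fuzzy model, equivalences."""

import numpy as np
import pytest

from modsrd import (
    FuzzyObservation,
    InsufficientDataError,
    RDDDataset,
    SingularDesignError,
    TriangularFuzzyNumber,
    assign_treatment,
    estimate_discontinuity_two_sided,
    fit_modified,
    fit_pooled,
    fit_side,
    fuzzify,
    treatment_effect,
)


def normal_equations(X, y):
    """Independent closed-form OLS oracle: solve XᵀX b = Xᵀy directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestAssignTreatment:
    @pytest.mark.parametrize(
        "x,c,expected", [(15, 15, 1), (14.9, 15, 0), (20, 15, 1), (-1, 0, 0)]
    )
    def test_threshold_rule(self, x, c, expected):
        # scoring at the threshold enrolls the subject: ties are treated
        assert assign_treatment(x, c) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assign_treatment(np.nan, 15)
        with pytest.raises(ValueError):
            assign_treatment(10, np.inf)


class TestFitSide:
    def test_exact_line_below(self):
        x = np.array([10.0, 11, 12, 13, 14])
        y = 2.0 + 0.5 * (x - 15)
        data = RDDDataset.from_crisp(y, x, cutoff=15.0)
        fit = fit_side(data, "below")
        assert fit.alpha_hat == pytest.approx(2.0, abs=1e-10)
        assert fit.beta_hat == pytest.approx(0.5, abs=1e-10)
        assert fit.n_used == 5

    def test_matches_normal_equations_oracle(self, rng):
        x = 15 + rng.uniform(0, 5, 8)
        y = rng.normal(0, 1, 8)
        data = RDDDataset.from_crisp(y, x, cutoff=15.0)
        fit = fit_side(data, "above")
        X = np.column_stack([np.ones(8), x - 15])
        a, b = normal_equations(X, y)
        assert fit.alpha_hat == pytest.approx(a, rel=1e-10)
        assert fit.beta_hat == pytest.approx(b, rel=1e-10)

    def test_cutoff_point_belongs_to_above_side(self):
        # x exactly at the cutoff is treated, so it is fitted on the above side
        x = np.array([13.0, 14.0, 15.0, 16.0])
        y = np.array([0.0, 0.0, 5.0, 6.0])
        data = RDDDataset.from_crisp(y, x, cutoff=15.0)
        assert fit_side(data, "above").n_used == 2
        assert fit_side(data, "below").n_used == 2

    def test_insufficient_data(self):
        data = RDDDataset.from_crisp([1.0, 2.0, 3.0], [14.0, 16.0, 17.0], 15.0)
        with pytest.raises(InsufficientDataError):
            fit_side(data, "below")

    def test_singular_design(self):
        data = RDDDataset.from_crisp([1.0, 2.0, 3.0], [14.0, 14.0, 14.0], 15.0)
        with pytest.raises(SingularDesignError):
            fit_side(data, "below")

    def test_bandwidth_restricts_window(self):
        x = np.array([5.0, 13.0, 14.0, 16.0, 17.0, 25.0])
        y = x.copy()
        data = RDDDataset.from_crisp(y, x, cutoff=15.0)
        assert fit_side(data, "below", bandwidth_h=3.0).n_used == 2
        assert fit_side(data, "below").n_used == 3


class TestPooled:
    def test_exact_piecewise_recovery(self):
        x = np.arange(5.0, 26.0)
        d = (x >= 15).astype(float)
        y = 1.0 + 0.4 * (1 - d) * (x - 15) + 0.7 * d * (x - 15) + 1.0 * d
        data = RDDDataset.from_crisp(y, x, cutoff=15.0)
        side = fit_pooled(data, parameterization="sidewise")
        assert side.psi_hat == pytest.approx((1.0, 0.4, 0.7, 1.0), abs=1e-9)
        inter = fit_pooled(data, parameterization="interaction")
        # interaction form: gamma is the slope offset 0.7 - 0.4
        assert inter.psi_hat == pytest.approx((1.0, 0.4, 0.3, 1.0), abs=1e-9)

    def test_reparameterization_identities(self, noisy_dataset):
        side = fit_pooled(noisy_dataset, parameterization="sidewise")
        inter = fit_pooled(noisy_dataset, parameterization="interaction")
        assert inter.delta == pytest.approx(side.delta, rel=1e-10)
        assert inter.gamma == pytest.approx(side.gamma - side.beta, rel=1e-9)
        np.testing.assert_allclose(inter.residuals, side.residuals, rtol=1e-9)

    def test_pooled_equals_two_sided(self, noisy_dataset):
        pooled = fit_pooled(noisy_dataset)
        above = fit_side(noisy_dataset, "above")
        below = fit_side(noisy_dataset, "below")
        jump = estimate_discontinuity_two_sided(above, below)
        assert pooled.delta == pytest.approx(jump, rel=1e-10)
        # the pooled fit nests the two independent side lines
        assert pooled.alpha == pytest.approx(below.alpha_hat, rel=1e-10)
        assert pooled.beta == pytest.approx(below.beta_hat, rel=1e-10)
        assert pooled.gamma == pytest.approx(above.beta_hat, rel=1e-10)

    def test_pooled_equals_two_sided_with_bandwidth(self, noisy_dataset):
        h = 6.0
        pooled = fit_pooled(noisy_dataset, bandwidth_h=h)
        jump = estimate_discontinuity_two_sided(
            fit_side(noisy_dataset, "above", h), fit_side(noisy_dataset, "below", h)
        )
        assert pooled.delta == pytest.approx(jump, rel=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        # tiny instance, coefficients against the closed-form solver
        x = np.array([11.0, 12.5, 13.0, 14.0, 15.5, 16.0, 18.0, 19.5])
        y = rng.normal(0, 1, 8)
        data = RDDDataset.from_crisp(y, x, cutoff=15.0)
        fit = fit_pooled(data, parameterization="sidewise")
        xc = x - 15
        d = (x >= 15).astype(float)
        X = np.column_stack([np.ones(8), (1 - d) * xc, d * xc, d])
        expected = normal_equations(X, y)
        np.testing.assert_allclose(fit.psi_hat, expected, rtol=1e-10)

    def test_residual_orthogonality(self, noisy_dataset):
        fit = fit_pooled(noisy_dataset)
        _, x, d = noisy_dataset.defuzzified()
        xc = x - 15
        X = np.column_stack([np.ones(len(x)), (1 - d) * xc, d * xc, d])
        np.testing.assert_allclose(X.T @ fit.residuals, 0.0, atol=1e-8)

    def test_translation_equivariance(self, noisy_dataset):
        base = fit_pooled(noisy_dataset)
        y, x, _ = noisy_dataset.defuzzified()
        # shift running variable and cutoff together: nothing changes
        shifted_x = RDDDataset.from_crisp(y, x + 7.0, cutoff=22.0)
        np.testing.assert_allclose(
            fit_pooled(shifted_x).psi_hat, base.psi_hat, rtol=1e-9
        )
        # shift the outcome: only alpha moves
        shifted_y = RDDDataset.from_crisp(y + 3.0, x, cutoff=15.0)
        fy = fit_pooled(shifted_y)
        assert fy.alpha == pytest.approx(base.alpha + 3.0, rel=1e-9)
        np.testing.assert_allclose(fy.psi_hat[1:], base.psi_hat[1:], rtol=1e-9)

    def test_empty_side_raises(self):
        data = RDDDataset.from_crisp(
            [1.0, 2.0, 3.0, 4.0], [10.0, 11.0, 12.0, 13.0], cutoff=15.0
        )
        with pytest.raises(InsufficientDataError):
            fit_pooled(data)

    def test_cluster_robust_needs_ids(self, noisy_dataset):
        with pytest.raises(ValueError, match="cluster"):
            fit_pooled(noisy_dataset, cluster_robust=True)

    def test_cluster_robust_same_coefficients(self, rng):
        x = rng.uniform(5, 25, 80)
        y = rng.normal(0, 1, 80) + (x >= 15)
        ids = rng.integers(0, 16, 80)
        data = RDDDataset.from_crisp(y, x, 15.0, cluster_ids=ids)
        plain = fit_pooled(data)
        clustered = fit_pooled(data, cluster_robust=True)
        np.testing.assert_allclose(clustered.psi_hat, plain.psi_hat, rtol=1e-12)
        assert clustered.standard_errors != plain.standard_errors


class TestModified:
    def test_crisp_limit_equals_pooled(self, noisy_dataset):
        mod = fit_modified(noisy_dataset)
        pooled = fit_pooled(noisy_dataset, parameterization="sidewise")
        assert mod.psi_hat == pooled.psi_hat
        np.testing.assert_array_equal(mod.residuals, pooled.residuals)

    def _fuzzy_dataset(self, rng, symmetric):
        x = rng.uniform(5, 25, 50)
        d = (x >= 15).astype(float)
        y = 1 + 0.5 * (1 - d) * (x - 15) + 0.3 * d * (x - 15) + d
        obs = []
        for yi, xi in zip(y, x):
            if symmetric:
                wy, wx = rng.uniform(0.1, 1.0, 2)
                y_fz = TriangularFuzzyNumber(yi - wy, yi, yi + wy)
                x_fz = TriangularFuzzyNumber(xi - wx, xi, xi + wx)
            else:
                y_fz = fuzzify(yi, 1.0, rng=rng)
                x_fz = fuzzify(xi, 1.0, rng=rng)
            obs.append(FuzzyObservation(y_fz, x_fz))
        return RDDDataset(obs, TriangularFuzzyNumber.crisp(15.0))

    def test_symmetric_spreads_equal_mode_fit(self, rng):
        # symmetric triangles have centroid == mode, so the fuzzy fit
        # coincides with the crisp fit on the modes
        data = self._fuzzy_dataset(rng, symmetric=True)
        mod = fit_modified(data)
        y_modes = [o.y_star.mode for o in data.observations]
        x_modes = [o.x_star.mode for o in data.observations]
        crisp = fit_pooled(RDDDataset.from_crisp(y_modes, x_modes, 15.0))
        np.testing.assert_allclose(mod.psi_hat, crisp.psi_hat, rtol=1e-10)

    def test_asymmetric_spreads_equal_centroid_fit(self, rng):
        data = self._fuzzy_dataset(rng, symmetric=False)
        mod = fit_modified(data)
        y_c = [o.y_star.centroid() for o in data.observations]
        x_c = [o.x_star.centroid() for o in data.observations]
        crisp = fit_pooled(RDDDataset.from_crisp(y_c, x_c, 15.0))
        np.testing.assert_allclose(mod.psi_hat, crisp.psi_hat, rtol=1e-10)

    def test_fuzzy_cutoff_defuzzified(self, rng):
        data = self._fuzzy_dataset(rng, symmetric=False)
        data.cutoff = TriangularFuzzyNumber(12.0, 15.0, 18.0)  # centroid 15
        mod = fit_modified(data)
        assert mod.cutoff_value == pytest.approx(15.0)


class TestTreatmentEffect:
    def test_is_delta(self, noisy_dataset):
        fit = fit_pooled(noisy_dataset)
        assert treatment_effect(fit) == fit.psi_hat[3]

    def test_equals_prediction_jump_at_cutoff(self, noisy_dataset):
        # difference of model-predicted outcomes just at/below the cutoff
        for param in ("sidewise", "interaction"):
            fit = fit_pooled(noisy_dataset, parameterization=param)
            at = fit.predict(np.array([15.0]))[0]
            eps = 1e-9
            below = fit.predict(np.array([15.0 - eps]))[0]
            assert treatment_effect(fit) == pytest.approx(at - below, abs=1e-6)

    def test_mismatched_sides_rejected(self, noisy_dataset):
        above = fit_side(noisy_dataset, "above")
        with pytest.raises(ValueError, match="above"):
            estimate_discontinuity_two_sided(above, above)
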