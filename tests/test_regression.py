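"""Gradient-descent polynomial training: oracles, descent, prediction."""

import numpy as np
import pytest

import optircb
from optircb import (
    ConvergenceError,
    NotFittedError,
    PhantomSample,
    PolyAbsorptionModel,
    ReflectanceProfile,
    TrainingConfig,
)
from optircb.regression import evaluate_model, fit_polynomial_model, predict_absorption

POOLED = TrainingConfig(pooling="pooled")

#: Monomial coefficients (low to high degree) of the ground-truth
#: polynomial used in the exact-recovery tests; absorption-scale values.
TRUTH_MONOMIAL = np.array([0.008, 0.003, -0.001, 0.0005, -0.0002])


def model_design(model, x):
    """Re-apply the model's stored feature transform by hand."""
    pw = np.stack([x**p for p in range(1, model.config.degree + 1)], axis=-1)
    z = (pw - model.feature_mean[0]) / model.feature_scale[0]
    design = np.column_stack([np.ones(len(x)), z])
    return design @ model.whiten[0]


def make_samples(reflectance_2d, absorption_2d):
    return [
        PhantomSample(phantom_id=i, reflectance=r, absorption=a,
                      scattering=np.ones_like(r))
        for i, (r, a) in enumerate(zip(reflectance_2d, absorption_2d))
    ]


@pytest.fixture()
def polynomial_truth_samples():
    """Samples whose absorption is an exact degree-4 polynomial of the
    pooled reflectance — recoverable with zero error."""
    rng = np.random.default_rng(3)
    refl = rng.uniform(0.5, 1.5, size=(10, 128))
    absorption = np.polynomial.polynomial.polyval(refl, TRUTH_MONOMIAL)
    return make_samples(refl, absorption), TRUTH_MONOMIAL


class TestFit:
    def test_exact_polynomial_recovery(self, polynomial_truth_samples):
        """Zero-noise data from a degree-4 polynomial is recovered exactly:
        vanishing MSE and the fitted function's monomial coefficients
        within 1e-4 of the generating ones."""
        samples, truth = polynomial_truth_samples
        model = fit_polynomial_model(samples, POOLED)
        mse, r2 = evaluate_model(model, samples)
        assert mse < 1e-10
        assert r2 == pytest.approx(1.0)
        x = np.concatenate([s.reflectance for s in samples])
        fitted = np.concatenate([
            predict_absorption(
                model,
                ReflectanceProfile(values=s.reflectance, patient_id=0,
                                   side="healthy", slice_id=0,
                                   treatment_id=0, eled=1),
            ).values
            for s in samples
        ])
        recovered = np.polynomial.polynomial.polyfit(x, fitted, 4)
        assert np.abs(recovered - truth).max() < 1e-4

    def test_gd_matches_normal_equations(self):
        """Full-batch GD at the default rate reaches the least-squares
        solution of the same conditioned design (n=200 oracle)."""
        rng = np.random.default_rng(7)
        refl = rng.uniform(0.2, 2.0, size=(200, 1))
        absorption = 0.01 * np.exp(-refl) + rng.normal(0, 1e-4, refl.shape)
        samples = make_samples(refl.reshape(200, 1), absorption.reshape(200, 1))
        model = fit_polynomial_model(samples, POOLED)
        design = model_design(model, refl.ravel())
        oracle, *_ = np.linalg.lstsq(design, absorption.ravel(), rcond=None)
        assert np.abs(model.coefficients[0] - oracle).max() < 1e-6

    def test_cost_history_non_increasing(self, default_model):
        """Descent is monotone up to 1-ulp roundoff at the fixed point."""
        costs = default_model.cost_history
        assert costs.size == default_model.config.n_iterations + 1
        assert np.all(np.diff(costs) <= 1e-12 * costs[0])
        assert costs[-1] <= costs[1]

    def test_permutation_invariance(self):
        samples = optircb.generate_phantom_dataset(n_phantoms=30, seed=2)
        cfg = TrainingConfig(n_iterations=500)
        a = fit_polynomial_model(samples, cfg)
        rng = np.random.default_rng(0)
        shuffled = [samples[i] for i in rng.permutation(len(samples))]
        b = fit_polynomial_model(shuffled, cfg)
        assert np.abs(a.coefficients - b.coefficients).max() < 1e-9

    def test_cv_scores_populated(self, default_model):
        assert len(default_model.cv_scores) == default_model.config.k_folds
        assert all(s.mse > 0 for s in default_model.cv_scores)

    def test_divergence_raises_naming_rate(self):
        samples = optircb.generate_phantom_dataset(n_phantoms=20, seed=5)
        cfg = TrainingConfig(learning_rate=6.0, n_iterations=200)
        with pytest.raises(ConvergenceError, match="6.0"):
            fit_polynomial_model(samples, cfg)

    def test_degenerate_reflectance_rejected(self):
        refl = np.ones((5, 16))
        samples = make_samples(refl, refl * 0.01)
        with pytest.raises(ValueError, match="distinct|degenerate"):
            fit_polynomial_model(samples, POOLED)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            fit_polynomial_model([], POOLED)


class TestPredict:
    def test_training_point_interpolation(self, polynomial_truth_samples):
        samples, _ = polynomial_truth_samples
        model = fit_polynomial_model(samples, POOLED)
        s = samples[0]
        profile = ReflectanceProfile(
            values=s.reflectance, patient_id=0, side="healthy",
            slice_id=0, treatment_id=0, eled=1,
        )
        curve = predict_absorption(model, profile)
        assert np.abs(curve.values - s.absorption).max() < 1e-8

    def test_output_length_and_metadata(self, default_model):
        profile = ReflectanceProfile(
            values=np.full(128, 1e-6), patient_id=4, side="unhealthy",
            slice_id=2, treatment_id=1, eled=1, wavelength_nm=690,
        )
        curve = predict_absorption(default_model, profile)
        assert curve.values.shape == (128,)
        assert (curve.patient_id, curve.slice_id, curve.treatment_id) == (4, 2, 1)
        assert curve.side == "unhealthy"

    def test_inversion_recovers_planted_absorption(self, default_model):
        """Zero-noise cohort profile at known mu_a: mean prediction within
        10% of the planted value."""
        spec = optircb.CohortSpec(
            n_patients=1, slices_per_patient=1, noise_sd=0.0,
            tumor_amplitude=0.0, baseline_mu_a=0.005, seed=1,
        )
        profiles, _ = optircb.generate_patient_cohort(spec)
        curve = predict_absorption(default_model, profiles[0])
        assert abs(curve.values.mean() - 0.005) / 0.005 < 0.10

    def test_eled2_profile_maps_to_source_relative_order(self, default_model):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(1e-6, 1e-7, 128)) + 1e-8
        p1 = ReflectanceProfile(values=vals, patient_id=0, side="healthy",
                                slice_id=0, treatment_id=0, eled=1)
        p2 = ReflectanceProfile(values=vals[::-1], patient_id=0, side="healthy",
                                slice_id=0, treatment_id=0, eled=2)
        c1 = predict_absorption(default_model, p1)
        c2 = predict_absorption(default_model, p2)
        assert np.allclose(c1.values, c2.values)

    def test_unfitted_model_raises(self):
        with pytest.raises(NotFittedError):
            predict_absorption(
                PolyAbsorptionModel(config=TrainingConfig()),
                ReflectanceProfile(values=np.ones(128), patient_id=0,
                                   side="healthy", slice_id=0,
                                   treatment_id=0, eled=1),
            )


class TestEvaluate:
    def test_perfect_fit(self, polynomial_truth_samples):
        samples, _ = polynomial_truth_samples
        model = fit_polynomial_model(samples, POOLED)
        mse, r2 = evaluate_model(model, samples)
        assert mse < 1e-10
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_null_model_scores_zero_r2(self):
        """A model trained on constant targets predicts the mean, so R²
        on targets centred at that mean is ~0."""
        rng = np.random.default_rng(2)
        refl = rng.uniform(0.5, 1.5, size=(20, 8))
        const = make_samples(refl, np.full_like(refl, 0.01))
        model = fit_polynomial_model(const, POOLED)
        test_y = 0.01 + rng.normal(0, 0.002, size=(20, 8))
        test_y -= test_y.mean() - 0.01  # centre exactly at the prediction
        mse, r2 = evaluate_model(model, make_samples(refl, test_y))
        assert abs(r2) < 0.05

    def test_zero_variance_targets_signalled(self, polynomial_truth_samples):
        samples, _ = polynomial_truth_samples
        model = fit_polynomial_model(samples, POOLED)
        refl = samples[0].reflectance[None, :]
        const = make_samples(refl, np.full_like(refl, 0.01))
        with pytest.raises(ValueError, match="zero variance"):
            evaluate_model(model, const)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, polynomial_truth_samples):
        samples, _ = polynomial_truth_samples
        model = fit_polynomial_model(samples, POOLED)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PolyAbsorptionModel.from_json(path)
        assert np.array_equal(loaded.coefficients, model.coefficients)
        assert np.array_equal(loaded.feature_mean, model.feature_mean)
        assert loaded.config == model.config
        assert [s.fold for s in loaded.cv_scores] == [s.fold for s in model.cv_scores]
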