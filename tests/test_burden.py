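"""Residual-disease scoring and the oRCB statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import optircb
from optircb import (
    InsufficientDataError,
    TreatmentSummary,
    compute_orcb,
    slice_residual,
    superpose_eleds,
    treatment_summary,
)
from conftest import make_curve


def summaries_from_errors(errors, start=0):
    return [
        TreatmentSummary(treatment_id=start + i, total_unhealthy=0.0,
                         total_healthy=0.0, total_error=e)
        for i, e in enumerate(errors)
    ]


class TestSuperposition:
    def test_identical_curves_idempotent(self):
        vals = np.linspace(0.004, 0.008, 128)
        combined = superpose_eleds(
            make_curve(vals, eled=1), make_curve(vals[::-1], eled=2)
        )
        # e2's curve is reversed into detector coordinates before averaging
        assert np.allclose(combined.values, vals)

    def test_constant_curves_average(self):
        combined = superpose_eleds(
            make_curve(np.full(128, 3.0), eled=1),
            make_curve(np.full(128, 5.0), eled=2),
        )
        assert np.allclose(combined.values, 4.0)

    def test_symmetric_phantom_combines_symmetrically(self, default_model):
        """Tumor at the exact detector centre, zero noise: the combined
        absorption estimate is symmetric under source exchange."""
        spec = optircb.CohortSpec(
            n_patients=1, slices_per_patient=1, noise_sd=0.0,
            tumor_center=(0.0, 63.5), seed=0,
        )
        profiles, _ = optircb.generate_patient_cohort(spec)
        by = {(p.side, p.eled): p for p in profiles if p.treatment_id == 0}
        combined = superpose_eleds(
            optircb.predict_absorption(default_model, by[("unhealthy", 1)]),
            optircb.predict_absorption(default_model, by[("unhealthy", 2)]),
        )
        assert np.abs(combined.values - combined.values[::-1]).max() < 1e-8

    def test_metadata_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            superpose_eleds(
                make_curve(np.ones(128), eled=1, slice_id=0),
                make_curve(np.ones(128), eled=2, slice_id=1),
            )

    def test_needs_one_curve_per_eled(self):
        with pytest.raises(ValueError, match="eLED"):
            superpose_eleds(
                make_curve(np.ones(128), eled=1), make_curve(np.ones(128), eled=1)
            )


class TestSliceResidual:
    def test_null_difference(self):
        vals = np.linspace(1.0, 2.0, 128)
        res = slice_residual(make_curve(vals), make_curve(vals, side="unhealthy"))
        assert res.error == 0.0
        assert res.auc_unhealthy == pytest.approx(res.auc_healthy)

    def test_triangular_bump_closed_form(self):
        """Unit triangle of half-width 10 has trapezoid area exactly 10."""
        healthy = np.full(128, 5.0)
        k = np.arange(128)
        bump = np.maximum(0.0, 1.0 - np.abs(k - 40) / 10.0)
        res = slice_residual(
            make_curve(healthy), make_curve(healthy + bump, side="unhealthy")
        )
        assert res.error == pytest.approx(10.0)

    def test_negative_differences_do_not_cancel(self):
        healthy = np.full(128, 5.0)
        unhealthy = healthy.copy()
        unhealthy[10:20] += 1.0   # excess plateau: trapezoid area 10
        unhealthy[60:70] -= 1.0   # equal deficit must not offset the excess
        res = slice_residual(
            make_curve(healthy), make_curve(unhealthy, side="unhealthy")
        )
        assert res.error == pytest.approx(10.0)

    def test_reference_patient_pretreatment_totals(self):
        """Curves built to the recorded pretreatment AUC totals of the
        complete-responder reference patient reproduce its printed error."""
        n = 128
        healthy_level = 1838.4 / (n - 1)  # trapezoid of a constant curve
        healthy = np.full(n, healthy_level)
        k = np.arange(n)
        bump = np.maximum(0.0, 1.0 - np.abs(k - 63.5) / 20.0)
        bump *= 64.56 / np.trapezoid(bump)
        res = slice_residual(
            make_curve(healthy), make_curve(healthy + bump, side="unhealthy")
        )
        # the recorded table rounds AUCs to 0.1, so its unhealthy-healthy
        # difference (64.5) and error (64.56) disagree below that precision
        assert res.auc_healthy == pytest.approx(1838.4, abs=0.1)
        assert res.auc_unhealthy == pytest.approx(1902.9, abs=0.1)
        assert res.error == pytest.approx(64.56, abs=0.005)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            slice_residual(make_curve(np.ones(128)), make_curve(np.ones(64)))


class TestTreatmentSummary:
    def test_singleton(self):
        res = slice_residual(
            make_curve(np.full(128, 1.0)), make_curve(np.full(128, 1.5))
        )
        total = treatment_summary([res])
        assert total.total_error == pytest.approx(res.error)
        assert total.total_healthy == pytest.approx(res.auc_healthy)

    def test_additivity(self):
        from optircb import SliceResidual

        r1 = SliceResidual(slice_id=0, treatment_id=2, auc_healthy=1.0,
                           auc_unhealthy=4.0, error=3.0)
        r2 = SliceResidual(slice_id=1, treatment_id=2, auc_healthy=2.0,
                           auc_unhealthy=9.0, error=7.0)
        total = treatment_summary([r1, r2])
        assert total.total_error == pytest.approx(10.0)
        assert total.treatment_id == 2

    def test_mixed_treatments_rejected(self):
        from optircb import SliceResidual

        r1 = SliceResidual(0, 0, 1.0, 1.0, 0.0)
        r2 = SliceResidual(0, 1, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError, match="mix"):
            treatment_summary([r1, r2])

    def test_no_tumor_cohort_scores_zero_error(self, default_model):
        spec = optircb.CohortSpec(
            n_patients=1, slices_per_patient=2, n_treatments=2,
            tumor_amplitude=0.0, noise_sd=0.0, seed=0,
        )
        profiles, _ = optircb.generate_patient_cohort(spec)
        summaries, _ = optircb.score_profiles(default_model, profiles)
        assert all(s.total_error == 0.0 for s in summaries[0])


class TestComputeOrcb:
    @pytest.mark.parametrize(
        "errors,expected",
        [
            ((160.95, 130.92), 81.34),
            ((33.34, 21.46), 64.37),
        ],
    )
    def test_reference_patient_values(self, errors, expected):
        est = compute_orcb(summaries_from_errors(errors))
        assert round(est.value, 2) == expected

    def test_equal_errors_score_100(self):
        est = compute_orcb(summaries_from_errors([5.0, 5.0, 5.0]))
        assert est.value == 100.0

    def test_any_zero_error_scores_0(self):
        est = compute_orcb(summaries_from_errors([12.0, 0.0, 3.0]))
        assert est.value == 0.0
        assert est.treatments_used == (1, 0)

    def test_all_zero_errors_score_0(self):
        est = compute_orcb(summaries_from_errors([0.0, 0.0]))
        assert est.value == 0.0

    def test_missing_treatments_excluded(self):
        nan = float("nan")
        est = compute_orcb(summaries_from_errors([39.97, 34.34, nan, nan, 21.46]))
        assert est.value == pytest.approx(100 * 21.46 / 39.97)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            compute_orcb(summaries_from_errors([5.0]))
        with pytest.raises(InsufficientDataError):
            compute_orcb(summaries_from_errors([5.0, float("nan")]))

    @given(
        errors=st.lists(st.floats(0.01, 1e6), min_size=2, max_size=8),
        scale=st.floats(0.01, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_scale_invariance(self, errors, scale):
        a = compute_orcb(summaries_from_errors(errors))
        b = compute_orcb(summaries_from_errors([e * scale for e in errors]))
        assert 0.0 <= a.value <= 100.0
        assert a.value == pytest.approx(b.value, rel=1e-9)

    def test_shrinking_final_error_never_raises_orcb(self):
        errors = [50.0, 30.0, 20.0]
        base = compute_orcb(summaries_from_errors(errors)).value
        smaller = compute_orcb(summaries_from_errors([50.0, 30.0, 10.0])).value
        assert smaller <= base
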