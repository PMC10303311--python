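"""Residual-disease quantification and the oRCB statistic.

Absorption curves estimated from the two eLEDs are superposed into one
curve per slice; the cancerous side is compared against the contralateral
healthy baseline; the area under the positive part of the difference —
the residual-disease error — is summed over slices per treatment; and the
optical residual cancer burden (oRCB) of a patient is

    oRCB = 100 * min_t(total error) / max_t(total error)   (percent),

the smallest per-treatment error (usually the last cycle) relative to the
largest (usually pretreatment). A patient whose residual disease vanishes
by the final cycle scores 0; one whose disease never shrinks scores 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .regression import AbsorptionCurve

__all__ = [
    "SliceResidual",
    "TreatmentSummary",
    "ORCBEstimate",
    "InsufficientDataError",
    "superpose_eleds",
    "slice_residual",
    "treatment_summary",
    "compute_orcb",
]

#: Below this total error at every treatment, disease is deemed absent.
ZERO_ERROR_EPS = 1e-12


class InsufficientDataError(ValueError):
    """Raised when a patient has fewer than two usable treatments."""


@dataclass(frozen=True)
class SliceResidual:
    """Residual disease of one slice at one treatment."""

    slice_id: int
    treatment_id: int
    auc_healthy: float
    auc_unhealthy: float
    error: float

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("residual-disease error must be non-negative")


@dataclass(frozen=True)
class TreatmentSummary:
    """Per-treatment totals over all slices of one patient."""

    treatment_id: int
    total_unhealthy: float
    total_healthy: float
    total_error: float

    def __post_init__(self) -> None:
        if self.total_error < 0:
            raise ValueError("total error must be non-negative")


@dataclass(frozen=True)
class ORCBEstimate:
    """The oRCB statistic of one patient, in percent."""

    patient_id: int
    value: float
    min_error: float
    max_error: float
    treatments_used: tuple[int, int]  # (argmin, argmax) treatment ids

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ValueError("oRCB must lie in [0, 100]")


def _check_metadata(a: AbsorptionCurve, b: AbsorptionCurve, fields: Sequence[str]) -> None:
    for f in fields:
        if getattr(a, f) != getattr(b, f):
            raise ValueError(
                f"curve metadata mismatch on {f!r}: {getattr(a, f)!r} vs {getattr(b, f)!r}"
            )


def superpose_eleds(
    curve_e1: AbsorptionCurve, curve_e2: AbsorptionCurve
) -> AbsorptionCurve:
    """Combine the absorption estimates of the two light sources.

    The sources illuminate from opposite ends of the detector, so each
    point of the tissue is probed along two light paths; the combined
    estimate at a position is the mean of the two single-source estimates
    after reversing eLED 2's curve into eLED 1's detector coordinates.
    """
    _check_metadata(
        curve_e1, curve_e2,
        ("patient_id", "side", "slice_id", "treatment_id", "wavelength_nm"),
    )
    if {curve_e1.eled, curve_e2.eled} != {1, 2}:
        raise ValueError("superposition needs one curve from each eLED")
    if curve_e1.values.size != curve_e2.values.size:
        raise ValueError("curves must have equal length")
    a = curve_e1.values if curve_e1.eled == 1 else curve_e1.values[::-1]
    b = curve_e2.values[::-1] if curve_e2.eled == 2 else curve_e2.values
    return replace(curve_e1, values=0.5 * (a + b), eled=1)


def slice_residual(
    healthy: AbsorptionCurve, unhealthy: AbsorptionCurve
) -> SliceResidual:
    """Residual-disease area of one slice.

    Integrates (trapezoid rule, unit spacing in detector-position index)
    the healthy and unhealthy absorption curves and the positive part of
    their difference. Taking the positive part before integrating keeps
    positions where the cancerous side reads *below* baseline from
    cancelling genuine excess absorption elsewhere in the slice.
    """
    if healthy.values.size != unhealthy.values.size:
        raise ValueError("curves must have equal length")
    _check_metadata(healthy, unhealthy, ("patient_id", "slice_id", "treatment_id"))
    auc_h = float(np.trapezoid(healthy.values))
    auc_u = float(np.trapezoid(unhealthy.values))
    excess = np.maximum(unhealthy.values - healthy.values, 0.0)
    return SliceResidual(
        slice_id=healthy.slice_id,
        treatment_id=healthy.treatment_id,
        auc_healthy=auc_h,
        auc_unhealthy=auc_u,
        error=float(np.trapezoid(excess)),
    )


def treatment_summary(slices: Sequence[SliceResidual]) -> TreatmentSummary:
    """Sum slice residuals of one treatment into patient-level totals."""
    if len(slices) == 0:
        raise ValueError("no slices provided")
    treatment_ids = {s.treatment_id for s in slices}
    if len(treatment_ids) != 1:
        raise ValueError(f"slices mix treatments: {sorted(treatment_ids)}")
    return TreatmentSummary(
        treatment_id=slices[0].treatment_id,
        total_unhealthy=sum(s.auc_unhealthy for s in slices),
        total_healthy=sum(s.auc_healthy for s in slices),
        total_error=sum(s.error for s in slices),
    )


def compute_orcb(
    summaries: Sequence[TreatmentSummary],
    patient_id: int = 0,
    eps: float = ZERO_ERROR_EPS,
) -> ORCBEstimate:
    """The oRCB statistic: 100 x min over max of per-treatment errors.

    Treatments with missing (non-finite) totals are excluded; at least two
    usable treatments are required. If the largest error does not exceed
    ``eps`` there was no measurable disease at any cycle and the value is
    0 (complete response). The result is clamped to [0, 100].
    """
    usable = [s for s in summaries if math.isfinite(s.total_error)]
    if len(usable) < 2:
        raise InsufficientDataError(
            f"patient {patient_id}: need >= 2 treatments with data, "
            f"have {len(usable)}"
        )
    errors = np.asarray([s.total_error for s in usable])
    i_min, i_max = int(np.argmin(errors)), int(np.argmax(errors))
    lo, hi = float(errors[i_min]), float(errors[i_max])
    value = 0.0 if hi <= eps else float(np.clip(100.0 * lo / hi, 0.0, 100.0))
    return ORCBEstimate(
        patient_id=patient_id,
        value=value,
        min_error=lo,
        max_error=hi,
        treatments_used=(usable[i_min].treatment_id, usable[i_max].treatment_id),
    )
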