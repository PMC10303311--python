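"""End-to-end orchestration: phantoms -> model -> cohort -> oRCB -> pRCB.

``run_pipeline`` wires the stages together exactly as they would run on
real scans: train the absorption model on a phantom set, estimate
absorption curves for every cohort scan line, superpose the two eLED
views, score residual disease per slice and treatment, compute each
patient's oRCB, and (when pathological RCB values are supplied for some
patients) fit the oRCB-to-pRCB map and classify everyone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import (
    InsufficientDataError,
    ORCBEstimate,
    SliceResidual,
    TreatmentSummary,
    compute_orcb,
    slice_residual,
    superpose_eleds,
    treatment_summary,
)
from .io import RunConfig, write_ground_truth, write_scan_table
from .prcb import PRCBModel, PRCBPrediction, fit_prcb_model, predict_prcb
from .regression import PolyAbsorptionModel, fit_polynomial_model, predict_absorption
from .synthetic import (
    HEALTHY,
    UNHEALTHY,
    ReflectanceProfile,
    generate_patient_cohort,
    generate_phantom_dataset,
)

__all__ = ["PipelineResult", "score_profiles", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    model: PolyAbsorptionModel
    summaries: dict[int, list[TreatmentSummary]]
    orcb: dict[int, ORCBEstimate]
    prcb_model: PRCBModel | None = None
    predictions: dict[int, PRCBPrediction] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": pid,
                "treatment_id": s.treatment_id,
                "unhealthy": s.total_unhealthy,
                "healthy": s.total_healthy,
                "error": s.total_error,
            }
            for pid, summaries in sorted(self.summaries.items())
            for s in summaries
        ]
        return pd.DataFrame(rows)

    def patient_frame(self) -> pd.DataFrame:
        rows = []
        for pid, est in sorted(self.orcb.items()):
            row: dict = {"patient_id": pid, "orcb": est.value}
            pred = self.predictions.get(pid)
            if pred is not None:
                row.update(
                    prcb_value=pred.prcb_value,
                    ci_lower=pred.ci_lower,
                    ci_upper=pred.ci_upper,
                    rcb_class=pred.rcb_class,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def score_profiles(
    model: PolyAbsorptionModel,
    profiles: Sequence[ReflectanceProfile],
    reuse_healthy_baseline: bool = False,
    zero_error_eps: float = 1e-12,
) -> tuple[dict[int, list[TreatmentSummary]], dict[int, ORCBEstimate]]:
    """Score scan lines into per-treatment summaries and per-patient oRCB.

    Curves from the two eLEDs of each (patient, side, slice, treatment)
    are superposed; the healthy side is the per-treatment baseline, or —
    with ``reuse_healthy_baseline`` — the earliest treatment's healthy
    scan reused as a fixed reference across all treatments.
    """
    combined: dict[tuple[int, str, int, int], dict[int, object]] = {}
    for p in profiles:
        key = (p.patient_id, p.side, p.slice_id, p.treatment_id)
        combined.setdefault(key, {})[p.eled] = predict_absorption(model, p)

    curves = {}
    for (pid, side, sl, tr), by_eled in combined.items():
        if set(by_eled) != {1, 2}:
            raise ValueError(
                f"patient {pid} side {side} slice {sl} treatment {tr}: "
                f"need both eLEDs, have {sorted(by_eled)}"
            )
        curves[(pid, side, sl, tr)] = superpose_eleds(by_eled[1], by_eled[2])

    patients = sorted({k[0] for k in curves})
    summaries: dict[int, list[TreatmentSummary]] = {}
    orcb: dict[int, ORCBEstimate] = {}
    for pid in patients:
        treatments = sorted({k[3] for k in curves if k[0] == pid})
        baseline_tr = treatments[0]
        per_treatment: list[TreatmentSummary] = []
        for tr in treatments:
            slices = sorted({k[2] for k in curves if k[0] == pid and k[3] == tr})
            residuals: list[SliceResidual] = []
            for sl in slices:
                healthy_key = (
                    (pid, HEALTHY, sl, baseline_tr)
                    if reuse_healthy_baseline
                    else (pid, HEALTHY, sl, tr)
                )
                healthy = curves[healthy_key]
                unhealthy = curves[(pid, UNHEALTHY, sl, tr)]
                if reuse_healthy_baseline and healthy.treatment_id != tr:
                    healthy = replace(healthy, treatment_id=tr)
                residuals.append(slice_residual(healthy, unhealthy))
            per_treatment.append(treatment_summary(residuals))
        summaries[pid] = per_treatment
        try:
            orcb[pid] = compute_orcb(per_treatment, patient_id=pid, eps=zero_error_eps)
        except InsufficientDataError:
            logger.warning("patient %d skipped: insufficient treatments", pid)
    return summaries, orcb


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    known_prcb: Mapping[int, float] | None = None,
    profiles: Sequence[ReflectanceProfile] | None = None,
) -> PipelineResult:
    """Run the full analysis and optionally write the report bundle.

    With no ``profiles``, a synthetic cohort is simulated from the config;
    ``known_prcb`` maps patient ids to pathological RCB values and, when
    given (three or more), drives the oRCB-to-pRCB regression. The report
    bundle is a treatment-summary CSV, a patient oRCB/pRCB CSV, the
    trained model JSON and, for simulated cohorts, the ground-truth
    sidecar and the scan table itself.
    """
    logging.basicConfig(level=config.log_level)
    logger.info("pipeline start, config %s", config.digest())
    geometry = config.probe_geometry()

    phantoms = generate_phantom_dataset(
        n_phantoms=config.phantoms.n_phantoms,
        mu_a_range=config.phantoms.mu_a_range,
        mu_s_range=config.phantoms.mu_s_range,
        geometry=geometry,
        noise_sd=config.phantoms.noise_sd,
        seed=config.phantoms.seed,
    )
    model = fit_polynomial_model(phantoms, config.training_config())

    truth = None
    if profiles is None:
        profiles, truth = generate_patient_cohort(config.cohort_spec(), geometry)

    summaries, orcb = score_profiles(
        model,
        profiles,
        reuse_healthy_baseline=config.analysis.reuse_healthy_baseline,
        zero_error_eps=config.analysis.zero_error_eps,
    )

    result = PipelineResult(model=model, summaries=summaries, orcb=orcb)
    if known_prcb:
        pairs = [
            (orcb[pid].value, value)
            for pid, value in sorted(known_prcb.items())
            if pid in orcb
        ]
        if len(pairs) < 3 or np.ptp([p[0] for p in pairs]) == 0:
            logger.warning(
                "pRCB mapping skipped: need >= 3 graded patients with "
                "non-constant oRCB, have %d", len(pairs),
            )
        else:
            result.prcb_model = fit_prcb_model(pairs)
            for pid, est in sorted(orcb.items()):
                result.predictions[pid] = predict_prcb(
                    result.prcb_model,
                    est.value,
                    confidence=config.analysis.confidence,
                    patient_id=pid,
                )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.summary_frame().to_csv(out / "treatment_summaries.csv", index=False)
        result.patient_frame().to_csv(out / "patients.csv", index=False)
        model.to_json(out / "absorption_model.json")
        config.to_json(out / "config.json")
        if truth is not None:
            write_ground_truth(truth, out / "ground_truth.json")
            write_scan_table(profiles, out / "scans.csv")
        logger.info("report bundle written to %s", out)
    return result
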