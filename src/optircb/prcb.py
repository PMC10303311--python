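"""Mapping optical RCB to the pathological RCB index and class.

Patients who reach surgery have a pathological residual cancer burden
(pRCB) index graded from the resection specimen; the optical surrogate
(oRCB, percent) is available for every monitored patient. A straight-line
ordinary-least-squares fit on the patients with known pRCB converts oRCB
into a predicted pRCB index, with a constant-half-width t confidence
interval, and the index is binned into the standard response classes:

    RCB-0 (= 0, complete response), RCB-I (0, 1.36],
    RCB-II (1.36, 3.28], RCB-III (> 3.28).

The interval deliberately carries no leverage term: with a handful of
training pairs the goal is an honest constant uncertainty band, and the
half-width t(1-alpha/2, n-2) * s_resid is reported identically at every
prediction point. Negative point predictions are clamped to 0 (a negative
disease burden is not meaningful) while the interval brackets the raw,
unclamped prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RCB_CLASS_BOUNDS",
    "PRCBModel",
    "PRCBPrediction",
    "fit_prcb_model",
    "predict_prcb",
    "classify_rcb",
]

#: Upper bound (inclusive) of each class on the pRCB index scale.
RCB_CLASS_BOUNDS: tuple[tuple[str, float], ...] = (
    ("RCB-0", 0.0),
    ("RCB-I", 1.36),
    ("RCB-II", 3.28),
    ("RCB-III", float("inf")),
)


def classify_rcb(value: float) -> str:
    """Bin a non-negative pRCB index into its response class.

    Exact zero is a pathological complete response (RCB-0); the remaining
    cut points 1.36 and 3.28 are inclusive upper bounds.
    """
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"pRCB index must be finite and >= 0, got {value!r}")
    if value == 0.0:
        return "RCB-0"
    if value <= 1.36:
        return "RCB-I"
    if value <= 3.28:
        return "RCB-II"
    return "RCB-III"


@dataclass(frozen=True)
class PRCBModel:
    """Straight-line oRCB-to-pRCB fit with its diagnostics."""

    slope: float
    intercept: float
    residual_se: float
    df: int
    r_squared: float
    mse: float
    train_pairs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("need residual degrees of freedom >= 1")
        if self.residual_se < 0:
            raise ValueError("residual standard error must be >= 0")


@dataclass(frozen=True)
class PRCBPrediction:
    """Predicted pRCB index, uncertainty band and class for one patient."""

    patient_id: int
    orcb: float
    prcb_raw: float
    prcb_value: float
    ci_lower: float
    ci_upper: float
    confidence: float
    rcb_class: str

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.prcb_raw <= self.ci_upper:
            raise ValueError("interval must bracket the raw prediction")


def fit_prcb_model(pairs: Sequence[tuple[float, float]]) -> PRCBModel:
    """Ordinary least squares of known pRCB on oRCB, with intercept.

    Needs at least three pairs with non-constant oRCB. ``r_squared``
    follows the usual centred convention; when the pRCB targets are
    constant the fit is the flat line and R² is reported as 0.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 training pairs, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("oRCB values are all identical; slope is unidentifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    sse = float(res.ssr)
    df = int(res.df_resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 0.0 if sst == 0 else 1.0 - sse / sst
    return PRCBModel(
        slope=float(slope),
        intercept=float(intercept),
        residual_se=float(np.sqrt(sse / df)),
        df=df,
        r_squared=r_squared,
        mse=sse / len(pairs),
        train_pairs=tuple((float(a), float(b)) for a, b in pairs),
    )


def predict_prcb(
    model: PRCBModel, orcb: float, confidence: float = 0.95, patient_id: int = 0
) -> PRCBPrediction:
    """Predict the pRCB index from an oRCB value.

    The interval is ``raw ± t(1-alpha/2, df) * residual_se`` — the same
    half-width at every oRCB. The point estimate is clamped at 0 and
    classified; the interval brackets the unclamped prediction.
    """
    if not 0.0 <= orcb <= 100.0:
        raise ValueError(f"oRCB must lie in [0, 100], got {orcb}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    raw = model.intercept + model.slope * orcb
    half_width = float(stats.t.ppf(0.5 + confidence / 2.0, model.df)) * model.residual_se
    value = max(raw, 0.0)
    return PRCBPrediction(
        patient_id=patient_id,
        orcb=float(orcb),
        prcb_raw=float(raw),
        prcb_value=float(value),
        ci_lower=float(raw - half_width),
        ci_upper=float(raw + half_width),
        confidence=confidence,
        rcb_class=classify_rcb(value),
    )
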