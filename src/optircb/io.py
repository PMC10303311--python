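"""File formats and run configuration.

Scan lines travel as long-form CSV (one row per detector position),
summaries and patient tables as CSV mirroring the cohort tables, models
and configuration as JSON. Configuration is validated strictly: unknown
keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .probe import ProbeGeometry
from .regression import TrainingConfig
from .synthetic import CohortSpec, CohortTruth, ReflectanceProfile

__all__ = [
    "SCAN_COLUMNS",
    "ScanTableError",
    "read_scan_table",
    "write_scan_table",
    "write_ground_truth",
    "read_ground_truth",
    "RunConfig",
]

SCAN_COLUMNS = (
    "patient_id",
    "side",
    "slice_id",
    "treatment_id",
    "eled",
    "wavelength_nm",
    "position_index",
    "reflectance",
)

_GROUP_KEYS = list(SCAN_COLUMNS[:6])


class ScanTableError(ValueError):
    """Raised for malformed scan-table files, naming the offending rows."""


def write_scan_table(profiles: Sequence[ReflectanceProfile], path: str | Path) -> None:
    """Write profiles as a long-form scan CSV (one row per position)."""
    frames = []
    for p in profiles:
        n = p.values.size
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": p.patient_id,
                    "side": p.side,
                    "slice_id": p.slice_id,
                    "treatment_id": p.treatment_id,
                    "eled": p.eled,
                    "wavelength_nm": p.wavelength_nm,
                    "position_index": np.arange(n),
                    "reflectance": p.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_scan_table(
    path: str | Path, n_positions: int = 128
) -> list[ReflectanceProfile]:
    """Read a scan CSV back into profiles, validating completeness.

    Every (patient, side, slice, treatment, eLED, wavelength) group must
    contain exactly ``n_positions`` rows with distinct position indices
    0..n_positions-1 and strictly positive reflectance.
    """
    df = pd.read_csv(path)
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise ScanTableError(f"scan table missing columns: {sorted(missing)}")
    bad = df.index[~(df["reflectance"] > 0)].tolist()
    if bad:
        raise ScanTableError(
            f"non-positive reflectance at data rows {bad[:10]}"
            + ("..." if len(bad) > 10 else "")
        )
    profiles: list[ReflectanceProfile] = []
    for key, grp in df.groupby(_GROUP_KEYS, sort=True):
        label = dict(zip(_GROUP_KEYS, key))
        positions = grp["position_index"].to_numpy()
        if len(grp) != n_positions or set(positions) != set(range(n_positions)):
            raise ScanTableError(
                f"group {label} must have positions 0..{n_positions - 1} "
                f"exactly once (rows {grp.index[:5].tolist()}...)"
            )
        ordered = grp.sort_values("position_index")
        profiles.append(
            ReflectanceProfile(
                values=ordered["reflectance"].to_numpy(),
                patient_id=int(label["patient_id"]),
                side=str(label["side"]),
                slice_id=int(label["slice_id"]),
                treatment_id=int(label["treatment_id"]),
                eled=int(label["eled"]),
                wavelength_nm=int(label["wavelength_nm"]),
            )
        )
    return profiles


def write_ground_truth(truth: CohortTruth, path: str | Path) -> None:
    """Ground-truth sidecar: planted tumor amplitude per patient/treatment."""
    payload = {
        f"{pid}/{tid}": amp for (pid, tid), amp in sorted(truth.amplitudes.items())
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> CohortTruth:
    payload = json.loads(Path(path).read_text())
    amplitudes = {}
    for key, amp in payload.items():
        pid, tid = key.split("/")
        amplitudes[(int(pid), int(tid))] = float(amp)
    return CohortTruth(amplitudes=amplitudes)


# -- run configuration -------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Strict):
    n_pixels: int = 2048
    pixel_pitch_um: float = 14.0
    eled_offset_mm: float = 15.0
    wavelengths_nm: tuple[int, ...] = (690, 750, 800, 850)
    n_positions: int = 128


class PhantomSection(_Strict):
    n_phantoms: int = 640
    mu_a_range: tuple[float, float] = (0.003, 0.015)
    mu_s_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.01
    seed: int = 0


class TrainingSection(_Strict):
    degree: int = 4
    learning_rate: float = 0.5
    n_iterations: int = 10_000
    k_folds: int = 5
    seed: int = 0
    pooling: str = "per_position"


class CohortSection(_Strict):
    n_patients: int = 15
    slices_per_patient: int = 12
    n_treatments: int = 7
    tumor_amplitude: float = 0.004
    tumor_center: tuple[float, float] = (5.5, 63.5)
    tumor_width: tuple[float, float] = (2.0, 15.0)
    response_ratio: float = 0.3
    noise_sd: float = 0.01
    seed: int = 0
    baseline_mu_a: float = 0.005
    baseline_mu_s: float = 1.0
    wavelength_nm: int = 690


class AnalysisSection(_Strict):
    reuse_healthy_baseline: bool = False
    zero_error_eps: float = Field(default=1e-12, ge=0)
    confidence: float = Field(default=0.95, gt=0, lt=1)


class RunConfig(_Strict):
    """Validated configuration of one end-to-end pipeline run."""

    geometry: GeometrySection = GeometrySection()
    phantoms: PhantomSection = PhantomSection()
    training: TrainingSection = TrainingSection()
    cohort: CohortSection = CohortSection()
    analysis: AnalysisSection = AnalysisSection()
    log_level: str = "INFO"

    def probe_geometry(self) -> ProbeGeometry:
        return ProbeGeometry(**self.geometry.model_dump())

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(**self.training.model_dump())

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(**self.cohort.model_dump())

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))

    def digest(self) -> str:
        """Short stable hash of the configuration, for log provenance."""
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:12]
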