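"""Synthetic phantom and patient-cohort generators.

No clinical scans are distributed with the package, so every downstream
stage is exercised against simulated data with known ground truth: a
phantom training set (homogeneous breast-mimicking media scanned once
each) and longitudinal patient cohorts in which a localized absorption
excess — the tumor — decays over successive chemotherapy cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .probe import DIFFUSION_RATIO_MIN, ProbeGeometry, TissueOptics, diffuse_reflectance

__all__ = [
    "PhantomSample",
    "ReflectanceProfile",
    "CohortSpec",
    "CohortTruth",
    "generate_phantom_dataset",
    "generate_patient_cohort",
]

HEALTHY = "healthy"
UNHEALTHY = "unhealthy"


@dataclass(frozen=True)
class PhantomSample:
    """One phantom scan: reflectance with its generating ground truth.

    All three arrays have one value per detector position; ``absorption``
    and ``scattering`` are in 1/mm and record the truth the regression
    stage is trained against.
    """

    phantom_id: int
    reflectance: np.ndarray
    absorption: np.ndarray
    scattering: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=float)
        a = np.asarray(self.absorption, dtype=float)
        s = np.asarray(self.scattering, dtype=float)
        if not (r.shape == a.shape == s.shape) or r.ndim != 1:
            raise ValueError("reflectance/absorption/scattering must be 1-D and equal length")
        if np.any(r <= 0):
            raise ValueError("reflectance must be strictly positive")
        object.__setattr__(self, "reflectance", r)
        object.__setattr__(self, "absorption", a)
        object.__setattr__(self, "scattering", s)


@dataclass(frozen=True)
class ReflectanceProfile:
    """One scan line: reflectance values plus acquisition metadata."""

    values: np.ndarray
    patient_id: int
    side: str
    slice_id: int
    treatment_id: int
    eled: int
    wavelength_nm: int = 690

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if np.any(v <= 0):
            raise ValueError("reflectance must be strictly positive")
        if self.side not in (HEALTHY, UNHEALTHY):
            raise ValueError(f"side must be '{HEALTHY}' or '{UNHEALTHY}'")
        if self.eled not in (1, 2):
            raise ValueError("eled must be 1 or 2")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CohortSpec:
    """Simulation conditions for a longitudinal patient cohort.

    Defaults mirror the monitored-study structure: 15 patients, 12 scan
    slices per breast, 7 scan time points (pretreatment plus six
    post-treatment cycles), both breasts scanned with both eLEDs at
    690 nm. The tumor is a separable Gaussian absorption excess in
    (slice, position) whose amplitude decays geometrically from
    ``tumor_amplitude`` at pretreatment to
    ``response_ratio * tumor_amplitude`` at the final cycle.
    """

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

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.slices_per_patient < 1:
            raise ValueError("cohort must have at least one patient and slice")
        if self.n_treatments < 2:
            raise ValueError("need at least pretreatment plus one cycle")
        if not 0.0 <= self.response_ratio <= 1.0:
            raise ValueError("response_ratio must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tumor_amplitude < 0:
            raise ValueError("tumor_amplitude must be non-negative")


@dataclass(frozen=True)
class CohortTruth:
    """Planted per-patient, per-treatment tumor amplitudes (1/mm)."""

    amplitudes: dict[tuple[int, int], float]

    def amplitude(self, patient_id: int, treatment_id: int) -> float:
        return self.amplitudes[(patient_id, treatment_id)]


def _validate_ranges(name: str, rng_pair: tuple[float, float]) -> None:
    lo, hi = rng_pair
    if not (0 < lo <= hi):
        raise ValueError(f"{name} range must satisfy 0 < low <= high, got {rng_pair}")


def generate_phantom_dataset(
    n_phantoms: int = 640,
    mu_a_range: tuple[float, float] = (0.003, 0.015),
    mu_s_range: tuple[float, float] = (0.9, 1.1),
    geometry: ProbeGeometry | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    noise_seed: int | None = None,
) -> list[PhantomSample]:
    """Simulate a phantom training set with known optical properties.

    Each phantom is a homogeneous medium with absorption and reduced
    scattering drawn uniformly from the given ranges, scanned from eLED 1:
    reflectance is the diffusion forward model evaluated at the 128
    detector distances, perturbed by multiplicative log-normal noise of
    scale ``noise_sd``. Optics draws and noise draws come from
    independently seeded streams, so ``noise_seed`` can be varied while
    holding the ground-truth media fixed.
    """
    if n_phantoms < 1:
        raise ValueError("n_phantoms must be at least 1")
    _validate_ranges("mu_a", mu_a_range)
    _validate_ranges("mu_s", mu_s_range)
    if mu_s_range[0] / mu_a_range[1] < DIFFUSION_RATIO_MIN:
        raise ValueError(
            "ranges violate the diffusion regime: min(mu_s')/max(mu_a) "
            f"must be >= {DIFFUSION_RATIO_MIN}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    geometry = geometry or ProbeGeometry()

    optics_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    optics_rng = np.random.default_rng(optics_ss)
    noise_rng = np.random.default_rng(
        noise_ss if noise_seed is None else np.random.SeedSequence(noise_seed)
    )

    rho = geometry.source_detector_distances(eled=1)
    mu_a = optics_rng.uniform(*mu_a_range, size=n_phantoms)
    mu_s = optics_rng.uniform(*mu_s_range, size=n_phantoms)

    samples: list[PhantomSample] = []
    for i in range(n_phantoms):
        optics = TissueOptics(mu_a=mu_a[i], mu_s_prime=mu_s[i])
        clean = diffuse_reflectance(optics, rho)
        if noise_sd > 0:
            refl = clean * np.exp(noise_sd * noise_rng.standard_normal(rho.size))
        else:
            refl = np.asarray(clean).copy()
        samples.append(
            PhantomSample(
                phantom_id=i,
                reflectance=refl,
                absorption=np.full(rho.size, mu_a[i]),
                scattering=np.full(rho.size, mu_s[i]),
            )
        )
    return samples


def _tumor_profile(spec: CohortSpec, amplitude: float, n_positions: int) -> np.ndarray:
    """Per-(slice, position) absorption excess for one treatment."""
    s_c, p_c = spec.tumor_center
    s_w, p_w = spec.tumor_width
    slices = np.arange(spec.slices_per_patient, dtype=float)
    positions = np.arange(n_positions, dtype=float)
    slice_term = np.exp(-0.5 * ((slices - s_c) / s_w) ** 2)
    pos_term = np.exp(-0.5 * ((positions - p_c) / p_w) ** 2)
    return amplitude * np.outer(slice_term, pos_term)


def _amplitude_schedule(spec: CohortSpec) -> np.ndarray:
    """Geometric decay from full amplitude to response_ratio * amplitude."""
    t = np.arange(spec.n_treatments, dtype=float)
    frac = t / (spec.n_treatments - 1)
    if spec.response_ratio == 0.0:
        decay = np.where(frac > 0, 0.0, 1.0)
    else:
        decay = spec.response_ratio**frac
    return spec.tumor_amplitude * decay


def generate_patient_cohort(
    spec: CohortSpec, geometry: ProbeGeometry | None = None
) -> tuple[list[ReflectanceProfile], CohortTruth]:
    """Simulate reflectance scans for a treated cohort.

    For every patient, slice, treatment and eLED, emits one healthy-side
    profile (baseline optics) and one unhealthy-side profile (baseline
    plus the decaying Gaussian tumor excess), so the cohort contains
    ``n_patients * slices_per_patient * n_treatments * 2 sides * 2 eLEDs``
    profiles. Returns the profiles together with the planted per-treatment
    tumor amplitudes for recovery tests.
    """
    geometry = geometry or ProbeGeometry()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_pos = geometry.n_positions
    amplitudes = _amplitude_schedule(spec)

    profiles: list[ReflectanceProfile] = []
    truth: dict[tuple[int, int], float] = {}
    base = np.full(n_pos, spec.baseline_mu_a)

    for patient in range(spec.n_patients):
        for treatment in range(spec.n_treatments):
            truth[(patient, treatment)] = float(amplitudes[treatment])
            bump = _tumor_profile(spec, amplitudes[treatment], n_pos)
            for slice_id in range(spec.slices_per_patient):
                for side, mu_a in (
                    (HEALTHY, base),
                    (UNHEALTHY, base + bump[slice_id]),
                ):
                    optics = TissueOptics(mu_a=mu_a, mu_s_prime=spec.baseline_mu_s)
                    for eled in (1, 2):
                        rho = geometry.source_detector_distances(eled=eled)
                        clean = diffuse_reflectance(optics, rho)
                        if spec.noise_sd > 0:
                            vals = clean * np.exp(
                                spec.noise_sd * rng.standard_normal(n_pos)
                            )
                        else:
                            vals = np.asarray(clean).copy()
                        profiles.append(
                            ReflectanceProfile(
                                values=vals,
                                patient_id=patient,
                                side=side,
                                slice_id=slice_id,
                                treatment_id=treatment,
                                eled=eled,
                                wavelength_nm=spec.wavelength_nm,
                            )
                        )
    return profiles, CohortTruth(amplitudes=truth)
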