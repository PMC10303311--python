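"""Probe geometry and the diffuse-reflectance forward model.

The probe is a hand-held near-infrared scanner: a 2048-pixel linear CCD
(14 µm pitch) flanked by two encapsulated LEDs (eLEDs) mounted 15 mm from
either end of the detector, each selectable among 690/750/800/850 nm.
Backscattered light intensity versus distance from the source is recorded,
and 16 contiguous pixels are averaged into 128 detector positions.

The forward model used throughout the synthetic data path is the standard
steady-state diffusion-approximation reflectance of a semi-infinite
homogeneous medium: an isotropic point source buried at one transport mean
free path, mirrored across an extrapolated boundary whose offset follows
from the internal-reflection parameter of the tissue/air index mismatch.
It is valid in the diffusion regime (reduced scattering much larger than
absorption) and is used here as a physically monotone, invertible
reflectance-absorption link, not as a model of any particular instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProbeGeometry",
    "TissueOptics",
    "diffuse_reflectance",
    "average_pixels",
]

#: Minimum scattering-to-absorption ratio accepted for generated media.
DIFFUSION_RATIO_MIN = 10.0


@dataclass(frozen=True)
class ProbeGeometry:
    """Physical layout of the line-scan probe.

    Parameters
    ----------
    n_pixels:
        Number of active CCD pixels.
    pixel_pitch_um:
        Pixel pitch in micrometres.
    eled_offset_mm:
        Distance from each eLED to the near edge of the CCD, in mm.
    wavelengths_nm:
        Selectable source wavelengths, in nm.
    n_positions:
        Number of averaged detector positions per scan line.
    """

    n_pixels: int = 2048
    pixel_pitch_um: float = 14.0
    eled_offset_mm: float = 15.0
    wavelengths_nm: tuple[int, ...] = (690, 750, 800, 850)
    n_positions: int = 128

    def __post_init__(self) -> None:
        if self.n_pixels <= 0 or self.n_positions <= 0:
            raise ValueError("pixel and position counts must be positive")
        if self.n_pixels % self.n_positions != 0:
            raise ValueError(
                f"n_pixels ({self.n_pixels}) must be an integer multiple of "
                f"n_positions ({self.n_positions})"
            )
        if not set(self.wavelengths_nm) <= {690, 750, 800, 850}:
            raise ValueError("wavelengths must be a subset of {690, 750, 800, 850} nm")

    @property
    def block_size(self) -> int:
        """Number of contiguous pixels averaged into one detector position."""
        return self.n_pixels // self.n_positions

    @property
    def block_width_mm(self) -> float:
        """Width of one averaged detector position, in mm."""
        return self.block_size * self.pixel_pitch_um * 1e-3

    def source_detector_distances(self, eled: int = 1) -> np.ndarray:
        """Source-detector separation of each detector position, in mm.

        Position ``k`` is mapped to the centre of its pixel block:
        ``eled_offset + (k + 0.5) * block_width`` from eLED 1. The two
        sources illuminate from opposite ends of the CCD, so for eLED 2
        the same positions are seen in reversed order.
        """
        k = np.arange(self.n_positions)
        rho = self.eled_offset_mm + (k + 0.5) * self.block_width_mm
        if eled == 1:
            return rho
        if eled == 2:
            return rho[::-1].copy()
        raise ValueError(f"eled must be 1 or 2, got {eled!r}")


@dataclass(frozen=True)
class TissueOptics:
    """Bulk optical properties of a turbid medium.

    ``mu_a`` (absorption) and ``mu_s_prime`` (reduced scattering) are in
    1/mm; either may be a scalar or a per-position profile. The diffusion
    approximation requires scattering-dominated transport, enforced as
    ``mu_s_prime / mu_a >= 10``.
    """

    mu_a: float | np.ndarray
    mu_s_prime: float | np.ndarray
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        mu_a = np.asarray(self.mu_a, dtype=float)
        mu_s = np.asarray(self.mu_s_prime, dtype=float)
        if np.any(mu_a <= 0) or np.any(mu_s <= 0):
            raise ValueError("optical coefficients must be strictly positive")
        if np.any(mu_s / mu_a < DIFFUSION_RATIO_MIN):
            raise ValueError(
                "diffusion regime requires mu_s_prime/mu_a >= "
                f"{DIFFUSION_RATIO_MIN}"
            )
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")


def _internal_reflection_parameter(n_rel: float) -> float:
    """Boundary mismatch parameter A for the extrapolated boundary.

    Uses the empirical polynomial fit of the effective internal reflection
    coefficient in the relative refractive index, the standard choice for
    tissue/air interfaces.
    """
    r_eff = -1.440 * n_rel**-2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_eff) / (1.0 - r_eff)


def diffuse_reflectance(
    optics: TissueOptics, rho: float | np.ndarray
) -> float | np.ndarray:
    """Steady-state diffuse reflectance of a semi-infinite medium.

    Evaluates the extrapolated-boundary dipole solution at source-detector
    separation ``rho`` (mm): an isotropic source at depth
    ``z0 = 1/(mu_a + mu_s')`` and its negative image mirrored across the
    boundary plane at ``-zb = -2AD``. Reflectance is returned in relative
    units; only ratios and shapes are meaningful downstream.

    Strictly decreasing in ``rho`` and in ``mu_a``.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr <= 0):
        raise ValueError("source-detector distance must be strictly positive")

    mu_a = np.asarray(optics.mu_a, dtype=float)
    mu_s = np.asarray(optics.mu_s_prime, dtype=float)
    mu_t = mu_a + mu_s
    z0 = 1.0 / mu_t
    diff_const = 1.0 / (3.0 * mu_t)
    mu_eff = np.sqrt(mu_a / diff_const)
    zb = 2.0 * _internal_reflection_parameter(optics.refractive_index) * diff_const

    r1 = np.sqrt(z0**2 + rho_arr**2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho_arr**2)
    out = (
        z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
        + (z0 + 2.0 * zb) * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    ) / (4.0 * np.pi)
    if np.isscalar(rho) and out.ndim == 0:
        return float(out)
    return out


def average_pixels(raw_frame: np.ndarray, block_size: int = 16) -> np.ndarray:
    """Average contiguous pixel blocks of a raw CCD frame.

    ``output[k]`` is the arithmetic mean of
    ``raw_frame[block_size*k : block_size*(k+1)]``; a 2048-pixel frame with
    the default block size yields 128 detector positions.
    """
    frame = np.asarray(raw_frame, dtype=float)
    if frame.ndim != 1:
        raise ValueError("raw frame must be one-dimensional")
    if block_size <= 0:
        raise ValueError("block size must be positive")
    if frame.size % block_size != 0:
        raise ValueError(
            f"frame length {frame.size} is not divisible by block size {block_size}"
        )
    return frame.reshape(-1, block_size).mean(axis=1)
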