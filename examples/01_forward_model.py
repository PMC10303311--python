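"""Diffuse reflectance of a breast-like medium versus distance and absorption.

Evaluates the semi-infinite diffusion-approximation forward model on the
probe's detector geometry: reflectance falls off steeply with
source-detector distance, and at any fixed distance it falls as the
absorption coefficient rises — the monotone link the whole inverse
pipeline rests on.
"""

import numpy as np

from optircb import ProbeGeometry, TissueOptics, diffuse_reflectance

geometry = ProbeGeometry()
rho = geometry.source_detector_distances(eled=1)

print(f"detector positions: {geometry.n_positions}, "
      f"distances {rho[0]:.3f} .. {rho[-1]:.3f} mm from the eLED\n")

print("reflectance (relative units) at selected distances:")
print(f"{'mu_a (1/mm)':>12} " + " ".join(f"{r:>9.1f}mm" for r in rho[[0, 32, 64, 96, 127]]))
for mu_a in (0.003, 0.006, 0.009, 0.012, 0.015):
    optics = TissueOptics(mu_a=mu_a, mu_s_prime=1.0)
    vals = diffuse_reflectance(optics, rho[[0, 32, 64, 96, 127]])
    print(f"{mu_a:>12.3f} " + " ".join(f"{v:>11.3e}" for v in vals))

print(
    "\nEach row decreases left to right (farther detectors see less light)\n"
    "and each column decreases top to bottom (more absorbing tissue\n"
    "returns less light) — so reflectance at a fixed distance identifies\n"
    "the local absorption coefficient."
)
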