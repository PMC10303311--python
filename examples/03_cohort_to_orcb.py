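"""Score a simulated treatment cohort: residual disease and oRCB recovery.

Simulates patients whose tumor absorption contrast decays geometrically
over the treatment cycles, runs the full scoring chain (absorption
estimation -> dual-eLED superposition -> healthy-baseline subtraction ->
per-treatment AUC -> oRCB), and compares the recovered oRCB with the
planted response ratio.
"""

import numpy as np

from optircb import (
    CohortSpec,
    fit_polynomial_model,
    generate_patient_cohort,
    generate_phantom_dataset,
    score_profiles,
)

model = fit_polynomial_model(generate_phantom_dataset(n_phantoms=640, seed=1))

print(f"{'planted response ratio':>23} {'recovered oRCB (%)':>19}")
ratios = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
recovered = []
for r in ratios:
    spec = CohortSpec(
        n_patients=1, slices_per_patient=6, noise_sd=0.0,
        response_ratio=r, seed=3,
    )
    profiles, _ = generate_patient_cohort(spec)
    summaries, orcb = score_profiles(model, profiles)
    recovered.append(orcb[0].value)
    print(f"{r:>23.1f} {orcb[0].value:>19.2f}")

corr = np.corrcoef(ratios, recovered)[0, 1]
print(f"\nPearson correlation (oRCB/100 vs planted ratio): {corr:.4f}")
print(
    "\nA patient keeping r of the initial tumor contrast at the final\n"
    "cycle should score an oRCB near 100*r; the small systematic offset\n"
    "reflects the nonlinearity of the reflectance-absorption inverse."
)
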