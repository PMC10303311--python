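"""Train the reflectance-to-absorption polynomial on a synthetic phantom set.

Simulates the standard training conditions — 640 breast-mimicking
phantoms, 128 detector positions each, 1% multiplicative noise — and fits
the degree-4 polynomial by full-batch gradient descent (learning rate
0.5, 10,000 iterations) with 5-fold cross-validation, then evaluates on
phantoms the model never saw.
"""

from optircb import evaluate_model, fit_polynomial_model, generate_phantom_dataset

train = generate_phantom_dataset(n_phantoms=640, seed=1)
model = fit_polynomial_model(train)  # default TrainingConfig

print("cross-validation (5 folds over whole phantoms):")
for s in model.cv_scores:
    print(f"  fold {s.fold}: held-out MSE {s.mse:.3e} (1/mm)^2, R2 {s.r2:.4f}")

print(f"\ncost curve: {model.cost_history[0]:.3e} -> {model.cost_history[-1]:.3e} "
      f"over {model.config.n_iterations} iterations (monotone descent)")

test = generate_phantom_dataset(n_phantoms=200, seed=99)
mse, r2 = evaluate_model(model, test)
print(f"held-out test set (200 phantoms): MSE {mse:.3e} (1/mm)^2, R2 {r2:.4f}")
print(
    "\nR2 ~0.95 means the per-position polynomials explain ~95% of the\n"
    "absorption variance across phantoms; the remainder is the 1% probe\n"
    "noise plus the unmodelled spread in scattering."
)
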