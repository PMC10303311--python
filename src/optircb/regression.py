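"""Reflectance-to-absorption regression.

The inverse map from measured reflectance to the tissue absorption
coefficient is learned from phantom scans as polynomial regression fitted
by full-batch gradient descent, with k-fold cross-validation and MSE/R²
diagnostics. Because reflectance at a detector position depends on both
the local absorption and the source-detector distance of that position,
the default is a distance-resolved ensemble: one degree-d polynomial per
detector position, trained jointly (vectorized) on the phantom set. A
single pooled scalar-to-scalar model is available via
``TrainingConfig(pooling="pooled")``.

Each polynomial feature column (the powers of reflectance) is z-scored
and the columns are then decorrelated (whitened) before descent. Powers
of a positive-valued signal are strongly collinear; whitening makes the
design Gram matrix the identity, so the stated learning rate of 0.5 is
scale-free, the cost descends monotonically, and the iterates reach the
least-squares solution to machine precision well within the default
iteration budget.

Gradient descent on the quadratic cost J(w) = ||Xw - y||^2 / (2n) is run
through the precomputed sufficient statistics G = X'X/n and b = X'y/n;
the iterates w <- w - lr (Gw - b) are algebraically identical to
full-batch descent on the raw design.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .synthetic import PhantomSample, ReflectanceProfile

__all__ = [
    "TrainingConfig",
    "PolyAbsorptionModel",
    "AbsorptionCurve",
    "FoldScore",
    "NotFittedError",
    "ConvergenceError",
    "fit_polynomial_model",
    "predict_absorption",
    "evaluate_model",
]

logger = logging.getLogger(__name__)


class NotFittedError(RuntimeError):
    """Raised when prediction is attempted with an untrained model."""


class ConvergenceError(RuntimeError):
    """Raised when the gradient-descent cost diverges."""


@dataclass(frozen=True)
class TrainingConfig:
    degree: int = 4
    learning_rate: float = 0.5
    n_iterations: int = 10_000
    k_folds: int = 5
    seed: int = 0
    pooling: Literal["per_position", "pooled"] = "per_position"

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass(frozen=True)
class FoldScore:
    """Held-out diagnostics of one cross-validation fold."""

    fold: int
    mse: float
    r2: float


@dataclass
class PolyAbsorptionModel:
    """Trained polynomial map from reflectance to absorption (1/mm).

    ``coefficients`` has shape (n_groups, degree + 1) — one weight vector
    per detector position in the default distance-resolved mode, a single
    row in pooled mode. ``feature_mean``/``feature_scale`` hold the
    per-group z-scoring of each polynomial power of reflectance and
    ``whiten`` the per-group decorrelating transform applied after it.
    """

    config: TrainingConfig
    coefficients: np.ndarray | None = None
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    whiten: np.ndarray | None = None
    cost_history: np.ndarray | None = None
    cv_scores: list[FoldScore] = field(default_factory=list)

    @property
    def is_fitted(self) -> bool:
        return self.coefficients is not None

    @property
    def n_groups(self) -> int:
        if self.coefficients is None:
            raise NotFittedError("model has not been fitted")
        return self.coefficients.shape[0]

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        if not self.is_fitted:
            raise NotFittedError("cannot serialize an unfitted model")
        payload = {
            "config": {
                "degree": self.config.degree,
                "learning_rate": self.config.learning_rate,
                "n_iterations": self.config.n_iterations,
                "k_folds": self.config.k_folds,
                "seed": self.config.seed,
                "pooling": self.config.pooling,
            },
            "coefficients": self.coefficients.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "whiten": self.whiten.tolist(),
            "cv_scores": [
                {"fold": s.fold, "mse": s.mse, "r2": s.r2} for s in self.cv_scores
            ],
            "final_cost": float(self.cost_history[-1]),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PolyAbsorptionModel":
        payload = json.loads(Path(path).read_text())
        model = cls(config=TrainingConfig(**payload["config"]))
        model.coefficients = np.asarray(payload["coefficients"], dtype=float)
        model.feature_mean = np.asarray(payload["feature_mean"], dtype=float)
        model.feature_scale = np.asarray(payload["feature_scale"], dtype=float)
        model.whiten = np.asarray(payload["whiten"], dtype=float)
        model.cost_history = np.asarray([payload["final_cost"]])
        model.cv_scores = [FoldScore(**s) for s in payload["cv_scores"]]
        return model


@dataclass(frozen=True)
class AbsorptionCurve:
    """Per-position absorption estimates with scan metadata."""

    values: np.ndarray
    patient_id: int
    side: str
    slice_id: int
    treatment_id: int
    eled: int
    wavelength_nm: int = 690

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("absorption values must be a finite 1-D array")
        object.__setattr__(self, "values", v)


# -- internals ---------------------------------------------------------


def _stack_training_arrays(
    train: Sequence[PhantomSample], pooling: str
) -> tuple[np.ndarray, np.ndarray]:
    """Arrange samples as (n_groups, n_obs) reflectance/absorption arrays."""
    refl = np.stack([s.reflectance for s in train])  # (n_samples, n_positions)
    absn = np.stack([s.absorption for s in train])
    if pooling == "pooled":
        return refl.reshape(1, -1), absn.reshape(1, -1)
    return refl.T.copy(), absn.T.copy()  # (n_positions, n_samples)


def _powers(x: np.ndarray, degree: int) -> np.ndarray:
    """Powers x^1..x^degree along a new trailing axis."""
    return np.stack([x**p for p in range(1, degree + 1)], axis=-1)


def _standardize_design(
    x: np.ndarray,
    degree: int,
    mean: np.ndarray | None = None,
    scale: np.ndarray | None = None,
    whiten: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-scored, whitened polynomial design with intercept; x is (G, n).

    The transforms are estimated from x when not supplied (training) and
    re-applied as given otherwise (prediction). Whitening multiplies the
    standardized design by the inverse Cholesky factor of its Gram matrix,
    making the columns exactly orthonormal on the training data.
    """
    pw = _powers(x, degree)  # (G, n, degree)
    if mean is None:
        mean = pw.mean(axis=1)
        scale = pw.std(axis=1)
        if np.any(scale == 0):
            raise ValueError(
                "degenerate (constant) reflectance: polynomial features have "
                "zero variance"
            )
    z = (pw - mean[:, None, :]) / scale[:, None, :]
    ones = np.ones(z.shape[:2] + (1,))
    design = np.concatenate([ones, z], axis=-1)
    if whiten is None:
        n_obs = design.shape[1]
        gram = np.einsum("gnp,gnq->gpq", design, design) / n_obs
        try:
            chol = np.linalg.cholesky(gram)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "polynomial features are exactly collinear; cannot condition "
                "the design"
            ) from exc
        eye = np.broadcast_to(np.eye(gram.shape[-1]), gram.shape)
        whiten = np.transpose(np.linalg.solve(chol, eye), (0, 2, 1))
    return np.einsum("gnp,gpq->gnq", design, whiten), mean, scale, whiten


def _gradient_descent(
    design: np.ndarray, y: np.ndarray, config: TrainingConfig, record_cost: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize J(w)=||Xw-y||^2/(2n) per group; returns (weights, cost curve).

    The recorded cost is the mean of the per-group costs, one value per
    iteration starting at the initial all-zero weights.
    """
    n_obs = design.shape[1]
    gram = np.einsum("gnp,gnq->gpq", design, design) / n_obs
    moment = np.einsum("gnp,gn->gp", design, y) / n_obs
    y_sq = (y**2).mean(axis=1)

    w = np.zeros((design.shape[0], design.shape[2]))
    costs = np.empty(config.n_iterations + 1) if record_cost else None

    def cost_of(weights: np.ndarray) -> float:
        quad = np.einsum("gp,gpq,gq->g", weights, gram, weights)
        lin = np.einsum("gp,gp->g", weights, moment)
        return float(np.mean(0.5 * quad - lin + 0.5 * y_sq))

    rising = 0
    prev = cost_of(w)
    if record_cost:
        costs[0] = prev
    for it in range(1, config.n_iterations + 1):
        w -= config.learning_rate * (np.einsum("gpq,gq->gp", gram, w) - moment)
        cur = cost_of(w)
        if record_cost:
            costs[it] = cur
        rising = rising + 1 if cur > prev else 0
        if rising > 10:
            raise ConvergenceError(
                f"cost diverged at learning rate {config.learning_rate}: "
                f"increased for {rising} consecutive iterations (iteration {it})"
            )
        if it % 100 == 0:
            logger.debug("iteration %d cost %.6e", it, cur)
        prev = cur
    return w, costs if record_cost else np.asarray([prev])


def _predict_groups(
    model: PolyAbsorptionModel, x: np.ndarray
) -> np.ndarray:
    """Apply the fitted polynomials; x has shape (n_groups, n_obs)."""
    design, _, _, _ = _standardize_design(
        x, model.config.degree, model.feature_mean, model.feature_scale, model.whiten
    )
    return np.einsum("gnp,gp->gn", design, model.coefficients)


# -- public operations -------------------------------------------------


def fit_polynomial_model(
    train: Sequence[PhantomSample], config: TrainingConfig | None = None
) -> PolyAbsorptionModel:
    """Train the reflectance-to-absorption polynomial by gradient descent.

    Reflectance/absorption pairs are grouped per detector position (or
    pooled, per ``config.pooling``), polynomial features are z-scored and
    whitened, and full-batch gradient descent runs for ``n_iterations`` at
    ``learning_rate``. Cross-validation folds split whole phantoms;
    ``cv_scores`` hold each fold's held-out MSE and R² pooled over
    positions, and ``cost_history`` records the training cost at every
    iteration of the final full-data fit.
    """
    config = config or TrainingConfig()
    if len(train) == 0:
        raise ValueError("training set is empty")
    x, y = _stack_training_arrays(train, config.pooling)
    if np.unique(x).size < config.degree + 1:
        raise ValueError(
            f"need at least degree+1={config.degree + 1} distinct reflectance values"
        )

    # cross-validation over whole phantoms
    cv_scores: list[FoldScore] = []
    n_samples = len(train)
    if n_samples >= config.k_folds:
        order = np.random.default_rng(config.seed).permutation(n_samples)
        folds = np.array_split(order, config.k_folds)
        for i, held in enumerate(folds):
            mask = np.ones(n_samples, dtype=bool)
            mask[held] = False
            x_tr, y_tr = _stack_training_arrays(
                [train[j] for j in np.flatnonzero(mask)], config.pooling
            )
            design, mean, scale, whiten = _standardize_design(x_tr, config.degree)
            w, _ = _gradient_descent(design, y_tr, config, record_cost=False)
            fold_model = PolyAbsorptionModel(
                config=config, coefficients=w, feature_mean=mean,
                feature_scale=scale, whiten=whiten,
            )
            x_te, y_te = _stack_training_arrays(
                [train[j] for j in held], config.pooling
            )
            pred = _predict_groups(fold_model, x_te)
            mse = float(np.mean((pred - y_te) ** 2))
            sst = float(np.sum((y_te - y_te.mean()) ** 2))
            r2 = 1.0 - float(np.sum((pred - y_te) ** 2)) / sst if sst > 0 else float("nan")
            cv_scores.append(FoldScore(fold=i, mse=mse, r2=r2))
            logger.info("fold %d held-out MSE %.3e R2 %.4f", i, mse, r2)

    design, mean, scale, whiten = _standardize_design(x, config.degree)
    w, costs = _gradient_descent(design, y, config, record_cost=True)
    logger.info("final training cost %.6e after %d iterations", costs[-1], config.n_iterations)
    return PolyAbsorptionModel(
        config=config,
        coefficients=w,
        feature_mean=mean,
        feature_scale=scale,
        whiten=whiten,
        cost_history=costs,
        cv_scores=cv_scores,
    )


def predict_absorption(
    model: PolyAbsorptionModel, profile: ReflectanceProfile
) -> AbsorptionCurve:
    """Predict the per-position absorption curve of one scan line.

    Each position is evaluated with the polynomial trained at its
    source-detector distance. Curves are returned in source-relative
    order (position 0 nearest the illuminating eLED): profiles recorded
    from eLED 2 are stored in detector coordinates and therefore reversed
    before evaluation. ``superpose_eleds`` flips eLED 2's curve back when
    aligning the two views.
    """
    if not model.is_fitted:
        raise NotFittedError("model has not been fitted")
    vals = np.asarray(profile.values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("profile contains non-finite reflectance")
    x = vals[::-1] if profile.eled == 2 else vals
    if model.config.pooling == "per_position":
        if vals.size != model.n_groups:
            raise ValueError(
                f"profile length {vals.size} does not match the "
                f"{model.n_groups} per-position models"
            )
        pred = _predict_groups(model, x[:, None])[:, 0]
    else:
        pred = _predict_groups(model, x[None, :])[0]
    return AbsorptionCurve(
        values=pred,
        patient_id=profile.patient_id,
        side=profile.side,
        slice_id=profile.slice_id,
        treatment_id=profile.treatment_id,
        eled=profile.eled,
        wavelength_nm=profile.wavelength_nm,
    )


def evaluate_model(
    model: PolyAbsorptionModel, test: Sequence[PhantomSample]
) -> tuple[float, float]:
    """Held-out (MSE, R²) pooled over samples and positions.

    R² is taken about the test-set mean; zero-variance targets make it
    undefined and raise ``ValueError``.
    """
    if not model.is_fitted:
        raise NotFittedError("model has not been fitted")
    if len(test) == 0:
        raise ValueError("test set is empty")
    x, y = _stack_training_arrays(test, model.config.pooling)
    pred = _predict_groups(model, x)
    sse = float(np.sum((pred - y) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    mse = sse / y.size
    if sst == 0:
        raise ValueError("R² undefined: test targets have zero variance")
    return mse, 1.0 - sse / sst
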