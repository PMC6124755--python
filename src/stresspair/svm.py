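"""Soft-margin SVM with a Laplacian kernel on the selected biomarker pair.

The comparison classifier: a C-SVC with kernel
``k(x, y) = exp(-sigma * ||x - y||)`` (Euclidean norm, so ``k(x, x) = 1``)
trained on the two features the top-scoring-pair search selects. Inputs are
standardized by default (the convention of the kernel-method toolchain this
mirrors) and the kernel width defaults to the median heuristic — the
reciprocal of the median pairwise distance in the standardized training set.
The dual problem is solved by scikit-learn's SMO implementation to a 1e-6
tolerance; the model contract is the converged soft-margin solution, not the
particular solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import ValidationError
from .io import FeatureMatrix

_CHUNK = 65536  # rows per kernel block when predicting very large inputs


@dataclass
class SvmConfig:
    """Hyperparameters of the C-SVC comparison model.

    ``C`` is the soft-margin cost (default 1, the toolchain default);
    ``sigma`` the Laplacian kernel width, or ``"auto"`` for the median
    heuristic; ``cv_folds`` the stratified cross-validation fold count used
    for the internal CV error; ``scale`` standardizes the two features on
    the training set before the kernel is applied.
    """

    C: float = 1.0
    sigma: float | str = "auto"
    cv_folds: int = 10
    seed: int = 0
    scale: bool = True

    def validate(self) -> None:
        if self.C <= 0:
            raise ValidationError(f"C must be positive, got {self.C}")
        if self.sigma != "auto" and (
            not isinstance(self.sigma, (int, float)) or self.sigma <= 0
        ):
            raise ValidationError(f"sigma must be positive or 'auto', got {self.sigma!r}")
        if self.cv_folds < 2:
            raise ValidationError(f"cv_folds must be >= 2, got {self.cv_folds}")


def laplacian_kernel(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    """``exp(-sigma * ||x - y||)`` for all row pairs of X and Y."""
    return np.exp(-sigma * cdist(X, Y))


def _median_heuristic(Xs: np.ndarray) -> float:
    d = pdist(Xs)
    d = d[d > 0]
    return 1.0 / float(np.median(d)) if d.size else 1.0


@dataclass
class SvmModel:
    """A trained Laplacian-kernel C-SVC restricted to one feature pair.

    Stores the support vectors (in standardized coordinates), dual
    coefficients and intercept, so prediction is a pure function of the
    document — no solver state is needed after training.
    """

    features: tuple[str, str]
    class_levels: tuple[str, str]
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    sigma: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    training_error: float
    cv_error: float
    config: SvmConfig = field(repr=False)

    def _transform(self, fm: FeatureMatrix) -> np.ndarray:
        missing = [f for f in self.features if f not in fm.data.columns]
        if missing:
            raise ValidationError(f"model feature(s) missing from data: {missing}")
        X = fm.data[list(self.features)].to_numpy()
        return (X - self.scaler_mean) / self.scaler_sd

    def decision_function(self, fm: FeatureMatrix) -> np.ndarray:
        Xs = self._transform(fm)
        out = np.empty(len(Xs))
        for start in range(0, len(Xs), _CHUNK):
            block = Xs[start : start + _CHUNK]
            K = laplacian_kernel(block, self.support_vectors, self.sigma)
            out[start : start + _CHUNK] = K @ self.dual_coef + self.intercept
        return out

    def predict(self, fm: FeatureMatrix) -> pd.Series:
        dec = self.decision_function(fm)
        predicted = np.where(dec > 0, self.class_levels[1], self.class_levels[0])
        return pd.Series(predicted, index=fm.data.index, name="predicted")

    # -- plain-text serialization -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "svm",
            "features": list(self.features),
            "class_levels": list(self.class_levels),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "sigma": self.sigma,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "training_error": self.training_error,
            "cv_error": self.cv_error,
            "config": {
                "C": self.config.C,
                "sigma": self.config.sigma,
                "cv_folds": self.config.cv_folds,
                "seed": self.config.seed,
                "scale": self.config.scale,
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SvmModel":
        if payload.get("type") != "svm":
            raise ValidationError(f"not an svm model document: {payload.get('type')!r}")
        return cls(
            features=tuple(payload["features"]),
            class_levels=tuple(payload["class_levels"]),
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            dual_coef=np.asarray(payload["dual_coef"], dtype=float),
            intercept=float(payload["intercept"]),
            sigma=float(payload["sigma"]),
            scaler_mean=np.asarray(payload["scaler_mean"], dtype=float),
            scaler_sd=np.asarray(payload["scaler_sd"], dtype=float),
            training_error=float(payload["training_error"]),
            cv_error=float(payload["cv_error"]),
            config=SvmConfig(**payload["config"]),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SvmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_svm(fm: FeatureMatrix, config: SvmConfig | None = None) -> SvmModel:
    """Train the C-SVC on a two-feature labeled matrix.

    ``fm`` must be restricted to exactly the two selected features and carry
    two nonempty classes. Returns the fitted model with its training error
    (misclassified fraction on the training set) and the seeded, stratified
    ``cv_folds``-fold cross-validation error computed with the training-set
    scaler and kernel width held fixed.
    """
    config = config or SvmConfig()
    config.validate()
    if fm.n_features != 2:
        raise ValidationError(
            f"SVM expects exactly 2 feature columns, got {fm.n_features}"
        )
    levels = fm.class_levels  # raises if labels absent; enforces two classes
    y = fm.labels.to_numpy()
    counts = [(y == lev).sum() for lev in levels]
    if min(counts) < config.cv_folds:
        raise ValidationError(
            f"cv_folds={config.cv_folds} exceeds the smallest class size {min(counts)}"
        )

    X = fm.values
    if config.scale:
        mean, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValidationError("cannot standardize a zero-variance feature")
    else:
        mean, sd = np.zeros(2), np.ones(2)
    Xs = (X - mean) / sd
    sigma = _median_heuristic(Xs) if config.sigma == "auto" else float(config.sigma)

    K = laplacian_kernel(Xs, Xs, sigma)
    yy = (y == levels[1]).astype(int)  # 0 = first level, 1 = second
    svc = SVC(C=config.C, kernel="precomputed", tol=1e-6)
    svc.fit(K, yy)
    train_pred = svc.predict(K)
    training_error = float((train_pred != yy).mean())

    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    miss = 0
    for tr, te in skf.split(Xs, yy):
        fold = SVC(C=config.C, kernel="precomputed", tol=1e-6)
        fold.fit(K[np.ix_(tr, tr)], yy[tr])
        miss += int((fold.predict(K[np.ix_(te, tr)]) != yy[te]).sum())
    cv_error = miss / len(yy)

    support = svc.support_
    return SvmModel(
        features=(fm.feature_names[0], fm.feature_names[1]),
        class_levels=levels,
        support_vectors=Xs[support],
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        sigma=sigma,
        scaler_mean=mean,
        scaler_sd=sd,
        training_error=training_error,
        cv_error=cv_error,
        config=config,
    )


def predict_svm(model: SvmModel, fm: FeatureMatrix) -> pd.Series:
    """Predict class labels from the sign of the kernel decision function."""
    return model.predict(fm)
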