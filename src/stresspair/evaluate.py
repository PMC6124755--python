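"""Confusion matrices, Monte Carlo null distributions, empirical p-values
and BCa bootstrap confidence intervals for classifier prediction error.

The significance machinery follows the resampling design of the source
analysis:

* the **null distribution** of prediction error is obtained by replacing the
  model's two feature values of every validation sample with independent
  uniform draws inside each feature's observed range (pooled over both
  classes), keeping the actual labels, and recording the misclassified
  fraction of the frozen model over N iterations;
* the **empirical p-value** of an observed prediction error is
  ``(r + 1) / (N + 1)`` with r the number of null draws with strictly lower
  error — never zero, with floor ``1 / (N + 1)``;
* the **bootstrap** resamples validation rows with replacement (model
  frozen, never refitted), and summarizes the replicate errors by their mean
  and a bias-corrected and accelerated (BCa) 95% percentile interval, with
  the bias term z0 from the fraction of replicates below the observed error
  and the acceleration a from the jackknife skewness of leave-one-out
  errors.

All operations are pure functions of (model, data, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ValidationError
from .io import FeatureMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------
@dataclass
class ConfusionMatrix:
    """2x2 count table indexed (actual class, predicted class)."""

    counts: np.ndarray
    class_levels: tuple[str, str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def correct(self) -> int:
        return int(np.trace(self.counts))

    @property
    def accuracy(self) -> float:
        return self.correct / self.total

    @property
    def prediction_error(self) -> float:
        """Misclassified fraction (off-diagonal sum over total)."""
        return 1.0 - self.accuracy

    def to_dataframe(self) -> pd.DataFrame:
        idx = pd.Index(self.class_levels, name="actual")
        cols = pd.Index(self.class_levels, name="predicted")
        return pd.DataFrame(self.counts, index=idx, columns=cols)


def confusion(
    actual,
    predicted,
    class_levels: tuple[str, str] | None = None,
) -> ConfusionMatrix:
    """Exact 2x2 confusion counts of two equal-length label vectors."""
    a = np.asarray(pd.Series(actual).astype(str))
    p = np.asarray(pd.Series(predicted).astype(str))
    if len(a) != len(p):
        raise ValidationError(f"length mismatch: {len(a)} actual vs {len(p)} predicted")
    levels = class_levels or tuple(sorted(set(a)))
    if len(levels) != 2:
        raise ValidationError(f"need exactly two class levels, got {levels}")
    unknown = (set(a) | set(p)) - set(levels)
    if unknown:
        raise ValidationError(f"unknown label(s): {sorted(unknown)}")
    counts = np.zeros((2, 2), dtype=int)
    for ai, lev_a in enumerate(levels):
        for pi, lev_p in enumerate(levels):
            counts[ai, pi] = int(((a == lev_a) & (p == lev_p)).sum())
    return ConfusionMatrix(counts=counts, class_levels=(levels[0], levels[1]))


# ---------------------------------------------------------------------------
# Monte Carlo null
# ---------------------------------------------------------------------------
@dataclass
class NullDistribution:
    """Monte Carlo draws of prediction error under feature randomization."""

    errors: np.ndarray
    seed: int
    feature_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(self.errors)

    @property
    def mean_error(self) -> float:
        return float(self.errors.mean())


def monte_carlo_null(
    model,
    template: FeatureMatrix,
    n_iterations: int = 10000,
    seed: int = 0,
) -> NullDistribution:
    """Null distribution of a frozen model's prediction error.

    ``model`` must expose ``features`` (the two feature names) and
    ``predict(FeatureMatrix)``; ``template`` supplies the observed per-feature
    [min, max] (pooled over both classes) and the actual labels. Each
    iteration replaces every template sample's feature values by independent
    uniforms within those ranges and records the misclassified fraction.
    """
    if n_iterations < 1:
        raise ValidationError(f"n_iterations must be >= 1, got {n_iterations}")
    if template.labels is None:
        raise ValidationError("template must carry labels")
    features = list(model.features)
    data = template.select_features(features).data
    lo = data.min(axis=0).to_numpy()
    hi = data.max(axis=0).to_numpy()
    degenerate = np.flatnonzero(lo == hi)
    if degenerate.size:
        raise ValidationError(
            f"degenerate range (min = max) for feature {features[degenerate[0]]!r}"
        )

    rng = np.random.default_rng(seed)
    n = template.n_samples
    actual = template.labels.to_numpy()
    draws = rng.uniform(lo, hi, size=(n_iterations, n, len(features)))
    big = FeatureMatrix(
        pd.DataFrame(
            draws.reshape(n_iterations * n, len(features)),
            columns=features,
            index=pd.RangeIndex(n_iterations * n).astype(str),
        )
    )
    predicted = model.predict(big).to_numpy().reshape(n_iterations, n)
    errors = (predicted != actual[None, :]).mean(axis=1)
    return NullDistribution(
        errors=errors,
        seed=seed,
        feature_ranges={f: (float(l), float(h)) for f, l, h in zip(features, lo, hi)},
    )


# ---------------------------------------------------------------------------
# empirical p-value
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class EmpiricalP:
    """Empirical p-value ``(r + 1) / (N + 1)`` of an observed error."""

    r: int
    N: int
    p: float


def empirical_p(epe: float, null: NullDistribution) -> EmpiricalP:
    """P-value of an observed prediction error against a Monte Carlo null.

    ``r`` counts null draws with strictly lower error than ``epe``; the
    returned p is exactly ``(r + 1) / (N + 1)`` and can never be zero.
    """
    if not 0.0 <= epe <= 1.0:
        raise ValidationError(f"epe must be in [0, 1], got {epe}")
    r = int((null.errors < epe).sum())
    N = null.n_iterations
    return EmpiricalP(r=r, N=N, p=(r + 1) / (N + 1))


# ---------------------------------------------------------------------------
# bootstrap with BCa interval
# ---------------------------------------------------------------------------
@dataclass
class BootstrapResult:
    """Bootstrap replicate errors with mean and BCa 95% interval."""

    replicate_errors: np.ndarray
    observed_epe: float
    ci_low: float
    ci_high: float
    z0: float
    a: float
    seed: int
    level: float = 0.95

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_errors)

    @property
    def mean_error(self) -> float:
        return float(self.replicate_errors.mean())


def _bca_interval(
    replicates: np.ndarray,
    observed: float,
    jackknife: np.ndarray,
    level: float,
) -> tuple[float, float, float, float]:
    """Standard Efron BCa percentile bounds; returns (lo, hi, z0, a)."""
    R = len(replicates)
    prop = (replicates < observed).sum() / R
    if prop in (0.0, 1.0):
        # degenerate bias estimate; clamp half a replicate inside
        logger.info("BCa bias proportion clamped away from %s", prop)
        prop = min(max(prop, 0.5 / R), 1 - 0.5 / R)
    z0 = norm.ppf(prop)
    dm = jackknife.mean() - jackknife
    denom = (dm**2).sum() ** 1.5
    a = float((dm**3).sum() / (6 * denom)) if denom > 0 else 0.0
    alpha = (1 - level) / 2
    bounds = []
    for z_alpha in (norm.ppf(alpha), norm.ppf(1 - alpha)):
        zz = z0 + z_alpha
        adj = norm.cdf(z0 + zz / (1 - a * zz)) if a * zz < 1 else 1.0
        bounds.append(float(np.quantile(replicates, min(max(adj, 0.0), 1.0))))
    return bounds[0], bounds[1], float(z0), a


def bootstrap_epe(
    model,
    validation: FeatureMatrix,
    n_replicates: int = 10000,
    seed: int = 0,
    level: float = 0.95,
) -> BootstrapResult:
    """Bootstrap the prediction error of a frozen model on a validation set.

    Rows are resampled with replacement (same n) ``n_replicates`` times; the
    model is never refitted. Per-sample misclassification is computed once,
    so each replicate error is the mean of a resampled 0/1 vector. Returns
    the replicate distribution with its BCa interval.
    """
    if validation.labels is None:
        raise ValidationError("validation set must carry labels")
    if n_replicates < 1:
        raise ValidationError(f"n_replicates must be >= 1, got {n_replicates}")
    if n_replicates < 100:
        warnings.warn(
            f"n_replicates={n_replicates} is small for interval estimation",
            stacklevel=2,
        )
    miss = (
        model.predict(validation).to_numpy() != validation.labels.to_numpy()
    ).astype(float)
    n = len(miss)
    observed = float(miss.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_replicates, n))
    replicates = miss[idx].mean(axis=1)

    if np.ptp(replicates) == 0:
        value = float(replicates[0])
        logger.info("all bootstrap replicates identical (%.6g); degenerate CI", value)
        lo = hi = value
        z0 = a = 0.0
    else:
        jackknife = (miss.sum() - miss) / (n - 1)
        lo, hi, z0, a = _bca_interval(replicates, observed, jackknife, level)
    return BootstrapResult(
        replicate_errors=replicates,
        observed_epe=observed,
        ci_low=lo,
        ci_high=hi,
        z0=z0,
        a=a,
        seed=seed,
        level=level,
    )
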