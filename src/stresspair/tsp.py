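"""Top-scoring-pair (TSP) rank classifier.

For a feature pair (i, j) and class c, let ``p_c = P(value_i < value_j)``
estimated over the samples of class c. The pair score is
``delta = |p1 - p2|``: the between-class difference in the probability that
one feature of the pair exceeds the other within a sample. The fitted
classifier is nothing but the y = x line in the (i, j) plane — a sample is
assigned to the class whose typical ordering it shows. Because only the
within-sample order of the two features matters, scores and predictions are
invariant under any strictly increasing transform applied jointly to both
features.

One caveat that distinguishes this use from expression-profiling practice:
the parameters carry heterogeneous physical units, and the comparison
``value_i < value_j`` is applied to the raw recorded values exactly as
measured. A pair can only discriminate if the two parameters' numeric ranges
actually cross between classes; no normalization is inserted.

Ties ``value_i == value_j`` count as NOT(value_i < value_j) when scoring
(strict inequality) and are assigned to the orientation class at prediction
time — both fixed, documented rules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ValidationError
from .io import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairScore:
    """Score of one unordered feature pair.

    ``gamma`` is the secondary (tie-break) score: with every sample's
    features replaced by their within-sample ranks, gamma is the absolute
    difference between the class means of (rank_j - rank_i). It orders pairs
    of equal delta and plays no other role.
    """

    feature_i: str
    feature_j: str
    p1: float
    p2: float
    delta: float
    gamma: float


@dataclass
class TspModel:
    """A fitted top-scoring pair and its y = x decision rule.

    ``orientation`` is the class predicted when ``value_i < value_j`` (the
    class with the larger p_c at fit time); the other class is predicted when
    ``value_i > value_j``; ties go to the orientation class.
    """

    feature_i: str
    feature_j: str
    orientation: str
    class_levels: tuple[str, str]
    delta: float
    gamma: float
    pair_scores: list[PairScore] | None = field(default=None, repr=False, compare=False)

    @property
    def features(self) -> tuple[str, str]:
        return (self.feature_i, self.feature_j)

    @property
    def pair(self) -> tuple[str, str]:
        return self.features

    def predict(self, fm: FeatureMatrix) -> pd.Series:
        return predict_tsp(self, fm)

    # -- plain-text serialization -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "tsp",
            "feature_i": self.feature_i,
            "feature_j": self.feature_j,
            "orientation": self.orientation,
            "class_levels": list(self.class_levels),
            "delta": self.delta,
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TspModel":
        if payload.get("type") != "tsp":
            raise ValidationError(f"not a tsp model document: {payload.get('type')!r}")
        return cls(
            feature_i=payload["feature_i"],
            feature_j=payload["feature_j"],
            orientation=payload["orientation"],
            class_levels=tuple(payload["class_levels"]),
            delta=float(payload["delta"]),
            gamma=float(payload["gamma"]),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TspModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _class_masks(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    levels = fm.class_levels
    y = fm.labels.to_numpy()
    mask1 = y == levels[0]
    mask2 = y == levels[1]
    if not mask1.any() or not mask2.any():
        raise ValidationError("each class must contain at least one sample")
    return mask1, mask2, levels


def _resolve(fm: FeatureMatrix, feat: str | int) -> int:
    if isinstance(feat, (int, np.integer)):
        if not 0 <= feat < fm.n_features:
            raise ValidationError(f"feature index {feat} out of range")
        return int(feat)
    try:
        return fm.feature_names.index(feat)
    except ValueError:
        raise ValidationError(f"unknown feature: {feat!r}") from None


def score_pair(fm: FeatureMatrix, i: str | int, j: str | int) -> PairScore:
    """Score one feature pair on a labeled matrix.

    ``i`` / ``j`` may be feature names or column indices. Class 1 is the
    lexicographically first label level.
    """
    ii, jj = _resolve(fm, i), _resolve(fm, j)
    if ii == jj:
        raise ValidationError("a pair must consist of two distinct features")
    mask1, mask2, _ = _class_masks(fm)
    X = fm.values
    less = X[:, ii] < X[:, jj]
    p1 = float(less[mask1].mean())
    p2 = float(less[mask2].mean())
    ranks = rankdata(X, axis=1)
    d = ranks[:, jj] - ranks[:, ii]
    gamma = float(abs(d[mask1].mean() - d[mask2].mean()))
    return PairScore(
        feature_i=fm.feature_names[ii],
        feature_j=fm.feature_names[jj],
        p1=p1,
        p2=p2,
        delta=abs(p1 - p2),
        gamma=gamma,
    )


def fit_tsp(fm: FeatureMatrix) -> TspModel:
    """Exhaustively score all feature pairs and return the top-scoring one.

    All p(p-1)/2 unordered pairs are evaluated; the winner maximizes delta,
    with ties broken by gamma and then by lexicographic feature-name order.
    The full ranked list is attached as ``model.pair_scores``. If every pair
    has delta 0 a model is still returned, with a logged warning that the
    data carry no pairwise rank signal.
    """
    mask1, mask2, levels = _class_masks(fm)
    if mask1.sum() < 2 or mask2.sum() < 2:
        raise ValidationError("each class needs >= 2 samples to fit")
    X = fm.values
    p = fm.n_features
    if p < 2:
        raise ValidationError("need >= 2 features to form a pair")
    names = fm.feature_names
    ranks = rankdata(X, axis=1)
    mean_rank_1 = ranks[mask1].mean(axis=0)
    mean_rank_2 = ranks[mask2].mean(axis=0)

    scores: list[PairScore] = []
    for a in range(p):
        less = X[:, [a]] < X[:, a + 1:]  # samples x (p - a - 1)
        p1s = less[mask1].mean(axis=0)
        p2s = less[mask2].mean(axis=0)
        for off, b in enumerate(range(a + 1, p)):
            gamma = abs(
                (mean_rank_1[b] - mean_rank_1[a]) - (mean_rank_2[b] - mean_rank_2[a])
            )
            scores.append(
                PairScore(
                    feature_i=names[a],
                    feature_j=names[b],
                    p1=float(p1s[off]),
                    p2=float(p2s[off]),
                    delta=float(abs(p1s[off] - p2s[off])),
                    gamma=float(gamma),
                )
            )
    scores.sort(key=lambda s: (-s.delta, -s.gamma, s.feature_i, s.feature_j))
    best = scores[0]
    if best.delta == 0:
        logger.warning(
            "all pair scores are zero: no pairwise rank signal discriminates "
            "the classes; returning the lexicographically first pair"
        )
    orientation = levels[0] if best.p1 >= best.p2 else levels[1]
    return TspModel(
        feature_i=best.feature_i,
        feature_j=best.feature_j,
        orientation=orientation,
        class_levels=levels,
        delta=best.delta,
        gamma=best.gamma,
        pair_scores=scores,
    )


def predict_tsp(model: TspModel, fm: FeatureMatrix) -> pd.Series:
    """Predict class labels by the y = x rule of a fitted pair.

    A sample is assigned the orientation class iff ``value_i <= value_j``
    (ties go to the orientation class), else the other class. Deterministic;
    requires both model features in ``fm``.
    """
    missing = [f for f in model.features if f not in fm.data.columns]
    if missing:
        raise ValidationError(f"model feature(s) missing from data: {missing}")
    vi = fm.data[model.feature_i].to_numpy()
    vj = fm.data[model.feature_j].to_numpy()
    other = (
        model.class_levels[1]
        if model.orientation == model.class_levels[0]
        else model.class_levels[0]
    )
    predicted = np.where(vi <= vj, model.orientation, other)
    return pd.Series(predicted, index=fm.data.index, name="predicted")
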