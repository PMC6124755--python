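"""Synthetic two-class cohorts with the structure of a chronic-stress phenotype panel.

The generator emulates a murine chronic psychosocial stress study in which
~28 physiological and immunological parameters are recorded per animal:
organ weights (adrenals, thymus, spleen, pituitary) in mg plus their
body-weight-relative counterparts in mg/g, body weight on day 1 / day 20 and
the derived weight gain, plasma corticosterone, mesenteric lymph-node cell
counts, and splenocyte viability read-outs across a corticosterone dose
ladder. Stressed animals carry a planted adrenal-hypertrophy signal (higher
adrenal weight), thymus involution (lower absolute and relative thymus
weight), mild splenomegaly, and inflated within-class dispersion relative to
controls. Body weight and its gain are deliberately uninformative.

Primary measurements are drawn from truncated-at-zero Gaussians; correlated
families (left/right adrenal, the viability dose ladders) share a latent
factor; relative organ weights, total adrenal weight, day-20 body weight and
weight gain are computed exactly from the generated primaries, so the
absolute/relative correlation structure of a real panel arises by
construction rather than by covariance tuning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CohortConfigError
from .io import TRAIN, VALIDATION, FeatureMatrix, write_feature_table

#: class level names, control first (lexicographic order is load-bearing:
#: every two-level operation sorts levels, so NoStress is always level 1)
NO_STRESS = "NoStress"
STRESS = "Stress"

# canonical feature names (unit suffixes are part of the name)
LEFT_ADRENAL = "left adrenal weight [mg]"
RIGHT_ADRENAL = "right adrenal weight [mg]"
TOTAL_ADRENAL = "total adrenal weight [mg]"
REL_LEFT_ADRENAL = "relative left adrenal weight [mg/g]"
REL_RIGHT_ADRENAL = "relative right adrenal weight [mg/g]"
REL_TOTAL_ADRENAL = "relative total adrenal weight [mg/g]"
PITUITARY = "pituitary weight [mg]"
REL_PITUITARY = "relative pituitary weight [mg/g]"
CORT = "plasma corticosterone [ng/ml]"
SPLEEN = "spleen weight [mg]"
REL_SPLEEN = "relative spleen weight [mg/g]"
MLN_CELLS = "mesenteric lymph node cells [10^6 cells]"
BW_DAY1 = "body weight day 1 [g]"
BW_DAY20 = "body weight day 20 [g]"
BW_GAIN = "body weight gain [g]"
THYMUS = "thymus weight [mg]"
REL_THYMUS = "relative thymus weight [mg/g]"

_VIABILITY_BASAL = [
    f"splenocyte viability basal {d} uM CORT [OD]"
    for d in ("0", "0.005", "0.05", "0.1", "0.5", "5")
]
_VIABILITY_LPS = [
    f"splenocyte viability LPS {d} uM CORT [OD]"
    for d in ("0", "0.005", "0.05", "0.1", "0.5")
]

# (name, control mean, control SD, strictly positive?) for every primary
# (i.e. directly drawn) measurement. Baselines are typical values for adult
# male C57BL/6 mice; SDs give realistic coefficients of variation.
_PRIMARY_SPECS: list[tuple[str, float, float, bool]] = [
    (LEFT_ADRENAL, 1.80, 0.30, True),
    (RIGHT_ADRENAL, 1.45, 0.28, True),
    (PITUITARY, 2.90, 0.30, True),
    (CORT, 30.0, 12.0, True),
    (SPLEEN, 110.0, 14.0, True),
    (MLN_CELLS, 18.0, 5.0, True),
    (BW_DAY1, 20.5, 0.9, True),
    (BW_GAIN, 5.5, 1.1, False),
    (THYMUS, 62.0, 8.0, True),
    *[
        (name, mean, sd, True)
        for name, mean, sd in zip(
            _VIABILITY_BASAL, (0.52, 0.50, 0.47, 0.44, 0.36, 0.28),
            (0.080, 0.078, 0.074, 0.070, 0.062, 0.050),
        )
    ],
    *[
        (name, mean, sd, True)
        for name, mean, sd in zip(
            _VIABILITY_LPS, (1.25, 1.20, 1.10, 0.95, 0.70),
            (0.15, 0.15, 0.14, 0.13, 0.11),
        )
    ],
]
_PRIMARY_NAMES = [s[0] for s in _PRIMARY_SPECS]

#: panel order of the full 28-parameter feature set
DEFAULT_FEATURES: list[str] = [
    LEFT_ADRENAL,
    RIGHT_ADRENAL,
    TOTAL_ADRENAL,
    REL_LEFT_ADRENAL,
    REL_RIGHT_ADRENAL,
    REL_TOTAL_ADRENAL,
    PITUITARY,
    REL_PITUITARY,
    CORT,
    SPLEEN,
    REL_SPLEEN,
    MLN_CELLS,
    *_VIABILITY_BASAL,
    *_VIABILITY_LPS,
    BW_DAY1,
    BW_DAY20,
    BW_GAIN,
    THYMUS,
    REL_THYMUS,
]

#: stressed-class mean shifts in control-SD units (sign encodes direction):
#: adrenal hypertrophy up, thymus involution down, mild splenomegaly up.
#: The right adrenal responds more weakly than the left (laterality of the
#: trophic response), which is what makes the left the better discriminator.
DEFAULT_INFORMATIVE: dict[str, float] = {
    LEFT_ADRENAL: +2.0,
    RIGHT_ADRENAL: +0.8,
    THYMUS: -1.5,
    SPLEEN: +0.8,
}

#: (feature names, latent-factor loading) blocks sharing one factor each
DEFAULT_BLOCKS: list[tuple[tuple[str, ...], float]] = [
    ((LEFT_ADRENAL, RIGHT_ADRENAL), 0.6),
    (tuple(_VIABILITY_BASAL), 0.7),
    (tuple(_VIABILITY_LPS), 0.7),
]

# organ-weight-like columns that must come out strictly positive
_POSITIVE_DERIVED = [
    TOTAL_ADRENAL,
    REL_LEFT_ADRENAL,
    REL_RIGHT_ADRENAL,
    REL_TOTAL_ADRENAL,
    REL_PITUITARY,
    REL_SPLEEN,
    BW_DAY20,
    REL_THYMUS,
]


@dataclass
class CohortConfig:
    """Configuration of a synthetic two-class cohort.

    ``n_per_class`` animals per class are generated; within each class the
    last ``n_validation_per_class`` are tagged ``validation`` and the rest
    ``train``. The default sizes reproduce a 57-animal training set and a
    37-animal blinded validation set split 19 control / 18 stressed.

    ``informative_spec`` maps primary feature names to the stressed-class
    mean shift in control-SD units (positive = higher under stress).
    ``noise_sd_ratio`` inflates every stressed-class SD, modelling the higher
    heterogeneity of stressed animals. ``correlation_blocks`` lists groups of
    primary features sharing one latent factor with the given loading.
    """

    n_per_class: int = 47
    n_features: int = 28
    informative_spec: dict[str, float] | None = None
    noise_sd_ratio: float = 1.5
    correlation_blocks: list[tuple[tuple[str, ...], float]] | None = None
    n_validation_per_class: tuple[int, int] | None = None
    seed: int = 0

    def resolved_informative(self) -> dict[str, float]:
        if self.informative_spec is not None:
            return dict(self.informative_spec)
        return dict(DEFAULT_INFORMATIVE) if self.n_features == 28 else {}

    def resolved_blocks(self) -> list[tuple[tuple[str, ...], float]]:
        if self.correlation_blocks is not None:
            return [(tuple(b), lam) for b, lam in self.correlation_blocks]
        return list(DEFAULT_BLOCKS) if self.n_features == 28 else []

    def resolved_validation_counts(self) -> tuple[int, int]:
        if self.n_validation_per_class is not None:
            return self.n_validation_per_class
        if self.n_per_class == 47:
            return (19, 18)  # the 57/37 design with a 19+18 blinded set
        n_val = int(math.floor(0.4 * self.n_per_class))
        return (n_val, n_val)

    def validate(self) -> None:
        if self.n_per_class < 2:
            raise CohortConfigError(f"n_per_class must be >= 2, got {self.n_per_class}")
        if self.n_features < 2:
            raise CohortConfigError(f"n_features must be >= 2, got {self.n_features}")
        if self.noise_sd_ratio < 1:
            raise CohortConfigError(
                f"noise_sd_ratio must be >= 1, got {self.noise_sd_ratio}"
            )
        names = set(_feature_names(self.n_features))
        primaries = set(_primary_specs(self.n_features)[0])
        for feat in self.resolved_informative():
            if feat not in names:
                raise CohortConfigError(f"unknown feature in informative_spec: {feat!r}")
            if feat not in primaries:
                raise CohortConfigError(
                    f"informative_spec may only shift primary features, not the "
                    f"derived column {feat!r}"
                )
        for block, loading in self.resolved_blocks():
            unknown = [f for f in block if f not in primaries]
            if unknown:
                raise CohortConfigError(f"unknown feature(s) in correlation block: {unknown}")
            if not 0.0 <= loading <= 1.0:
                raise CohortConfigError(f"block loading must be in [0, 1], got {loading}")
        n_val = self.resolved_validation_counts()
        for count in n_val:
            if count < 0 or self.n_per_class - count < 2:
                raise CohortConfigError(
                    f"validation counts {n_val} leave fewer than 2 training "
                    f"samples per class out of n_per_class={self.n_per_class}"
                )


@dataclass
class LabeledCohort:
    """A generated cohort: numeric matrix plus class labels and split tags."""

    data: pd.DataFrame
    labels: pd.Series
    split: pd.Series
    config: CohortConfig = field(repr=False)

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    def to_feature_matrix(self) -> FeatureMatrix:
        return FeatureMatrix(self.data.copy(), labels=self.labels, split=self.split)

    def write(self, path: str | Path, delimiter: str = "\t") -> Path:
        return write_feature_table(self.to_feature_matrix(), path, delimiter=delimiter)


def _feature_names(n_features: int) -> list[str]:
    if n_features == 28:
        return list(DEFAULT_FEATURES)
    return [f"param{i + 1:02d} [au]" for i in range(n_features)]


def _primary_specs(n_features: int) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Names, means, SDs and positivity flags of the primary features."""
    if n_features == 28:
        names = _PRIMARY_NAMES
        means = np.array([s[1] for s in _PRIMARY_SPECS])
        sds = np.array([s[2] for s in _PRIMARY_SPECS])
        positive = np.array([s[3] for s in _PRIMARY_SPECS])
    else:
        names = _feature_names(n_features)
        means = np.full(n_features, 10.0)
        sds = np.full(n_features, 2.0)
        positive = np.full(n_features, True)
    return list(names), means, sds, positive


def _draw_class(
    rng: np.random.Generator,
    n: int,
    names: list[str],
    means: np.ndarray,
    sds: np.ndarray,
    positive: np.ndarray,
    shifts: np.ndarray,
    sd_ratio: float,
    blocks: list[tuple[tuple[str, ...], float]],
) -> np.ndarray:
    eps = rng.standard_normal((n, len(names)))
    for block, lam in blocks:
        factor = rng.standard_normal(n)
        idx = [names.index(f) for f in block]
        eps[:, idx] = math.sqrt(1.0 - lam * lam) * eps[:, idx] + lam * factor[:, None]
    values = means + shifts * sds + sd_ratio * sds * eps
    # truncate-at-zero by redrawing offending entries (vanishingly rare at
    # the default baselines; redraws lose the latent-factor term, acceptable
    # for the tail events this guards against)
    lower = np.where(positive, 0.0, -np.inf)
    for _ in range(100):
        bad = values <= lower
        if not bad.any():
            break
        values[bad] = (means + shifts * sds + sd_ratio * sds * rng.standard_normal(
            (n, len(names))
        ))[bad]
    else:
        values = np.maximum(values, np.where(positive, 1e-9, -np.inf))
    return values


def generate_cohort(config: CohortConfig) -> LabeledCohort:
    """Generate a deterministic two-class cohort from ``config``.

    Control animals are drawn first, then stressed animals with the
    configured mean shifts and SD inflation; derived columns (relative organ
    weights = absolute / day-20 body weight, total adrenal = left + right,
    weight gain = day 20 - day 1) are then computed exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names, means, sds, positive = _primary_specs(config.n_features)
    informative = config.resolved_informative()
    blocks = config.resolved_blocks()

    per_class: dict[str, np.ndarray] = {}
    for level, is_stress in ((NO_STRESS, False), (STRESS, True)):
        shifts = np.zeros(len(names))
        sd_ratio = 1.0
        if is_stress:
            for feat, shift in informative.items():
                shifts[names.index(feat)] = shift
            sd_ratio = config.noise_sd_ratio
        per_class[level] = _draw_class(
            rng, config.n_per_class, names, means, sds, positive, shifts,
            sd_ratio, blocks,
        )

    frames = []
    n_val = dict(zip((NO_STRESS, STRESS), config.resolved_validation_counts()))
    for level in (NO_STRESS, STRESS):
        primary = pd.DataFrame(per_class[level], columns=names)
        if config.n_features == 28:
            table = _assemble_panel(primary)
        else:
            table = primary
        table.index = [f"{level}_{i + 1:03d}" for i in range(config.n_per_class)]
        table["label"] = level
        n_train = config.n_per_class - n_val[level]
        table["split"] = [TRAIN] * n_train + [VALIDATION] * n_val[level]
        frames.append(table)

    full = pd.concat(frames)
    labels = full.pop("label")
    split = full.pop("split")
    return LabeledCohort(data=full, labels=labels, split=split, config=config)


def _assemble_panel(primary: pd.DataFrame) -> pd.DataFrame:
    """Compute the derived columns and order the full 28-parameter panel."""
    out = primary.copy()
    out[BW_DAY20] = out[BW_DAY1] + out[BW_GAIN]
    # re-derive the gain so gain == day20 - day1 holds bit-exactly
    out[BW_GAIN] = out[BW_DAY20] - out[BW_DAY1]
    out[TOTAL_ADRENAL] = out[LEFT_ADRENAL] + out[RIGHT_ADRENAL]
    bw = out[BW_DAY20]
    out[REL_LEFT_ADRENAL] = out[LEFT_ADRENAL] / bw
    out[REL_RIGHT_ADRENAL] = out[RIGHT_ADRENAL] / bw
    out[REL_TOTAL_ADRENAL] = out[TOTAL_ADRENAL] / bw
    out[REL_PITUITARY] = out[PITUITARY] / bw
    out[REL_SPLEEN] = out[SPLEEN] / bw
    out[REL_THYMUS] = out[THYMUS] / bw
    if (out[_POSITIVE_DERIVED].to_numpy() <= 0).any():
        # day-20 weight is day-1 plus gain; a negative total would need a
        # gain below -20 g, far outside the generated range
        raise CohortConfigError("derived organ-weight column is non-positive")
    return out[DEFAULT_FEATURES]
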