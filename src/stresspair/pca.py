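"""Principal component analysis of the standardized phenotype panel.

The decomposition is computed on centered, unit-variance parameters (i.e. on
the correlation structure), via singular value decomposition of the
standardized matrix for numerical stability. Component signs follow a fixed
convention — the largest-magnitude loading of each component is positive —
so that repeated runs and figure exports are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import FeatureMatrix


@dataclass
class PCAResult:
    """Loadings, scores and the explained-variance decomposition.

    ``loadings`` is features x components with orthonormal columns;
    ``scores`` is samples x components; ``sdev`` holds the component
    standard deviations (square roots of the correlation-matrix
    eigenvalues), matching the conventional variance-table export.
    """

    loadings: np.ndarray
    scores: np.ndarray
    sdev: np.ndarray
    explained_variance_ratio: np.ndarray
    cumulative_ratio: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def variance_table(self) -> pd.DataFrame:
        """Standard deviation, proportion and cumulative proportion per PC."""
        return pd.DataFrame(
            {
                "standard_deviation": self.sdev,
                "proportion_of_variance": self.explained_variance_ratio,
                "cumulative_proportion": self.cumulative_ratio,
            },
            index=[f"PC{i + 1}" for i in range(self.n_components)],
        )

    def loadings_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings,
            index=self.feature_names,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )

    def scores_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=self.sample_ids,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )


def fit_pca(fm: FeatureMatrix) -> PCAResult:
    """Fit a PCA on centered and scaled parameters.

    Requires at least two samples and two features, no missing values and a
    nonzero variance in every feature (a zero-variance feature is reported
    by name). Returns ``min(n_samples - 1, n_features)`` components ordered
    by decreasing variance.
    """
    X = fm.values
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValidationError(f"PCA needs >= 2 samples and >= 2 features, got {n}x{p}")
    if np.isnan(X).any():
        raise ValidationError("PCA input contains missing values")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(
            f"zero-variance feature: {fm.feature_names[zero[0]]!r}"
        )
    Z = (X - X.mean(axis=0)) / sd

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(n - 1, p)
    loadings = Vt[:k].T
    scores = U[:, :k] * s[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(k)] < 0
    loadings[:, flip] *= -1
    scores[:, flip] *= -1

    var = s**2
    ratio = var[:k] / var.sum()
    return PCAResult(
        loadings=loadings,
        scores=scores,
        sdev=s[:k] / np.sqrt(n - 1),
        explained_variance_ratio=ratio,
        cumulative_ratio=np.cumsum(ratio),
        feature_names=fm.feature_names,
        sample_ids=fm.sample_ids,
    )


def export_biplot_data(res: PCAResult, top_k: int | None = None) -> pd.DataFrame:
    """Per-feature loading vectors on PC1-PC3 for a biplot-style export.

    Each row gives the PC1/PC2 arrow coordinates, the raw PC3 loading, and a
    PC3 magnitude bin on a 1-5 scale (equal-width bins of |loading| from 0 to
    the maximum; an all-constant PC3 column lands in a single bin). With
    ``top_k`` set, only the ``top_k`` features with the longest PC1/PC2
    arrows are kept, in decreasing arrow length.
    """
    if res.n_components < 3:
        raise ValidationError(
            f"biplot export needs >= 3 components, got {res.n_components}"
        )
    pc3_abs = np.abs(res.loadings[:, 2])
    top = pc3_abs.max()
    if top == 0:
        bins = np.ones(len(pc3_abs), dtype=int)
    else:
        bins = np.minimum(5, 1 + np.floor(pc3_abs / top * 5).astype(int))
    table = pd.DataFrame(
        {
            "PC1": res.loadings[:, 0],
            "PC2": res.loadings[:, 1],
            "PC3": res.loadings[:, 2],
            "pc3_size_bin": bins,
        },
        index=res.feature_names,
    )
    if top_k is not None:
        arrow = np.hypot(table["PC1"], table["PC2"])
        table = table.loc[arrow.sort_values(ascending=False).index[:top_k]]
    return table
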