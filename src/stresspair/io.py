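"""Reading, writing and in-memory representation of sample x parameter tables.

The canonical on-disk format is a delimited text table (TSV by default) with a
sample-identifier first column, one numeric column per measured parameter
(column names may carry unit suffixes such as ``[mg]`` or ``[mg/g]`` and are
matched verbatim), and optional ``label`` / ``split`` metadata columns holding
the two-level stress status and the train/validation membership. A thin
adapter ingests ``.xlsx``/``.xlsm`` spreadsheets through the same path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import TableParseError, ValidationError

logger = logging.getLogger(__name__)

_SPREADSHEET_SUFFIXES = {".xlsx", ".xlsm"}

#: canonical split tags
TRAIN = "train"
VALIDATION = "validation"


@dataclass
class FeatureMatrix:
    """Rectangular numeric table of samples x named parameters.

    Parameters
    ----------
    data:
        ``pandas.DataFrame`` indexed by unique sample ids with unique,
        numerically-typed feature columns.
    labels:
        Optional per-sample class label; when present it must take exactly two
        distinct levels (the binary stressed / non-stressed contrast).
    split:
        Optional per-sample partition tag, e.g. ``"train"`` / ``"validation"``.
    """

    data: pd.DataFrame
    labels: pd.Series | None = None
    split: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate feature name: {dup!r}")
        try:
            self.data = self.data.astype(np.float64)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"feature columns must be numeric: {exc}") from exc
        for name, attr in (("labels", self.labels), ("split", self.split)):
            if attr is None:
                continue
            series = pd.Series(attr)
            if len(series) != self.n_samples:
                raise ValidationError(
                    f"{name} has {len(series)} entries for {self.n_samples} samples"
                )
            series.index = self.data.index
            setattr(self, name, series.astype(str))
        if self.labels is not None:
            levels = sorted(self.labels.unique())
            if len(levels) != 2:
                raise ValidationError(
                    f"labels must take exactly two levels, got {levels}"
                )

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def class_levels(self) -> tuple[str, str]:
        if self.labels is None:
            raise ValidationError("feature matrix carries no labels")
        levels = sorted(self.labels.unique())
        return levels[0], levels[1]

    # -- subsetting ----------------------------------------------------------
    def select_features(self, names: list[str] | tuple[str, ...]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown feature(s): {missing}")
        return FeatureMatrix(
            self.data.loc[:, list(names)].copy(),
            labels=None if self.labels is None else self.labels.copy(),
            split=None if self.split is None else self.split.copy(),
        )

    def subset_split(self, tag: str) -> "FeatureMatrix":
        return subset_split(self, tag)


def subset_split(fm: FeatureMatrix, tag: str) -> FeatureMatrix:
    """Return the rows whose split annotation equals ``tag``, order preserved."""
    if fm.split is None:
        raise ValidationError("feature matrix carries no split annotation")
    present = set(fm.split.unique())
    if tag not in present:
        raise ValidationError(f"unknown split tag {tag!r}; present: {sorted(present)}")
    mask = (fm.split == tag).to_numpy()
    return FeatureMatrix(
        fm.data.loc[mask].copy(),
        labels=None if fm.labels is None else fm.labels.loc[mask].copy(),
        split=fm.split.loc[mask].copy(),
    )


def read_feature_table(
    path: str | Path,
    label_column: str | None = "label",
    split_column: str | None = "split",
    delimiter: str = "\t",
    drop_incomplete: bool = True,
) -> FeatureMatrix:
    """Read a delimited (or .xlsx) sample x parameter table.

    The first column is taken as the sample identifier. All non-metadata
    columns are coerced to numbers; a non-numeric cell raises
    :class:`TableParseError` naming the offending sample and column. Rows with
    missing values in feature columns are logged and excluded by default.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if path.suffix.lower() in _SPREADSHEET_SUFFIXES:
        raw = pd.read_excel(path, index_col=0)
    else:
        raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id: {dup!r}")

    labels = split = None
    for colname, required_as in ((label_column, "label"), (split_column, "split")):
        if colname is None:
            continue
        if colname not in raw.columns:
            raise ValidationError(
                f"{required_as} column {colname!r} not found in {path.name}"
            )
    if label_column is not None:
        labels = raw.pop(label_column).astype(str)
    if split_column is not None:
        split = raw.pop(split_column).astype(str)

    numeric = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            sample = bad.idxmax()
            raise TableParseError(
                f"non-numeric value {raw.loc[sample, col]!r} in column {col!r}, "
                f"sample {sample!r}"
            )
        numeric[col] = coerced

    incomplete = numeric.isna().any(axis=1)
    if incomplete.any():
        ids = list(numeric.index[incomplete])
        logger.warning(
            "%d sample(s) with missing values excluded from analysis: %s",
            len(ids),
            ids,
        )
        if drop_incomplete:
            numeric = numeric.loc[~incomplete]
            if labels is not None:
                labels = labels.loc[~incomplete]
            if split is not None:
                split = split.loc[~incomplete]

    return FeatureMatrix(numeric, labels=labels, split=split)


def write_feature_table(
    fm: FeatureMatrix, path: str | Path, delimiter: str = "\t"
) -> Path:
    """Write a feature matrix (plus label/split columns) as delimited text.

    Floats are rendered with 12 significant digits so that write-then-read is
    the identity to that precision.
    """
    path = Path(path)
    out = fm.data.copy()
    if fm.labels is not None:
        out["label"] = fm.labels
    if fm.split is not None:
        out["split"] = fm.split
    out.index.name = "sample_id"
    out.to_csv(path, sep=delimiter, float_format="%.12g")
    return path
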