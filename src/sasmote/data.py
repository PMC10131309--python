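"""Validated labeled dataset shared by every resampling stage.

A :class:`LabeledDataset` is a numeric feature matrix plus a binary label
vector in which the *minority* class (the strictly less frequent one) has
been resolved.  Rows are never reordered: every index stored downstream —
neighbor lists, synthetic-point provenance — refers to the original row
position of this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    AmbiguousMinorityError,
    DataFormatError,
    DegenerateLabelsError,
    MissingDataError,
)

__all__ = ["LabeledDataset", "validate_dataset", "class_counts"]


@dataclass(frozen=True)
class LabeledDataset:
    """Immutable numeric feature matrix with resolved binary labels.

    Parameters
    ----------
    features
        Float matrix of shape ``(n_samples, n_features)``; all finite.
    labels
        Per-row class tag, length ``n_samples``.  Exactly two distinct
        values when used for resampling.
    feature_names
        Column identifiers, one per feature column.
    label_name
        Identifier of the label column (used when round-tripping CSV).
    minority_label, majority_label
        The two class tags; ``minority_label`` is the strictly less
        frequent one unless the caller designated it explicitly.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]
    label_name: str
    minority_label: object
    majority_label: object
    origin: np.ndarray = field(default=None, repr=False)  # "original"/"synthetic"

    def __post_init__(self):
        if self.features.ndim != 2:
            raise DataFormatError("features must be a 2-D matrix")
        if len(self.labels) != self.features.shape[0]:
            raise DataFormatError("labels length does not match feature rows")
        if len(self.feature_names) != self.features.shape[1]:
            raise DataFormatError("feature_names length does not match columns")
        if self.origin is None:
            object.__setattr__(
                self, "origin", np.full(self.n_samples, "original", dtype=object)
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def minority_mask(self) -> np.ndarray:
        return self.labels == self.minority_label

    @property
    def minority_indices(self) -> np.ndarray:
        """Row positions of minority samples, in original order."""
        return np.flatnonzero(self.minority_mask)

    @property
    def majority_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.minority_mask)

    @property
    def minority_features(self) -> np.ndarray:
        return self.features[self.minority_mask]

    # -- conversion -----------------------------------------------------
    def to_frame(self, include_origin: bool = False) -> pd.DataFrame:
        """Render as a DataFrame with the original header layout.

        With ``include_origin=True`` an extra ``origin`` column tags each
        row ``original`` or ``synthetic``.
        """
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df[self.label_name] = self.labels
        if include_origin:
            df["origin"] = self.origin
        return df

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        """Row subset (e.g. a CV fold) keeping the resolved class tags."""
        rows = np.asarray(rows)
        return replace(
            self,
            features=self.features[rows],
            labels=self.labels[rows],
            origin=self.origin[rows],
        )

    def equals(self, other: "LabeledDataset") -> bool:
        return (
            np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
            and self.feature_names == other.feature_names
            and self.label_name == other.label_name
            and self.minority_label == other.minority_label
            and self.majority_label == other.majority_label
        )


def validate_dataset(
    raw_table,
    label_name: str,
    minority_label=None,
) -> LabeledDataset:
    """Validate a raw table into a :class:`LabeledDataset`.

    Parameters
    ----------
    raw_table
        A :class:`pandas.DataFrame` (or an already validated
        :class:`LabeledDataset`, returned unchanged — validation is
        idempotent) with one label column and numeric feature columns.
    label_name
        Name of the label column.
    minority_label
        Explicit minority class tag.  Required only when the two classes
        are exactly tied; otherwise the strictly less frequent tag wins.

    Raises
    ------
    DataFormatError
        Non-numeric feature cell, or too few rows/columns.
    MissingDataError
        Any NaN/inf feature value (named by row and column).
    DegenerateLabelsError
        Fewer than two distinct labels.
    AmbiguousMinorityError
        Exact class tie without an explicit designation.
    """
    if isinstance(raw_table, LabeledDataset):
        return raw_table
    df = pd.DataFrame(raw_table)
    if label_name not in df.columns:
        raise DataFormatError(f"label column {label_name!r} not found")
    if df.shape[0] < 2:
        raise DataFormatError("need at least 2 rows")
    feature_cols = [c for c in df.columns if c != label_name]
    if not feature_cols:
        raise DataFormatError("need at least one feature column")

    feat_df = df[feature_cols]
    try:
        features = feat_df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError):
        bad = [c for c in feature_cols if not np.issubdtype(feat_df[c].dtype, np.number)]
        raise DataFormatError(f"non-numeric feature column(s): {bad or feature_cols}")
    if not np.isfinite(features).all():
        r, c = np.argwhere(~np.isfinite(features))[0]
        raise MissingDataError(
            f"missing/non-finite value at row {df.index[r]}, column {feature_cols[c]!r}"
        )

    labels = df[label_name].to_numpy()
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise DegenerateLabelsError(
            f"label column holds a single class ({values.tolist()}); two required"
        )
    if len(values) > 2:
        raise DegenerateLabelsError(
            f"label column holds {len(values)} classes; binary labels required"
        )

    if minority_label is not None:
        if minority_label not in values:
            raise DegenerateLabelsError(
                f"designated minority label {minority_label!r} absent from data"
            )
        maj = values[values != minority_label][0]
        minority, majority = minority_label, maj
    elif counts[0] == counts[1]:
        raise AmbiguousMinorityError(
            "classes are exactly tied; pass minority_label explicitly"
        )
    else:
        order = np.argsort(counts)
        minority, majority = values[order[0]], values[order[1]]

    return LabeledDataset(
        features=features,
        labels=labels,
        feature_names=tuple(feature_cols),
        label_name=label_name,
        minority_label=minority,
        majority_label=majority,
    )


def class_counts(ds: LabeledDataset) -> tuple[int, int]:
    """Return ``(minority_count, majority_count)``; they sum to n_samples."""
    m = int(ds.minority_mask.sum())
    return m, ds.n_samples - m
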