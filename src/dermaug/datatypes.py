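"""Core containers passed between pipeline stages.

Two objects travel through the whole workflow: :class:`LesionSample` (an RGB
dermoscopy-style image plus its binary lesion mask and class label) and
:class:`FeatureTable` (a named feature matrix with a binary label column and a
real/synthetic provenance flag).  Both are thin, validated wrappers over numpy
arrays / pandas DataFrames so that every stage can rely on the same contracts:
labels are 0 (not-melanoma) / 1 (melanoma), masks are boolean, and synthetic
rows are flagged explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: provenance flag values for FeatureTable rows
SOURCE_REAL = "real"
SOURCE_SYNTHETIC = "synthetic"

#: reserved (non-feature) column names in CSV interchange files
RESERVED_COLUMNS = ("sample_id", "label", "source")


@dataclass
class LesionSample:
    """An RGB lesion image, its binary mask, class label and provenance.

    Attributes
    ----------
    image : uint8 array, shape (H, W, 3)
    mask : bool array, shape (H, W)
        True on lesion pixels; the ground-truth region for synthetic samples.
    label : int
        0 = not-melanoma, 1 = melanoma.
    sample_id : str
    provenance : dict
        Generator/stage metadata (seed, spec fields, processing history).
    hair_mask : bool array or None
        For synthetic samples, the exact pixels touched by hair strokes.
    """

    image: np.ndarray
    mask: np.ndarray
    label: int
    sample_id: str = "sample"
    provenance: dict = field(default_factory=dict)
    hair_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValidationError("image: expected an (H, W, 3) RGB array")
        msk = np.asarray(self.mask, dtype=bool)
        if msk.shape != img.shape[:2]:
            raise ValidationError("mask: shape must match image height/width")
        if not msk.any():
            raise ValidationError("mask: must contain at least one lesion pixel")
        if self.label not in (0, 1):
            raise ValidationError("label: must be 0 (not-melanoma) or 1 (melanoma)")
        self.image = img
        self.mask = msk


class FeatureTable:
    """A named feature matrix with binary labels and a source flag.

    This is the object every downstream stage consumes: feature selection,
    augmentation, quality metrics, evaluation and interpretability all operate
    on a ``FeatureTable``.  Internally a single :class:`pandas.DataFrame`
    indexed by ``sample_id`` with a ``label`` column (0/1), a ``source`` column
    (``"real"`` / ``"synthetic"``) and one column per feature.
    """

    def __init__(self, features: pd.DataFrame, labels, source=None, sample_ids=None):
        X = pd.DataFrame(features).copy()
        for col in RESERVED_COLUMNS:
            if col in X.columns:
                raise ValidationError(f"features: reserved column name {col!r}")
        y = pd.Series(np.asarray(labels), index=X.index, name="label")
        bad = set(pd.unique(y)) - {0, 1}
        if bad:
            raise ValidationError(f"label: non-binary values {sorted(bad)!r}")
        if len(y) != len(X):
            raise ValidationError("label: length must match feature rows")
        if source is None:
            source = [SOURCE_REAL] * len(X)
        src = pd.Series(list(source), index=X.index, name="source")
        bad_src = set(src.unique()) - {SOURCE_REAL, SOURCE_SYNTHETIC}
        if bad_src:
            raise ValidationError(f"source: invalid values {sorted(bad_src)!r}")
        if sample_ids is not None:
            ids = pd.Index([str(s) for s in sample_ids], name="sample_id")
            if len(ids) != len(X):
                raise ValidationError("sample_id: length must match feature rows")
        else:
            ids = pd.Index([f"s{i:05d}" for i in range(len(X))], name="sample_id")
        if ids.has_duplicates:
            dupes = ids[ids.duplicated()].unique().tolist()
            raise ValidationError(f"sample_id: duplicate ids {dupes[:5]!r}")
        X.index = ids
        y.index = ids
        src.index = ids
        self._X = X
        self._y = y.astype(int)
        self._source = src

    # -- accessors ---------------------------------------------------------
    @property
    def features(self) -> pd.DataFrame:
        """Feature matrix (copy-safe view), indexed by sample_id."""
        return self._X

    @property
    def labels(self) -> pd.Series:
        return self._y

    @property
    def source(self) -> pd.Series:
        return self._source

    @property
    def feature_names(self) -> list[str]:
        return list(self._X.columns)

    @property
    def sample_ids(self) -> pd.Index:
        return self._X.index

    def __len__(self) -> int:
        return len(self._X)

    # -- convenience -------------------------------------------------------
    @property
    def n_minority(self) -> int:
        counts = self._y.value_counts()
        return int(counts.min()) if len(counts) == 2 else 0

    @property
    def minority_label(self) -> int:
        counts = self._y.value_counts()
        return int(counts.idxmin())

    def class_counts(self) -> tuple[int, int]:
        """(n_majority, n_minority) row counts."""
        counts = self._y.value_counts()
        return int(counts.max()), int(counts.min())

    def imbalance_ratio(self) -> float:
        """Majority/minority count ratio (the dataset-overview convention)."""
        n_maj, n_min = self.class_counts()
        if n_min == 0:
            raise ValidationError("label: both classes must be present")
        return n_maj / n_min

    def subset(self, row_indexer) -> "FeatureTable":
        """Row subset by boolean mask or positional indices; keeps metadata."""
        arr = np.asarray(row_indexer)
        if arr.dtype == bool:
            X = self._X.loc[arr]
        else:
            X = self._X.iloc[arr]
        return FeatureTable(
            X.reset_index(drop=True),
            self._y.loc[X.index].to_numpy(),
            self._source.loc[X.index].to_numpy(),
            sample_ids=X.index,
        )

    def select_features(self, names) -> "FeatureTable":
        missing = [n for n in names if n not in self._X.columns]
        if missing:
            raise ValidationError(f"features: unknown names {missing[:5]!r}")
        return FeatureTable(
            self._X[list(names)].reset_index(drop=True),
            self._y.to_numpy(),
            self._source.to_numpy(),
            sample_ids=self._X.index,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame with sample_id, label, source then feature columns."""
        out = self._X.copy()
        out.insert(0, "source", self._source)
        out.insert(0, "label", self._y)
        return out.reset_index()

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self._X.equals(other._X)
            and self._y.equals(other._y)
            and self._source.equals(other._source)
        )
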