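"""Radiomic feature catalog, feature-table / label I/O and validation.

The catalog enumerates the 120 radiomic features (PyRadiomics-style names)
grouped into eight classes: first-order intensity statistics, 3D shape,
2D shape, and five texture families (GLCM, GLRLM, GLSZM, NGTDM, GLDM).
Feature tables are wide CSV/TSV files, one row per segmented lesion;
labels are per-lesion binary indicators for up to three classification
tasks ("pathologic", "pathologic_with_ECS", "non_pathologic").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureClass",
    "FeatureCatalogEntry",
    "FeatureTable",
    "LabelSet",
    "TASK_NAMES",
    "feature_catalog",
    "load_feature_table",
    "write_feature_table",
    "load_labels",
    "write_labels",
    "ValidationError",
    "ParseError",
    "ConsistencyError",
    "AlignmentError",
    "DegenerateLabelError",
]

TASK_NAMES = ("pathologic", "pathologic_with_ECS", "non_pathologic")


class ValidationError(ValueError):
    """A table violates the catalog contract (e.g. missing column)."""


class ParseError(ValueError):
    """A cell could not be parsed as a real number."""


class ConsistencyError(ValueError):
    """Label columns contradict each other (ECS=1 without pathologic=1)."""


class AlignmentError(ValueError):
    """Label sample ids do not match the feature table."""


class DegenerateLabelError(ValueError):
    """A task has only one class present."""


class FeatureClass(str, enum.Enum):
    first_order = "first_order"
    shape_3d = "shape_3d"
    shape_2d = "shape_2d"
    glcm = "glcm"
    glrlm = "glrlm"
    glszm = "glszm"
    ngtdm = "ngtdm"
    gldm = "gldm"


# Per-class feature names. Class cardinalities (19, 16, 10, 24, 16, 16, 5, 14)
# sum to 120; multiplied by the 252 segmented lymph nodes they reproduce the
# per-class extraction totals (4788, 4032, 2520, 6048, 4032, 4032, 1260, 3528)
# and a grand total of 30,240 extracted feature values.
_CLASS_FEATURES: dict[FeatureClass, tuple[str, str]] = {
    FeatureClass.first_order: (
        "original_firstorder_",
        (
            "10Percentile 90Percentile Energy Entropy InterquartileRange "
            "Kurtosis Maximum Mean MeanAbsoluteDeviation Median Minimum Range "
            "RobustMeanAbsoluteDeviation RootMeanSquared Skewness "
            "StandardDeviation TotalEnergy Uniformity Variance"
        ),
    ),
    FeatureClass.shape_3d: (
        "original_shape_",
        (
            "Compactness1 Compactness2 Elongation Flatness LeastAxisLength "
            "MajorAxisLength Maximum2DDiameterColumn Maximum2DDiameterRow "
            "Maximum2DDiameterSlice Maximum3DDiameter MeshVolume "
            "MinorAxisLength Sphericity SurfaceArea SurfaceVolumeRatio "
            "VoxelVolume"
        ),
    ),
    FeatureClass.shape_2d: (
        "original_shape2D_",
        (
            "Elongation MajorAxisLength MaximumDiameter MeshSurface "
            "MinorAxisLength Perimeter PerimeterSurfaceRatio PixelSurface "
            "SphericalDisproportion Sphericity"
        ),
    ),
    FeatureClass.glcm: (
        "original_glcm_",
        (
            "Autocorrelation ClusterProminence ClusterShade ClusterTendency "
            "Contrast Correlation DifferenceAverage DifferenceEntropy "
            "DifferenceVariance Id Idm Idmn Idn Imc1 Imc2 InverseVariance "
            "JointAverage JointEnergy JointEntropy MCC MaximumProbability "
            "SumAverage SumEntropy SumSquares"
        ),
    ),
    FeatureClass.glrlm: (
        "original_glrlm_",
        (
            "GrayLevelNonUniformity GrayLevelNonUniformityNormalized "
            "GrayLevelVariance HighGrayLevelRunEmphasis LongRunEmphasis "
            "LongRunHighGrayLevelEmphasis LongRunLowGrayLevelEmphasis "
            "LowGrayLevelRunEmphasis RunEntropy RunLengthNonUniformity "
            "RunLengthNonUniformityNormalized RunPercentage RunVariance "
            "ShortRunEmphasis ShortRunHighGrayLevelEmphasis "
            "ShortRunLowGrayLevelEmphasis"
        ),
    ),
    FeatureClass.glszm: (
        "original_glszm_",
        (
            "GrayLevelNonUniformity GrayLevelNonUniformityNormalized "
            "GrayLevelVariance HighGrayLevelZoneEmphasis LargeAreaEmphasis "
            "LargeAreaHighGrayLevelEmphasis LargeAreaLowGrayLevelEmphasis "
            "LowGrayLevelZoneEmphasis SizeZoneNonUniformity "
            "SizeZoneNonUniformityNormalized SmallAreaEmphasis "
            "SmallAreaHighGrayLevelEmphasis SmallAreaLowGrayLevelEmphasis "
            "ZoneEntropy ZonePercentage ZoneVariance"
        ),
    ),
    FeatureClass.ngtdm: (
        "original_ngtdm_",
        "Busyness Coarseness Complexity Contrast Strength",
    ),
    FeatureClass.gldm: (
        "original_gldm_",
        (
            "DependenceEntropy DependenceNonUniformity "
            "DependenceNonUniformityNormalized DependenceVariance "
            "GrayLevelNonUniformity GrayLevelVariance HighGrayLevelEmphasis "
            "LargeDependenceEmphasis LargeDependenceHighGrayLevelEmphasis "
            "LargeDependenceLowGrayLevelEmphasis LowGrayLevelEmphasis "
            "SmallDependenceEmphasis SmallDependenceHighGrayLevelEmphasis "
            "SmallDependenceLowGrayLevelEmphasis"
        ),
    ),
}

EXPECTED_CLASS_CARDINALITIES: dict[FeatureClass, int] = {
    FeatureClass.first_order: 19,
    FeatureClass.shape_3d: 16,
    FeatureClass.shape_2d: 10,
    FeatureClass.glcm: 24,
    FeatureClass.glrlm: 16,
    FeatureClass.glszm: 16,
    FeatureClass.ngtdm: 5,
    FeatureClass.gldm: 14,
}


@dataclass(frozen=True)
class FeatureCatalogEntry:
    name: str
    feature_class: FeatureClass
    index: int


def feature_catalog() -> list[FeatureCatalogEntry]:
    """Return the canonical 120-feature catalog.

    Classes appear in the fixed enum order; features are alphabetical
    within each class, so indices are fully deterministic.
    """
    entries: list[FeatureCatalogEntry] = []
    for fclass in FeatureClass:
        prefix, names = _CLASS_FEATURES[fclass]
        for name in sorted(names.split()):
            entries.append(
                FeatureCatalogEntry(prefix + name, fclass, len(entries))
            )
    assert len(entries) == 120
    return entries


def catalog_class_of(name: str, catalog: list[FeatureCatalogEntry]) -> FeatureClass:
    for entry in catalog:
        if entry.name == name:
            return entry.feature_class
    raise KeyError(name)


@dataclass
class FeatureTable:
    """Wide feature matrix: n samples x d named real-valued features."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # (n, d) float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n != len(self.sample_ids):
            raise ValidationError("row count does not match sample_ids")
        if d != len(self.feature_names):
            raise ValidationError("column count does not match feature_names")
        if len(set(self.feature_names)) != d:
            raise ValidationError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at row {bad[0]}, column "
                f"{self.feature_names[bad[1]]}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, names: list[str]) -> "FeatureTable":
        """Column subset in the given order; unknown names raise KeyError."""
        pos = {f: j for j, f in enumerate(self.feature_names)}
        idx = [pos[f] for f in names]
        return FeatureTable(self.sample_ids, list(names), self.values[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_names,
        )


@dataclass
class LabelSet:
    """Per-sample binary labels for the classification tasks.

    Every sample labeled pathologic_with_ECS=1 must also be pathologic=1:
    extracapsular spread is a refinement of the pathologic class.
    """

    sample_ids: list[str]
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for task, y in self.labels.items():
            y = np.asarray(y, dtype=int)
            self.labels[task] = y
            if task not in TASK_NAMES:
                raise ValidationError(f"unknown task {task!r}")
            if y.shape != (n,):
                raise AlignmentError(f"label vector for {task!r} has wrong length")
            if not np.isin(y, (0, 1)).all():
                raise ValidationError(f"labels for {task!r} are not binary")
            if y.min() == y.max():
                raise DegenerateLabelError(f"task {task!r} has a single class")
        if "pathologic_with_ECS" in self.labels and "pathologic" in self.labels:
            ecs = self.labels["pathologic_with_ECS"]
            path = self.labels["pathologic"]
            if np.any((ecs == 1) & (path == 0)):
                raise ConsistencyError(
                    "sample labeled pathologic_with_ECS=1 but pathologic=0"
                )

    def task(self, name: str) -> np.ndarray:
        return self.labels[name]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-separated table (auto-detected from the header)."""
    path = Path(path)
    header = path.open("r", encoding="utf-8").readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def load_feature_table(
    path: str | Path,
    catalog: list[FeatureCatalogEntry] | None = None,
    strict: bool = False,
) -> FeatureTable:
    """Load a wide feature table from CSV/TSV.

    Columns prefixed ``diagnostics_`` (extractor metadata) are dropped. A
    ``sample_id`` column, if present, provides row ids; otherwise rows are
    numbered. In strict mode the retained columns must be exactly the
    catalog names and are re-ordered into canonical catalog order.
    """
    df = _read_delimited(path)
    if "sample_id" in df.columns:
        sample_ids = df["sample_id"].astype(str).tolist()
        df = df.drop(columns=["sample_id"])
    else:
        sample_ids = [str(i) for i in range(len(df))]
    drop = [c for c in df.columns if c.startswith("diagnostics_")]
    df = df.drop(columns=drop)

    if strict:
        if catalog is None:
            catalog = feature_catalog()
        names = [e.name for e in catalog]
        missing = [c for c in names if c not in df.columns]
        if missing:
            raise ValidationError(f"missing catalog column: {missing[0]}")
        extra = [c for c in df.columns if c not in set(names)]
        if extra:
            raise ValidationError(f"unexpected non-catalog column: {extra[0]}")
        df = df[names]

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col]
        if raw.isna().any():
            i = int(np.flatnonzero(raw.isna().to_numpy())[0])
            raise ValidationError(f"missing value at row {i}, column {col!r}")
        try:
            # numpy's parser is correctly rounded, unlike pd.to_numeric
            values[:, j] = raw.to_numpy(dtype=str).astype(float)
        except ValueError:
            ok = pd.to_numeric(raw, errors="coerce").notna()
            i = int(np.flatnonzero(~ok.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {raw.iloc[i]!r} at row {i}, "
                f"column {col!r}"
            ) from None
    return FeatureTable(sample_ids, list(df.columns), values)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write CSV that round-trips bit-identically through load_feature_table."""
    # repr-precision floats round-trip exactly through the text format
    df = table.to_dataframe().map(lambda v: repr(float(v)))
    df.to_csv(path)


def load_labels(path: str | Path, table: FeatureTable) -> LabelSet:
    """Load the per-task 0/1 label file and align it to *table* by sample id."""
    df = _read_delimited(path)
    if "sample_id" not in df.columns:
        raise AlignmentError("label file has no sample_id column")
    ids = df["sample_id"].astype(str).tolist()
    unknown = set(ids) - set(table.sample_ids)
    if unknown:
        raise AlignmentError(f"unknown sample id(s): {sorted(unknown)[:3]}")
    if set(table.sample_ids) - set(ids):
        raise AlignmentError("label file does not cover all table samples")
    order = pd.Index(ids).get_indexer(table.sample_ids)
    labels: dict[str, np.ndarray] = {}
    for task in TASK_NAMES:
        if task in df.columns:
            col = pd.to_numeric(df[task], errors="coerce")
            if col.isna().any():
                raise ParseError(f"non-numeric label in task {task!r}")
            labels[task] = col.to_numpy(dtype=int)[order]
    if not labels:
        raise ValidationError("no recognised task columns in label file")
    return LabelSet(list(table.sample_ids), labels)


def write_labels(labels: LabelSet, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": labels.sample_ids})
    for task, y in labels.labels.items():
        df[task] = y
    df.to_csv(path, index=False)
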