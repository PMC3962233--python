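"""Data model and delimited-text I/O for formulary matrices.

The core artifacts are binary incidence tables: a formula-by-plant usage
matrix, per-formula efficacy labels, a plant-by-activity annotation matrix,
and the three-way usage tensor obtained by crossing usage with activities.
All entries are validated to be in {0, 1} before any modelling happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, IdError, LabelError

logger = logging.getLogger(__name__)

__all__ = [
    "PlantUsageMatrix",
    "EfficacyLabels",
    "DummyResponse",
    "ActivityMatrix",
    "UsageTensor",
    "to_dummy",
    "build_tensor",
    "matricize",
    "fold",
    "unfolded_column_ids",
    "read_usage_table",
    "write_usage_table",
    "read_activity_table",
    "write_activity_table",
    "read_labels_table",
    "write_labels_table",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise IdError(f"duplicate {what} id: {x!r}")
        seen.add(x)


def _check_binary(M: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
    """Return an int8 copy of ``M``; raise FormatError naming the offending cell."""
    arr = np.asarray(M)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D table, got {arr.ndim}-D")
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"non-binary cell at row {row_ids[i]!r}, column {col_ids[j]!r}: {arr[i, j]!r}"
        )
    return arr.astype(np.int8)


@dataclass(frozen=True)
class PlantUsageMatrix:
    """Binary I x J incidence of plant usage across formulas.

    ``X[i, j] == 1`` iff formula ``i`` uses plant ``j``.
    """

    formula_ids: tuple[str, ...]
    plant_ids: tuple[str, ...]
    X: np.ndarray

    def __init__(self, formula_ids: Sequence[str], plant_ids: Sequence[str], X) -> None:
        object.__setattr__(self, "formula_ids", tuple(str(f) for f in formula_ids))
        object.__setattr__(self, "plant_ids", tuple(str(p) for p in plant_ids))
        _check_unique(self.formula_ids, "formula")
        _check_unique(self.plant_ids, "plant")
        arr = _check_binary(X, self.formula_ids, self.plant_ids)
        if arr.shape != (len(self.formula_ids), len(self.plant_ids)):
            raise FormatError(
                f"usage matrix shape {arr.shape} does not match "
                f"{len(self.formula_ids)} formulas x {len(self.plant_ids)} plants"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise FormatError("usage matrix must have at least one row and column")
        unused = np.flatnonzero(arr.sum(axis=0) == 0)
        if unused.size:
            logger.warning(
                "%d plant(s) with all-zero usage retained: %s",
                unused.size,
                ", ".join(self.plant_ids[j] for j in unused[:10]),
            )
        arr.setflags(write=False)
        object.__setattr__(self, "X", arr)

    @property
    def n_formulas(self) -> int:
        return len(self.formula_ids)

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=list(self.formula_ids), columns=list(self.plant_ids))


@dataclass(frozen=True)
class EfficacyLabels:
    """Per-formula efficacy class codes, ordered like the paired usage matrix."""

    formula_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __init__(self, formula_ids: Sequence[str], labels: Sequence[str]) -> None:
        object.__setattr__(self, "formula_ids", tuple(str(f) for f in formula_ids))
        object.__setattr__(self, "labels", tuple(str(l) for l in labels))
        _check_unique(self.formula_ids, "formula")
        if len(self.formula_ids) != len(self.labels):
            raise FormatError(
                f"{len(self.formula_ids)} formula ids but {len(self.labels)} labels"
            )

    def validate_against(self, class_names: Sequence[str]) -> None:
        allowed = set(class_names)
        for fid, lab in zip(self.formula_ids, self.labels):
            if lab not in allowed:
                raise LabelError(f"unknown efficacy label {lab!r} for formula {fid!r}")

    def class_counts(self, class_names: Sequence[str]) -> np.ndarray:
        self.validate_against(class_names)
        index = {c: l for l, c in enumerate(class_names)}
        counts = np.zeros(len(class_names), dtype=int)
        for lab in self.labels:
            counts[index[lab]] += 1
        return counts


@dataclass(frozen=True)
class DummyResponse:
    """I x L indicator matrix of efficacy membership; each row sums to one."""

    Y: np.ndarray
    class_names: tuple[str, ...]

    def __init__(self, Y, class_names: Sequence[str]) -> None:
        object.__setattr__(self, "class_names", tuple(str(c) for c in class_names))
        _check_unique(self.class_names, "class")
        arr = _check_binary(
            Y, [str(i) for i in range(np.asarray(Y).shape[0])], self.class_names
        )
        if arr.shape[1] != len(self.class_names):
            raise FormatError(
                f"dummy matrix has {arr.shape[1]} columns for {len(self.class_names)} classes"
            )
        rs = arr.sum(axis=1)
        if not np.all(rs == 1):
            i = int(np.flatnonzero(rs != 1)[0])
            raise FormatError(f"dummy row {i} sums to {rs[i]}, expected exactly 1")
        arr.setflags(write=False)
        object.__setattr__(self, "Y", arr)

    def to_labels(self) -> tuple[str, ...]:
        idx = np.argmax(self.Y, axis=1)
        return tuple(self.class_names[i] for i in idx)


@dataclass(frozen=True)
class ActivityMatrix:
    """Binary J x K plant-by-pharmacological-activity annotation."""

    plant_ids: tuple[str, ...]
    activity_ids: tuple[str, ...]
    A: np.ndarray

    def __init__(self, plant_ids: Sequence[str], activity_ids: Sequence[str], A) -> None:
        object.__setattr__(self, "plant_ids", tuple(str(p) for p in plant_ids))
        object.__setattr__(self, "activity_ids", tuple(str(a) for a in activity_ids))
        _check_unique(self.plant_ids, "plant")
        _check_unique(self.activity_ids, "activity")
        arr = _check_binary(A, self.plant_ids, self.activity_ids)
        if arr.shape != (len(self.plant_ids), len(self.activity_ids)):
            raise FormatError(
                f"activity matrix shape {arr.shape} does not match "
                f"{len(self.plant_ids)} plants x {len(self.activity_ids)} activities"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "A", arr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=list(self.plant_ids), columns=list(self.activity_ids))


@dataclass(frozen=True)
class UsageTensor:
    """Binary I x J x K tensor: plant j with activity k used in formula i."""

    X3: np.ndarray
    formula_ids: tuple[str, ...]
    plant_ids: tuple[str, ...]
    activity_ids: tuple[str, ...]

    def __init__(self, X3, formula_ids, plant_ids, activity_ids) -> None:
        object.__setattr__(self, "formula_ids", tuple(str(f) for f in formula_ids))
        object.__setattr__(self, "plant_ids", tuple(str(p) for p in plant_ids))
        object.__setattr__(self, "activity_ids", tuple(str(a) for a in activity_ids))
        arr = np.asarray(X3)
        if arr.ndim != 3:
            raise FormatError(f"expected a 3-D array, got {arr.ndim}-D")
        expected = (len(self.formula_ids), len(self.plant_ids), len(self.activity_ids))
        if arr.shape != expected:
            raise FormatError(f"tensor shape {arr.shape} does not match ids {expected}")
        if not np.isin(arr, (0, 1)).all():
            i, j, k = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise FormatError(
                f"non-binary tensor entry at ({self.formula_ids[i]!r}, "
                f"{self.plant_ids[j]!r}, {self.activity_ids[k]!r})"
            )
        arr = arr.astype(np.int8)
        arr.setflags(write=False)
        object.__setattr__(self, "X3", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.X3.shape


def to_dummy(labels: EfficacyLabels, class_names: Sequence[str]) -> DummyResponse:
    """Indicator-code labels against an ordered class set: Y[i, l] = 1 iff label_i == class l."""
    labels.validate_against(class_names)
    index = {c: l for l, c in enumerate(class_names)}
    Y = np.zeros((len(labels.labels), len(class_names)), dtype=np.int8)
    for i, lab in enumerate(labels.labels):
        Y[i, index[lab]] = 1
    return DummyResponse(Y, class_names)


def build_tensor(usage: PlantUsageMatrix, activities: ActivityMatrix) -> UsageTensor:
    """Cross usage with activity annotations: X3[i, j, k] = X[i, j] * A[j, k]."""
    if usage.plant_ids != activities.plant_ids:
        raise AlignmentError(
            "plant ids of usage and activity matrices differ "
            f"({len(usage.plant_ids)} vs {len(activities.plant_ids)} ids)"
        )
    X3 = usage.X[:, :, None] * activities.A[None, :, :]
    return UsageTensor(X3, usage.formula_ids, usage.plant_ids, activities.activity_ids)


def matricize(t: UsageTensor | np.ndarray) -> np.ndarray:
    """Unfold an I x J x K array into I x JK with activity-major blocks of J columns.

    Column index of entry (j, k) is ``k*J + j`` (0-based), i.e. the K frontal
    I x J slabs are concatenated left to right.
    """
    X3 = t.X3 if isinstance(t, UsageTensor) else np.asarray(t)
    I, J, K = X3.shape
    return X3.transpose(0, 2, 1).reshape(I, J * K)


def fold(M: np.ndarray, J: int, K: int) -> np.ndarray:
    """Inverse of :func:`matricize`: reshape I x JK back into I x J x K."""
    M = np.asarray(M)
    I = M.shape[0]
    if M.shape[1] != J * K:
        raise FormatError(f"cannot fold {M.shape[1]} columns into J={J} x K={K}")
    return M.reshape(I, K, J).transpose(0, 2, 1)


def unfolded_column_ids(plant_ids: Sequence[str], activity_ids: Sequence[str]) -> list[str]:
    """Identifiers for the JK unfolded columns, in matricize order."""
    return [f"{p}|{a}" for a in activity_ids for p in plant_ids]


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Tables carry a header of variable ids and a first
# column of observation ids; the usage table may embed the label column.
# ---------------------------------------------------------------------------

def _read_frame(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return df


def read_usage_table(
    path,
    sep: str = "\t",
    label_col: str | None = "efficacy",
    class_names: Sequence[str] | None = None,
) -> tuple[PlantUsageMatrix, EfficacyLabels | None]:
    """Read a formula x plant table, optionally with an embedded label column.

    Returns the validated usage matrix and, when ``label_col`` is present in
    the file, the paired efficacy labels (validated against ``class_names``
    when given).
    """
    df = _read_frame(path, sep)
    labels = None
    if label_col is not None and label_col in df.columns:
        labels = EfficacyLabels(df.index.tolist(), df[label_col].tolist())
        if class_names is not None:
            labels.validate_against(class_names)
        df = df.drop(columns=[label_col])
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in usage table {path}: {exc}") from exc
    usage = PlantUsageMatrix(df.index.tolist(), df.columns.tolist(), values)
    return usage, labels


def write_usage_table(
    path, usage: PlantUsageMatrix, labels: EfficacyLabels | None = None,
    sep: str = "\t", label_col: str = "efficacy",
) -> None:
    df = usage.to_frame()
    if labels is not None:
        if labels.formula_ids != usage.formula_ids:
            raise AlignmentError("labels and usage matrix have different formula ids")
        df[label_col] = list(labels.labels)
    df.to_csv(path, sep=sep, index_label="formula_id")


def read_activity_table(path, sep: str = "\t") -> ActivityMatrix:
    df = _read_frame(path, sep)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in activity table {path}: {exc}") from exc
    return ActivityMatrix(df.index.tolist(), df.columns.tolist(), values)


def write_activity_table(path, activities: ActivityMatrix, sep: str = "\t") -> None:
    activities.to_frame().to_csv(path, sep=sep, index_label="plant_id")


def read_labels_table(path, sep: str = "\t") -> EfficacyLabels:
    """Two-column file: formula id, efficacy label."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"labels file must have exactly 2 columns, got {df.shape[1]}")
    return EfficacyLabels(df.iloc[:, 0].tolist(), df.iloc[:, 1].tolist())


def write_labels_table(path, labels: EfficacyLabels, sep: str = "\t") -> None:
    pd.DataFrame(
        {"formula_id": list(labels.formula_ids), "efficacy": list(labels.labels)}
    ).to_csv(path, sep=sep, index=False)
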