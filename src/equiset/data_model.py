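"""Dataset container, exclusion-set (embedded) views, and tabular I/O.

The central objects of the package are a numeric data matrix ``X`` with a
designated outcome ``y`` (continuous, or binary in {0, 1}) and *embedded*
views of it: the logical dataset obtained by excluding a set of features.
The multiple-solutions searches create many embedded datasets, so views are
represented as exclusion sets over one shared base matrix and never copy
data. Features are addressed by integer index into the base dataset
everywhere internally; names appear only at I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "OutcomeType",
    "Dataset",
    "EmbeddedView",
    "embed",
    "read_table",
    "write_table",
    "write_solutions_json",
    "read_solutions_json",
]

SOLUTIONS_SCHEMA = "equiset-solutions-v1"


class OutcomeType(str, Enum):
    CONTINUOUS = "continuous"
    BINARY = "binary"


class DataError(ValueError):
    """Raised when a table or dataset violates the package's invariants."""


@dataclass(frozen=True)
class Dataset:
    """Immutable container for a feature matrix and an outcome vector.

    Parameters
    ----------
    X
        Numeric matrix, shape ``(n_samples, n_features)``. No missing values.
    feature_names
        Unique identifiers, one per column of ``X``.
    y
        Outcome vector of length ``n_samples``. For a binary outcome it must
        take values in {0, 1} with both classes present.
    outcome_type
        Whether ``y`` is continuous or binary.
    """

    X: np.ndarray
    feature_names: tuple
    y: np.ndarray
    outcome_type: OutcomeType

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "outcome_type", OutcomeType(self.outcome_type))
        if X.ndim != 2:
            raise DataError("X must be 2-dimensional")
        n, p = X.shape
        if len(self.feature_names) != p:
            raise DataError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            dupes = sorted(
                {n for n in self.feature_names if self.feature_names.count(n) > 1}
            )
            raise DataError(f"duplicate feature names: {dupes}")
        if y.shape != (n,):
            raise DataError("y length does not match number of samples")
        if n < 10:
            raise DataError(f"need at least 10 samples, got {n}")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise DataError("missing or non-finite values are not supported")
        if self.outcome_type is OutcomeType.BINARY:
            values = set(np.unique(y))
            if not values <= {0.0, 1.0}:
                raise DataError("binary outcome must take values in {0, 1}")
            if len(values) < 2:
                raise DataError("binary outcome is constant (one class only)")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    # A Dataset behaves as a view over itself with an empty exclusion set,
    # so every search routine can accept either object interchangeably.
    @property
    def base(self) -> "Dataset":
        return self

    @property
    def excluded(self) -> frozenset:
        return frozenset()

    @property
    def active(self) -> tuple:
        return tuple(range(self.n_features))

    def name_of(self, index: int) -> str:
        return self.feature_names[index]

    def index_of(self, name: str) -> int:
        return self.feature_names.index(name)


@dataclass(frozen=True)
class EmbeddedView:
    """Logical dataset with some base features excluded (``D^E``).

    The view shares the base matrix; the active feature list is the base
    feature list minus ``excluded``, in base order. Views compose: embedding
    a view unions its exclusion set with the new one.
    """

    base: Dataset
    excluded: frozenset

    def __post_init__(self):
        excluded = frozenset(int(i) for i in self.excluded)
        object.__setattr__(self, "excluded", excluded)
        universe = set(range(self.base.n_features))
        if not excluded <= universe:
            raise DataError(f"excluded indices {sorted(excluded - universe)} out of range")

    @property
    def active(self) -> tuple:
        ex = self.excluded
        return tuple(i for i in range(self.base.n_features) if i not in ex)

    @property
    def n_samples(self) -> int:
        return self.base.n_samples

    @property
    def outcome_type(self) -> OutcomeType:
        return self.base.outcome_type

    @property
    def X(self) -> np.ndarray:
        return self.base.X

    @property
    def y(self) -> np.ndarray:
        return self.base.y


View = Union[Dataset, EmbeddedView]


def embed(view: View, exclude: Iterable[int]) -> EmbeddedView:
    """Exclude features from a dataset or view, returning a composed view.

    Raises
    ------
    DataError
        If an index in ``exclude`` is not active in the input view.
    """
    exclude = frozenset(int(i) for i in exclude)
    active = frozenset(view.active)
    if not exclude <= active:
        raise DataError(
            f"cannot exclude inactive features {sorted(exclude - active)}"
        )
    return EmbeddedView(base=view.base, excluded=view.excluded | exclude)


def _read_frame(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    # header row is mandatory; duplicate names must be detected before pandas
    # mangles them (it appends ".1" suffixes)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise DataError(f"duplicate column names in header: {dupes}")
    return pd.read_csv(path, sep=sep)


def read_table(path, target: str, outcome_type: OutcomeType | str) -> Dataset:
    """Read a CSV/TSV file into a :class:`Dataset`.

    ``target`` names the outcome column; all other columns become features in
    file order. Cells must be numeric; a non-numeric cell is reported with its
    row and column.
    """
    frame = _read_frame(path)
    if target not in frame.columns:
        raise DataError(f"target column {target!r} not found in {path}")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"non-numeric value {frame[col].iloc[row]!r} at row {row + 2}, "
                f"column {col!r}"
            )
        if frame[col].isna().any():
            row = int(np.flatnonzero(frame[col].isna().to_numpy())[0])
            raise DataError(f"missing value at row {row + 2}, column {col!r}")
        frame[col] = coerced
    y = frame[target].to_numpy(dtype=float)
    features = frame.drop(columns=[target])
    return Dataset(
        X=features.to_numpy(dtype=float),
        feature_names=tuple(features.columns),
        y=y,
        outcome_type=outcome_type,
    )


def write_table(dataset: Dataset, path, target: str = "T") -> None:
    """Write a dataset to CSV/TSV (dialect chosen by file extension)."""
    if target in dataset.feature_names:
        raise DataError(f"target name {target!r} collides with a feature name")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.DataFrame(dataset.X, columns=list(dataset.feature_names))
    frame[target] = dataset.y
    frame.to_csv(path, sep=sep, index=False)


def write_solutions_json(path, solutions: Sequence[Sequence[str]]) -> None:
    """Write a solution family as JSON (first entry = reference solution)."""
    payload = {
        "schema": SOLUTIONS_SCHEMA,
        "solutions": [list(s) for s in solutions],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_solutions_json(path) -> list:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != SOLUTIONS_SCHEMA:
        raise DataError(f"unrecognized solutions schema in {path}")
    return [list(s) for s in payload["solutions"]]
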