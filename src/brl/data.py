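"""Dataset containers and delimited-file I/O.

Two containers are used throughout the package:

``ContinuousDataset``
    an ``m x n`` matrix of continuous measurements (e.g. expression
    intensities) plus a categorical class column, as read from CSV/TSV.

``DiscreteDataset``
    the integer-coded form produced by applying a discretization scheme:
    per-variable codes ``0 .. r_i - 1`` with known arities, plus integer
    target codes.  All Bayesian scoring operates on this substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from brl.errors import ConfigurationError, ParseError, ValidationError


@dataclass
class ContinuousDataset:
    """Sample-by-feature matrix of continuous values with a class column.

    Parameters
    ----------
    values : (m, n) float array
        Continuous feature measurements, unitless.
    feature_names : list of str
        One name per column, in file order.
    class_labels : list
        One categorical class label per row.
    class_name : str
        Name of the class column (default ``"class"``).
    """

    values: np.ndarray
    feature_names: list[str]
    class_labels: list
    class_name: str = "class"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.class_labels = list(self.class_labels)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 2:
            raise ValidationError(f"need at least 2 instances, got {m}")
        if n < 1:
            raise ValidationError("need at least 1 feature")
        if len(self.feature_names) != n:
            raise ValidationError("feature_names length does not match matrix width")
        if len(self.class_labels) != m:
            raise ValidationError("class_labels length does not match matrix height")
        if any(pd.isna(lbl) for lbl in self.class_labels):
            raise ValidationError("missing class labels are not allowed")
        if len(set(self.class_labels)) < 2:
            raise ValidationError("class column must contain at least 2 distinct labels")
        if np.isnan(self.values).any():
            r, c = np.argwhere(np.isnan(self.values))[0]
            raise ValidationError(
                f"missing feature value at row {r}, column {self.feature_names[c]!r}; "
                "missing values are rejected, not imputed"
            )

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def class_codes(self) -> tuple[np.ndarray, list]:
        """Return (codes, ordered distinct labels); codes are 0-based by sorted label."""
        labels = sorted(set(self.class_labels), key=str)
        lut = {lbl: k for k, lbl in enumerate(labels)}
        return np.array([lut[lbl] for lbl in self.class_labels], dtype=np.intp), labels


@dataclass
class DiscreteDataset:
    """Integer-coded instances over variables of known arity plus a target.

    ``codes[s, i]`` is the interval/category code of instance ``s`` on
    variable ``i``; codes are 0-based and consecutive, ``0 <= code < arities[i]``.
    ``value_labels[i][c]`` is a human-readable label for code ``c`` of
    variable ``i`` (e.g. ``"(-inf, 3.2]"``).
    """

    codes: np.ndarray
    arities: list[int]
    value_labels: list[list[str]]
    target_codes: np.ndarray
    target_arity: int
    feature_names: list[str] = field(default_factory=list)
    class_values: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.intp)
        self.target_codes = np.asarray(self.target_codes, dtype=np.intp)
        m, n = self.codes.shape
        if len(self.arities) != n:
            raise ValidationError("arities length mismatch")
        if self.target_arity < 2:
            raise ValidationError("target must have at least 2 classes")
        if len(self.target_codes) != m:
            raise ValidationError("target_codes length mismatch")
        if not self.feature_names:
            self.feature_names = [f"v{i}" for i in range(n)]
        for i, r_i in enumerate(self.arities):
            if r_i < 1:
                raise ValidationError(f"variable {i} has arity {r_i} < 1")
            col = self.codes[:, i]
            if col.size and (col.min() < 0 or col.max() >= r_i):
                raise ValidationError(f"codes of variable {i} outside [0, {r_i})")
        if self.target_codes.size and (
            self.target_codes.min() < 0 or self.target_codes.max() >= self.target_arity
        ):
            raise ValidationError("target codes outside range")

    @property
    def m(self) -> int:
        return self.codes.shape[0]

    @property
    def n(self) -> int:
        return self.codes.shape[1]

    @property
    def r(self) -> int:
        """Maximum arity across variables."""
        return max(self.arities) if self.arities else 1

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.target_codes, minlength=self.target_arity)

    def majority_class(self) -> int:
        # np.argmax breaks ties toward the lower code, which is deterministic
        return int(np.argmax(self.class_counts()))


def read_dataset(path, class_column: str = "class", delimiter: str = ",") -> ContinuousDataset:
    """Read a delimited sample-by-feature matrix with a categorical class column.

    The file must have a header row.  All columns other than ``class_column``
    are treated as continuous features, kept in file order.

    Raises
    ------
    ConfigurationError
        if ``class_column`` is absent from the header.
    ParseError
        if a feature cell is not numeric (the message names row and column).
    ValidationError
        if fewer than two distinct class labels are present.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype=str, keep_default_na=False)
    if class_column not in df.columns:
        raise ConfigurationError(
            f"class column {class_column!r} not found; header has {list(df.columns)}"
        )
    feature_names = [c for c in df.columns if c != class_column]
    if not feature_names:
        raise ValidationError("file contains no feature columns")
    values = np.empty((len(df), len(feature_names)), dtype=float)
    for j, name in enumerate(feature_names):
        try:
            # numpy's parser is correctly rounded, so write/read round-trips
            values[:, j] = np.asarray(df[name].to_numpy(), dtype=float)
        except ValueError:
            col = pd.to_numeric(df[name], errors="coerce")
            bad = np.flatnonzero(col.isna().to_numpy())
            row = bad[0] if bad.size else 0
            raise ParseError(
                f"non-numeric value {df[name].iloc[row]!r} in column {name!r}, "
                f"row {row + 2} (1-based, counting the header)"
            ) from None
    labels = df[class_column].tolist()
    if any(lbl == "" for lbl in labels):
        raise ValidationError("empty class label encountered")
    return ContinuousDataset(values, feature_names, labels, class_name=class_column)


def write_dataset(dataset: ContinuousDataset, path, delimiter: str = ",") -> None:
    """Write a continuous dataset back to a delimited file (features then class)."""
    df = pd.DataFrame(dataset.values, columns=dataset.feature_names)
    df[dataset.class_name] = dataset.class_labels
    # %.17g keeps every float64 exactly recoverable
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
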