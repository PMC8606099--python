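"""Subject-level dataset container and delimited-text reader.

A :class:`Dataset` holds one row per subject: outcome ``y``, exposure ``x``,
mediator ``m`` and an optional covariate matrix ``w``.  Column types for the
outcome and mediator are declared by the caller (``"continuous"`` or
``"binary"``), never inferred; binary columns must be coded 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset", "read_table"]

_TYPES = ("continuous", "binary")


def _as_1d(a, name):
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Dataset:
    """Typed subject-level data for a mediation analysis.

    Parameters
    ----------
    y, x, m : array-like, shape (n,)
        Outcome, exposure and mediator values.
    w : array-like, shape (n, p), optional
        Covariates shared by the two models (each model may use a subset).
    y_type, m_type : {"continuous", "binary"}
        Declared types of the outcome and mediator columns.
    w_names : sequence of str, optional
        Covariate column names; defaults to ``w0, w1, ...``.
    """

    y: np.ndarray
    x: np.ndarray
    m: np.ndarray
    w: np.ndarray = None
    y_type: str = "continuous"
    m_type: str = "continuous"
    w_names: tuple = field(default=None)

    def __post_init__(self):
        self.y = _as_1d(self.y, "y")
        self.x = _as_1d(self.x, "x")
        self.m = _as_1d(self.m, "m")
        n = self.y.size
        if self.x.size != n or self.m.size != n:
            raise ValueError("y, x and m must have equal length")
        if self.w is None:
            self.w = np.empty((n, 0))
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim == 1:
            self.w = self.w[:, None]
        if self.w.shape[0] != n:
            raise ValueError("w must have one row per subject")
        if self.w_names is None:
            self.w_names = tuple(f"w{j}" for j in range(self.w.shape[1]))
        else:
            self.w_names = tuple(self.w_names)
            if len(self.w_names) != self.w.shape[1]:
                raise ValueError("w_names length must match number of covariates")
        for t, name in ((self.y_type, "y_type"), (self.m_type, "m_type")):
            if t not in _TYPES:
                raise ValueError(f"{name} must be one of {_TYPES}, got {t!r}")
        for arr, name in ((self.y, "y"), (self.x, "x"), (self.m, "m"), (self.w, "w")):
            if not np.isfinite(arr).all():
                raise ValueError(
                    f"column {name} contains missing or nonfinite values; "
                    "resolve missingness before fitting"
                )
        if self.y_type == "binary":
            _check_binary(self.y, "y")
        if self.m_type == "binary":
            _check_binary(self.m, "m")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_covariates(self) -> int:
        return self.w.shape[1]

    @property
    def case(self) -> int:
        """Data-type case id: 1=cont/cont, 2=cont/bin, 3=bin/cont, 4=bin/bin
        (outcome type first)."""
        return {
            ("continuous", "continuous"): 1,
            ("continuous", "binary"): 2,
            ("binary", "continuous"): 3,
            ("binary", "binary"): 4,
        }[(self.y_type, self.m_type)]

    def covariate_columns(self, names):
        """Return the (n, k) submatrix of ``w`` for the given column names."""
        if names is None:
            return self.w, self.w_names
        idx = []
        for name in names:
            if name not in self.w_names:
                raise KeyError(f"unknown covariate {name!r}")
            idx.append(self.w_names.index(name))
        return self.w[:, idx], tuple(names)

    def take(self, indices) -> "Dataset":
        """Row subset/resample (used by the pairs bootstrap)."""
        indices = np.asarray(indices)
        return Dataset(
            y=self.y[indices],
            x=self.x[indices],
            m=self.m[indices],
            w=self.w[indices],
            y_type=self.y_type,
            m_type=self.m_type,
            w_names=self.w_names,
        )


def _check_binary(arr, name):
    bad = ~np.isin(arr, (0.0, 1.0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"column {name!r} is declared binary but contains value "
            f"{arr[row]!r} at row {row}; binary columns must be coded 0/1"
        )


def _check_binary_named(arr, column, path):
    bad = ~np.isin(arr, (0.0, 1.0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: column {column!r} is declared binary but contains "
            f"{arr[row]!r} at row {row}"
        )


def read_table(
    path,
    outcome: str,
    mediator: str,
    exposure: str,
    binary_outcome: bool = False,
    binary_mediator: bool = False,
    covariates=(),
    sep: str = ",",
) -> Dataset:
    """Read a delimited text table (header row required) into a Dataset.

    ``covariates`` is the union of covariate names used by either model;
    model-specific subsets are selected at fit time.
    """
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    covariates = list(covariates or ())
    needed = [outcome, mediator, exposure, *covariates]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: columns not found: {missing}")
    sub = df[needed]
    non_numeric = [
        c for c in needed if not np.issubdtype(pd.to_numeric(sub[c], errors="coerce").dtype, np.number)
    ]
    coerced = sub.apply(pd.to_numeric, errors="coerce")
    bad_cells = coerced.isna() & ~sub.isna()
    if bad_cells.any().any():
        col = bad_cells.any().idxmax()
        row = int(bad_cells[col].idxmax())
        raise ValueError(f"{path}: non-numeric value in column {col!r} at row {row}")
    if coerced.isna().any().any():
        col = coerced.isna().any().idxmax()
        raise ValueError(
            f"{path}: missing values in column {col!r}; resolve missingness "
            "before analysis"
        )
    del non_numeric
    if binary_outcome:
        _check_binary_named(coerced[outcome].to_numpy(), outcome, path)
    if binary_mediator:
        _check_binary_named(coerced[mediator].to_numpy(), mediator, path)
    return Dataset(
        y=coerced[outcome].to_numpy(),
        x=coerced[exposure].to_numpy(),
        m=coerced[mediator].to_numpy(),
        w=coerced[covariates].to_numpy() if covariates else None,
        y_type="binary" if binary_outcome else "continuous",
        m_type="binary" if binary_mediator else "continuous",
        w_names=tuple(covariates),
    )
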