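"""Shared design-matrix construction for the covariate-adjusted tests.

Categorical metadata columns are dummy-coded (first level dropped);
numeric columns enter as-is. The variable of interest always enters after
the covariates so sequential (Type I) decompositions attribute shared
variance to the covariates first.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def _encode(metadata: pd.DataFrame, column: str) -> np.ndarray:
    """Encode one metadata column as design columns (n, k) float array."""
    s = metadata[column]
    if pd.api.types.is_numeric_dtype(s):
        if s.isna().any():
            raise ValueError(f"column {column!r} has missing values after alignment")
        return s.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(s.astype(str), drop_first=True, dtype=float)
    if dummies.shape[1] == 0:
        raise ValueError(f"variable {column!r} is constant")
    return dummies.to_numpy()


def build_design(
    metadata: pd.DataFrame,
    variable: str,
    covariates: Sequence[str] = (),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (X_reduced, X_full, n_variable_columns).

    X_reduced holds intercept + covariates; X_full appends the variable of
    interest's columns. Raises on missing columns, constant variable, or a
    singular (collinear) full design, naming the offending columns.
    """
    for col in [variable, *covariates]:
        if col not in metadata.columns:
            raise KeyError(f"metadata has no column {col!r}")
    n = len(metadata)
    blocks = [np.ones((n, 1))]
    for cov in covariates:
        blocks.append(_encode(metadata, cov))
    x_red = np.hstack(blocks)
    var_block = _encode(metadata, variable)
    x_full = np.hstack([x_red, var_block])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError(
            f"singular design: {variable!r} with covariates {list(covariates)} "
            "are collinear"
        )
    return x_red, x_full, var_block.shape[1]


def hat_matrix(x: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of x."""
    q, _ = np.linalg.qr(x)
    return q @ q.T
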