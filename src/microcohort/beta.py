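"""Beta diversity: Bray-Curtis and UniFrac distances, PCoA, PERMANOVA.

Distances are computed on rarefied tables (rarefaction happens upstream).
PERMANOVA is the adonis-style covariate-adjusted variant: sequential
(Type I) sums of squares from the Gower-centered squared-distance matrix,
covariates entered before the variable of interest, significance by
permuting the variable's rows with the covariate structure fixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import skbio
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.stats.distance import DistanceMatrix

from microcohort._design import build_design, hat_matrix
from microcohort.io import CountTable

logger = logging.getLogger("microcohort")


def _check_nonzero(table: CountTable) -> None:
    zero = table.depths[table.depths == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {zero.index.tolist()}")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y), in [0,1]."""
    _check_nonzero(table)
    return _skbio_beta("braycurtis", table.matrix, ids=table.samples)


def unifrac(
    table: CountTable,
    tree: skbio.TreeNode,
    variant: Literal["unweighted", "weighted_normalized"] = "unweighted",
) -> DistanceMatrix:
    """UniFrac distance between samples on a shared phylogeny.

    ``unweighted`` compares branch presence/absence; ``weighted_normalized``
    weights branches by the difference in subtree relative abundance,
    normalized to [0,1]. Every table taxon must be a tree leaf.
    """
    _check_nonzero(table)
    leaves = {t.name for t in tree.tips()}
    missing = [t for t in table.taxa if t not in leaves]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing[:10]}")
    metric = "unweighted_unifrac" if variant == "unweighted" else "weighted_unifrac"
    kwargs = {"tree": tree, "taxa": table.taxa}
    if variant == "weighted_normalized":
        kwargs["normalized"] = True
    elif variant != "unweighted":
        raise ValueError(f"unknown UniFrac variant {variant!r}")
    return _skbio_beta(metric, table.matrix, ids=table.samples, **kwargs)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    """Classical-scaling embedding of a distance matrix.

    ``coordinates`` holds samples x axes (positive eigenvalues only, scaled
    by sqrt eigenvalue); all eigenvalues, including negative ones, are
    reported in ``eigenvalues``; ``proportion_explained`` divides each
    positive eigenvalue by the sum of positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix, n_axes: Optional[int] = None) -> PcoaResult:
    """Principal coordinates via eigendecomposition of -1/2 J D^2 J.

    Negative eigenvalues (non-Euclidean distances) are reported but never
    used for coordinates; axis signs are fixed by making each axis's
    largest-magnitude coordinate positive.
    """
    d = dm.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-10 if n else 0.0
    pos = vals > tol
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        logger.warning("pcoa: requested %d axes but only %d positive eigenvalues; clipping",
                       n_axes, n_pos)
        n_axes = n_pos
    coords = vecs[:, :n_axes] * np.sqrt(vals[:n_axes])
    for k in range(n_axes):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] *= -1
    pos_sum = vals[pos].sum() if n_pos else 1.0
    prop = np.where(vals > tol, vals / pos_sum, 0.0)
    frame = pd.DataFrame(coords, index=list(dm.ids),
                         columns=[f"PC{k + 1}" for k in range(n_axes)])
    return PcoaResult(coordinates=frame, eigenvalues=vals, proportion_explained=prop)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r2: float
    p: float
    n_permutations: int
    df: tuple[int, int]
    complete_enumeration: bool = False


def _gower(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    a = -0.5 * d**2
    return j @ a @ j


def _n_distinct_arrangements(column: np.ndarray) -> float:
    """Distinct row arrangements of the variable block (multiset permutations)."""
    _, counts = np.unique(column, axis=0, return_counts=True)
    total = math.factorial(len(column))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    variable: str,
    covariates: Sequence[str] = (),
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> PermanovaResult:
    """Covariate-adjusted PERMANOVA with sequential (Type I) SS.

    pseudo-F = (SS_variable/df_variable)/(SS_residual/df_residual) where
    SS terms are traces of projected Gower matrices, covariates entered
    first. p = (1 + #{F_perm >= F_obs}) / (1 + B) from permutations of the
    variable's rows; when the variable admits fewer distinct arrangements
    than B, all of them are enumerated and p = #{F >= F_obs}/#arrangements
    (the observed arrangement counts itself).
    """
    metadata = metadata.loc[list(dm.ids)]
    x_red, x_full, _ = build_design(metadata, variable, covariates)
    n = len(metadata)
    g = _gower(dm.data)
    trace_g = float(np.trace(g))
    var_block = x_full[:, x_red.shape[1]:]

    rank_red = np.linalg.matrix_rank(x_red)
    rank_full = np.linalg.matrix_rank(x_full)
    df_var = int(rank_full - rank_red)
    df_res = int(n - rank_full)
    if df_var < 1 or df_res < 1:
        raise ValueError("degenerate design for PERMANOVA")

    h_red = hat_matrix(x_red)
    ss_red = float(np.sum(h_red * g.T))  # tr(H G)

    tol = 1e-12 * max(abs(trace_g), 1.0)

    def f_for(block: np.ndarray) -> float:
        h_full = hat_matrix(np.hstack([x_red, block]))
        ss_full = float(np.sum(h_full * g.T))
        ss_var = ss_full - ss_red
        ss_res = trace_g - ss_full
        if ss_res <= tol:  # model exhausts the distance SS
            return np.inf if ss_var > tol else 0.0
        return (ss_var / df_var) / (ss_res / df_res)

    f_obs = float(f_for(var_block))
    h_full = hat_matrix(x_full)
    ss_full = float(np.sum(h_full * g.T))
    r2 = (ss_full - ss_red) / trace_g

    distinct = _n_distinct_arrangements(var_block)
    if distinct <= n_permutations:
        logger.info("permanova: only %d distinct arrangements; complete enumeration", distinct)
        from sympy.utilities.iterables import multiset_permutations

        rows = [tuple(r) for r in var_block]
        count = 0
        total = 0
        for perm in multiset_permutations(rows):
            block = np.array(perm, dtype=float)
            if f_for(block) >= f_obs - 1e-12:
                count += 1
            total += 1
        return PermanovaResult(pseudo_F=f_obs, r2=float(r2), p=count / total,
                               n_permutations=total, df=(df_var, df_res),
                               complete_enumeration=True)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        idx = rng.permutation(n)
        if f_for(var_block[idx]) >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(pseudo_F=f_obs, r2=float(r2), p=p,
                           n_permutations=n_permutations, df=(df_var, df_res))
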