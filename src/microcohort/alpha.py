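"""Alpha diversity: rarefaction, the three metrics, and adjusted tests.

Metrics follow the standard plug-in definitions on the rarefied counts:
observed richness (# nonzero taxa), Shannon index -sum p ln p (nats by
default) and Inverse Simpson 1/sum p^2. Associations with study variables
use ordinary least squares with covariates and a partial F test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from microcohort._design import build_design
from microcohort.io import CountTable

logger = logging.getLogger("microcohort")

METRICS = ("observed_asvs", "shannon", "inv_simpson")


def rarefy(table: CountTable, depth: Optional[int] = None, seed: Optional[int] = None,
           ) -> CountTable:
    """Subsample every sample to a common depth, without replacement.

    ``depth=None`` uses the minimum sample depth. Samples below the depth
    are dropped with a logged list; it is an error if no sample reaches it.
    """
    totals = table.depths
    if depth is None:
        depth = int(totals.min())
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    keep = totals[totals >= depth].index.tolist()
    if not keep:
        raise ValueError(f"rarefaction depth {depth} exceeds every sample's total")
    dropped = [s for s in table.samples if s not in set(keep)]
    if dropped:
        logger.warning("rarefy: dropped %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    mat = table.to_dataframe().loc[keep].to_numpy()
    out = np.empty_like(mat)
    for i, row in enumerate(mat):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountTable(pd.DataFrame(out, index=keep, columns=table.taxa))


def _props(row) -> np.ndarray:
    x = np.asarray(row, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot compute diversity of an empty sample")
    if (x < 0).any():
        raise ValueError("negative counts")
    return x / total


def observed_asvs(row) -> int:
    """Species richness: number of taxa with a nonzero count."""
    x = np.asarray(row, dtype=float)
    if x.sum() <= 0:
        raise ValueError("cannot compute diversity of an empty sample")
    return int(np.count_nonzero(x))


def shannon(row, base: float = np.e) -> float:
    """Shannon index -sum p ln p, with 0 ln 0 := 0. Nats by default."""
    p = _props(row)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


def inv_simpson(row) -> float:
    """Inverse Simpson index 1/sum p^2 (effective number of taxa)."""
    p = _props(row)
    return float(1.0 / (p**2).sum())


def alpha_table(table: CountTable, base: float = np.e) -> pd.DataFrame:
    """All three metrics per sample."""
    mat = table.matrix
    rows = {
        "observed_asvs": [observed_asvs(r) for r in mat],
        "shannon": [shannon(r, base=base) for r in mat],
        "inv_simpson": [inv_simpson(r) for r in mat],
    }
    return pd.DataFrame(rows, index=table.samples)


@dataclass(frozen=True)
class AlphaAssociation:
    coefficient: float
    F: float
    p: float
    df: tuple[int, int]


def alpha_association(
    values: pd.Series,
    metadata: pd.DataFrame,
    variable: str,
    covariates: Sequence[str] = (),
) -> AlphaAssociation:
    """OLS of an alpha metric on the variable of interest plus covariates.

    Returns the variable's coefficient (first of its design columns), the
    partial F statistic for its block and the two-sided parametric p.
    """
    values = pd.Series(values).astype(float)
    metadata = metadata.loc[values.index]
    x_red, x_full, q = build_design(metadata, variable, covariates)
    n, p_full = x_full.shape
    if n <= p_full + 1:
        raise ValueError(f"n={n} too small for {p_full} parameters")
    y = values.to_numpy()
    beta_full, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    resid_full = y - x_full @ beta_full
    beta_red, *_ = np.linalg.lstsq(x_red, y, rcond=None)
    resid_red = y - x_red @ beta_red
    rss_full = float(resid_full @ resid_full)
    rss_red = float(resid_red @ resid_red)
    df_res = n - p_full
    num = max(rss_red - rss_full, 0.0)
    if rss_full <= 1e-12 * max(rss_red, 1.0):
        # perfect fit: F diverges, p numerically zero (unless no effect at all)
        f_stat = np.inf if num > 0 else 0.0
        p_val = 0.0 if num > 0 else 1.0
    else:
        f_stat = (num / q) / (rss_full / df_res)
        p_val = float(st.f.sf(f_stat, q, df_res))
    coef = float(beta_full[x_red.shape[1]])
    return AlphaAssociation(coefficient=coef, F=float(f_stat), p=p_val, df=(q, df_res))
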