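"""Differential abundance: rank aggregation, filtering, GMPR, permutation F.

The procedure, per taxonomic rank: aggregate ASV counts to the rank,
keep taxa present in more than 10% of samples with a maximum relative
abundance above 0.2% (both strict), normalize by GMPR size factors
(geometric mean of pairwise median count ratios), square-root transform,
test each taxon with a covariate-adjusted permutation F-test
(Freedman-Lane residual permutation, 999 permutations by default), and
control FDR with the Benjamini-Hochberg step-up within the rank, flagging
q < 0.10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from microcohort._design import build_design
from microcohort.io import RANKS, CountTable

logger = logging.getLogger("microcohort")


# ---------------------------------------------------------------------------
# Aggregation and filtering
# ---------------------------------------------------------------------------

def lineage_label(lineage: Sequence[str]) -> str:
    """Label for a lineage prefix; trailing-unassigned entries pool into
    an ``unclassified_<parent>`` bucket under the last named ancestor."""
    entries = [str(e) for e in lineage]
    if entries[-1] != "":
        return ";".join(entries)
    named = [e for e in entries if e != ""]
    parent = named[-1] if named else "root"
    prefix = entries[: len(named)]
    return ";".join(prefix + [f"unclassified_{parent}"])


def aggregate(table: CountTable, taxonomy: pd.DataFrame, rank: str) -> CountTable:
    """Sum counts over ASVs sharing the lineage prefix through ``rank``."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank) + 1
    missing = [t for t in table.taxa if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxa missing from taxonomy: {missing[:10]}")
    lineages = taxonomy.loc[table.taxa, list(RANKS[:depth])].fillna("")
    labels = [lineage_label(row) for row in lineages.to_numpy()]
    df = table.to_dataframe()
    df.columns = labels
    out = df.T.groupby(level=0, sort=True).sum().T
    return CountTable(out)


def filter_taxa(
    table: CountTable,
    min_prevalence: float = 0.10,
    min_max_rel_abundance: float = 0.002,
) -> CountTable:
    """Keep taxa present in > min_prevalence of samples AND with maximum
    per-sample relative abundance > min_max_rel_abundance (both strict)."""
    mat = table.matrix.astype(float)
    depths = mat.sum(axis=1, keepdims=True)
    if (depths == 0).any():
        raise ValueError("zero-total sample in filter_taxa")
    prevalence = (mat > 0).mean(axis=0)
    max_rel = (mat / depths).max(axis=0)
    keep = (prevalence > min_prevalence) & (max_rel > min_max_rel_abundance)
    if not keep.any():
        raise ValueError(
            "all taxa removed by the prevalence/abundance filter; "
            "lower min_prevalence or min_max_rel_abundance"
        )
    return table.select_taxa([t for t, k in zip(table.taxa, keep) if k])


# ---------------------------------------------------------------------------
# GMPR normalization
# ---------------------------------------------------------------------------

def gmpr_size_factors(table: CountTable, min_shared: int = 1) -> pd.Series:
    """Geometric mean of pairwise ratios (GMPR) size factors.

    For samples i, j the pair ratio r_ij is the median of count_ik/count_jk
    over taxa nonzero in both (requiring at least ``min_shared`` such
    taxa); s_i is the geometric mean of r_ij over all j with a defined
    ratio (including the trivial self-ratio r_ii = 1, as in the reference
    formulation), rescaled so the factors have geometric mean 1. With the
    self-ratio included the factors recover exact scalar multiples of a
    common composition exactly, and scaling one sample's counts by c
    scales its factor relative to every other sample's by exactly c.
    """
    mat = table.matrix.astype(float)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("GMPR needs at least 2 samples")
    log_s = np.zeros(n)
    nonzero = mat > 0
    for i in range(n):
        log_ratios = [0.0]  # self-ratio r_ii = 1
        for j in range(n):
            if i == j:
                continue
            shared = nonzero[i] & nonzero[j]
            if shared.sum() < min_shared:
                continue
            ratio = np.median(mat[i, shared] / mat[j, shared])
            log_ratios.append(np.log(ratio))
        if len(log_ratios) == 1:
            raise ValueError(
                f"sample {table.samples[i]!r} shares fewer than {min_shared} "
                "nonzero taxa with every other sample"
            )
        log_s[i] = np.mean(log_ratios)
    log_s -= log_s.mean()  # geometric mean 1
    return pd.Series(np.exp(log_s), index=table.samples, name="size_factor")


def normalize(table: CountTable, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    missing = [s for s in table.samples if s not in size_factors.index]
    if missing:
        raise ValueError(f"missing size factors for samples: {missing[:10]}")
    sf = size_factors.loc[table.samples].to_numpy(dtype=float)
    if (sf <= 0).any() or not np.all(np.isfinite(sf)):
        raise ValueError("size factors must be finite and positive")
    return pd.DataFrame(
        table.matrix / sf[:, None], index=table.samples, columns=table.taxa
    )


# ---------------------------------------------------------------------------
# Permutation F-test (Freedman-Lane) and B-H FDR
# ---------------------------------------------------------------------------

_EPS = 1e-12


def _f_stats(y: np.ndarray, q_red: np.ndarray, q_full: np.ndarray,
             q_extra: int, df_res: int) -> np.ndarray:
    """Partial F for each column of y (n, m) given QR bases of the designs."""
    tot = (y**2).sum(axis=0)
    rss_red = tot - ((q_red.T @ y) ** 2).sum(axis=0)
    rss_full = tot - ((q_full.T @ y) ** 2).sum(axis=0)
    num = np.maximum(rss_red - rss_full, 0.0)
    scale = np.maximum(rss_red, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (num / q_extra) / (rss_full / df_res)
    # constant outcome (or perfect fit with no effect): define F = 0
    f = np.where((num <= _EPS * scale) & (rss_full <= _EPS * scale), 0.0, f)
    f = np.where(np.isnan(f), 0.0, f)
    return f


def _perm_f_many(
    y: np.ndarray,
    x_red: np.ndarray,
    x_full: np.ndarray,
    q_extra: int,
    n_permutations: int,
    seed: Optional[int],
    scheme: Literal["freedman-lane", "labels"],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """F, permutation p and direction for each column of y (n, m).

    One shared set of permutations is drawn for all columns. Under
    ``freedman-lane`` the residuals of the reduced (covariate-only) model
    are permuted and added back to its fitted values; under ``labels`` the
    outcome rows are permuted directly. The two coincide when there are no
    covariates.
    """
    n, m = y.shape
    q_red, _ = np.linalg.qr(x_red)
    q_full, _ = np.linalg.qr(x_full)
    df_res = n - x_full.shape[1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")

    f_obs = _f_stats(y, q_red, q_full, q_extra, df_res)
    beta_full = np.linalg.lstsq(x_full, y, rcond=None)[0]
    direction = np.sign(beta_full[x_red.shape[1], :])

    if scheme == "freedman-lane":
        fitted = q_red @ (q_red.T @ y)
        resid = y - fitted
    elif scheme == "labels":
        fitted = np.zeros_like(y)
        resid = y
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    rng = np.random.default_rng(seed)
    exceed = np.zeros(m, dtype=np.int64)
    for _ in range(n_permutations):
        idx = rng.permutation(n)
        y_star = fitted + resid[idx]
        f_b = _f_stats(y_star, q_red, q_full, q_extra, df_res)
        exceed += f_b >= f_obs - _EPS
    p = (1 + exceed) / (1 + n_permutations)
    return f_obs, p, direction


def perm_f_test(
    y: pd.Series,
    metadata: pd.DataFrame,
    variable: str,
    covariates: Sequence[str] = (),
    n_permutations: int = 999,
    seed: Optional[int] = None,
    scheme: Literal["freedman-lane", "labels"] = "freedman-lane",
) -> tuple[float, float, int]:
    """Covariate-adjusted permutation F-test for a single outcome.

    Returns (F, p, direction) where p = (1 + #{F_b >= F_obs})/(1 + B) and
    direction is the sign of the variable's fitted coefficient.
    """
    y = pd.Series(y).astype(float)
    metadata = metadata.loc[y.index]
    x_red, x_full, q_extra = build_design(metadata, variable, covariates)
    f, p, d = _perm_f_many(
        y.to_numpy()[:, None], x_red, x_full, q_extra, n_permutations, seed, scheme
    )
    return float(f[0]), float(p[0]), int(d[0])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# End-to-end per-rank pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonTestResult:
    taxon: str
    rank: str
    F: float
    p: float
    q: float
    direction: int
    n_permutations: int
    significant: bool


def run_da(
    table: CountTable,
    taxonomy: pd.DataFrame,
    metadata: pd.DataFrame,
    variable: str,
    covariates: Sequence[str] = (),
    ranks: Sequence[str] = ("Phylum", "Family", "Genus"),
    n_permutations: int = 999,
    seed: Optional[int] = None,
    fdr_threshold: float = 0.10,
    scheme: Literal["freedman-lane", "labels"] = "freedman-lane",
    min_prevalence: float = 0.10,
    min_max_rel_abundance: float = 0.002,
) -> pd.DataFrame:
    """Full differential-abundance analysis at each requested rank.

    Per rank: aggregate -> prevalence/abundance filter -> GMPR size
    factors on the filtered table -> normalize -> sqrt transform ->
    permutation F-test per taxon -> B-H FDR within the rank -> flag
    q < fdr_threshold. Deterministic under a fixed seed.
    """
    order = sorted(table.samples)  # canonical order: row-order invariance
    table = table.select_samples(order)
    metadata = metadata.loc[order]
    results = []
    for k, rank in enumerate(ranks):
        try:
            agg = aggregate(table, taxonomy, rank)
            filt = filter_taxa(agg, min_prevalence, min_max_rel_abundance)
            sf = gmpr_size_factors(filt)
            norm = normalize(filt, sf)
        except ValueError as exc:
            raise ValueError(f"rank {rank!r}: {exc}") from exc
        cols = sorted(norm.columns)  # canonical order: column-order invariance
        y = np.sqrt(norm[cols].to_numpy())
        x_red, x_full, q_extra = build_design(metadata, variable, covariates)
        rank_seed = None if seed is None else int(np.random.default_rng([seed, k]).integers(2**31))
        f, p, d = _perm_f_many(y, x_red, x_full, q_extra, n_permutations, rank_seed, scheme)
        q = bh_fdr(p)
        for i, taxon in enumerate(cols):
            results.append(
                TaxonTestResult(
                    taxon=taxon, rank=rank, F=float(f[i]), p=float(p[i]),
                    q=float(q[i]), direction=int(d[i]),
                    n_permutations=n_permutations,
                    significant=bool(q[i] < fdr_threshold),
                )
            )
    return pd.DataFrame([r.__dict__ for r in results])
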