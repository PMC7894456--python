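"""Cohort descriptive statistics: the "Table 1" machinery.

Two-sample t tests from printed group summaries, exact/chi-square tests on
contingency tables, exact pooling of group summaries into a whole-cohort
column, LMS growth-reference BMI z-scores and the CDC-style weight
classification (normal / overweight / obese, with obese = BMI >= 95th
percentile for age and sex).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from microcohort.io import OBESITY_CLASSES

#: Standard-normal quantiles for the 85th and 95th BMI-for-age percentiles.
Z_85TH = float(st.norm.ppf(0.85))
Z_95TH = float(st.norm.ppf(0.95))


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD of one group, in the variable's units."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"group size must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def t_test_from_summary(
    a: GroupSummary,
    b: GroupSummary,
    variant: Literal["pooled", "welch"] = "pooled",
) -> TTestResult:
    """Two-sample t test from group summaries (means, SDs, ns).

    ``pooled`` is the classic equal-variance test (df = n_a + n_b - 2);
    ``welch`` uses the Satterthwaite approximation. Two-sided p.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("t test needs n >= 2 in each group")
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=float(a.n + b.n - 2), p=1.0)
        raise ValueError("both SDs are zero with unequal means")
    t, p = st.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TTestResult(t=float(t), df=df, p=float(p))


def _as_table(tbl) -> np.ndarray:
    arr = np.asarray(tbl)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"contingency table must be at least 2x2, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("contingency table must hold non-negative integers")
    if arr.sum() == 0:
        raise ValueError("contingency table is empty")
    return arr.astype(np.int64)


def fisher_exact_2x2(tbl) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables (at
    fixed margins) no more probable than the observed one.
    """
    arr = _as_table(tbl)
    if arr.shape != (2, 2):
        raise ValueError(f"fisher_exact_2x2 needs a 2x2 table, got {arr.shape}")
    return float(st.fisher_exact(arr, alternative="two-sided")[1])


def chisq_rxc(tbl, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test on an r x c table.

    Yates continuity correction is applied only to 2x2 tables and only
    when requested. Raises on any zero row/column margin.
    """
    arr = _as_table(tbl)
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("contingency table has a zero margin")
    correction = bool(yates) and arr.shape == (2, 2)
    chi2, p, df, _ = st.chi2_contingency(arr, correction=correction)
    return float(chi2), int(df), float(p)


def combine_group_stats(groups: Sequence[GroupSummary]) -> GroupSummary:
    """Exactly pool group summaries into the summary of the concatenated data.

    Pooled variance = [sum (n_i - 1) s_i^2 + sum n_i (mean_i - M)^2] / (N - 1),
    which equals the variance of the concatenated raw observations.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to combine")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    total = ns.sum()
    grand = float((ns * means).sum() / total)
    ss = ((ns - 1) * sds**2).sum() + (ns * (means - grand) ** 2).sum()
    sd = float(np.sqrt(ss / (total - 1)))
    return GroupSummary(n=int(total), mean=grand, sd=sd)


# ---------------------------------------------------------------------------
# LMS growth-reference z-scores
# ---------------------------------------------------------------------------

def read_lms(path) -> pd.DataFrame:
    """Read an LMS reference CSV with columns sex, age_months, L, M, S."""
    df = pd.read_csv(path, dtype={"sex": str})
    required = {"sex", "age_months", "L", "M", "S"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: LMS reference missing columns {sorted(missing)}")
    return validate_lms(df)


def validate_lms(df: pd.DataFrame) -> pd.DataFrame:
    if (df["M"] <= 0).any() or (df["S"] <= 0).any():
        raise ValueError("LMS reference requires M > 0 and S > 0")
    for sex, grp in df.groupby("sex"):
        ages = grp["age_months"].to_numpy()
        if np.any(np.diff(ages) <= 0):
            raise ValueError(f"LMS ages must be strictly increasing within sex {sex!r}")
    return df.reset_index(drop=True)


def bmi_zscore(bmi: float, sex: str, age_months: float, ref: pd.DataFrame) -> float:
    """BMI-for-age z-score via the LMS method.

    L, M, S are linearly interpolated on age within sex; then
    z = ((bmi/M)^L - 1) / (L*S) for L != 0 and z = ln(bmi/M)/S for L = 0.
    """
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    sub = ref[ref["sex"] == sex]
    if sub.empty:
        raise ValueError(f"LMS reference has no rows for sex {sex!r}")
    ages = sub["age_months"].to_numpy()
    if age_months < ages[0] or age_months > ages[-1]:
        raise ValueError(
            f"age {age_months} months outside reference range [{ages[0]}, {ages[-1]}]"
        )
    L = float(np.interp(age_months, ages, sub["L"]))
    M = float(np.interp(age_months, ages, sub["M"]))
    S = float(np.interp(age_months, ages, sub["S"]))
    if L == 0:
        return float(np.log(bmi / M) / S)
    return float(((bmi / M) ** L - 1.0) / (L * S))


def classify_weight(z: float) -> str:
    """CDC-style class from a BMI z-score: normal / overweight / obese.

    Half-open bins: normal below the 85th percentile, overweight in
    [85th, 95th), obese at or above the 95th; a z exactly on a threshold
    goes to the upper category.
    """
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    if z >= Z_95TH:
        return "obese"
    if z >= Z_85TH:
        return "overweight"
    return "normal"


def obesity_flag(z: float) -> str:
    """Binary obesity class: normal + overweight merge into non-obese."""
    return OBESITY_CLASSES[1] if classify_weight(z) == "obese" else OBESITY_CLASSES[0]


# ---------------------------------------------------------------------------
# Table-1-style report
# ---------------------------------------------------------------------------

def cohort_summary(
    records: pd.DataFrame,
    group: str = "ethnicity",
    continuous: Sequence[str] = ("age", "weight_lb", "height_cm", "bmi", "bmi_z", "amy1_cnv"),
    categorical: Sequence[str] = ("sex", "obesity", "income", "education"),
    t_variant: Literal["pooled", "welch"] = "pooled",
) -> pd.DataFrame:
    """Per-group means/SDs or category counts with the appropriate test.

    Continuous variables get group mean (SD), a pooled Total column via
    :func:`combine_group_stats`, and a two-group t test. Categorical
    variables get per-group counts (%) and a Fisher exact test when the
    table is 2x2, otherwise a Pearson chi-square. Rows with missing values
    are dropped per variable (complete-case).
    """
    levels = [g for g in records[group].unique() if g != ""]
    if len(levels) < 2:
        raise ValueError(f"need >= 2 strata of {group!r}")
    rows = []
    for var in continuous:
        if var not in records.columns:
            continue
        sub = records[[group, var]].dropna()
        summaries = []
        cells = {}
        for lvl in levels:
            vals = sub.loc[sub[group] == lvl, var].astype(float)
            if len(vals) < 2:
                raise ValueError(f"stratum {lvl!r} has fewer than 2 values for {var!r}")
            gs = GroupSummary(n=len(vals), mean=float(vals.mean()), sd=float(vals.std(ddof=1)))
            summaries.append(gs)
            cells[lvl] = f"{gs.mean:.3g} ({gs.sd:.3g})"
        total = combine_group_stats(summaries)
        cells["Total"] = f"{total.mean:.3g} ({total.sd:.3g})"
        p = np.nan
        if len(levels) == 2:
            p = t_test_from_summary(summaries[0], summaries[1], variant=t_variant).p
        rows.append({"variable": var, "type": "continuous", **cells, "p": p})
    for var in categorical:
        if var not in records.columns:
            continue
        sub = records[records[var] != ""][[group, var]].dropna()
        tbl = pd.crosstab(sub[var], sub[group])[levels]
        cells = {}
        for lvl in levels:
            counts = tbl[lvl]
            pct = 100 * counts / counts.sum()
            cells[lvl] = "; ".join(f"{c}: {n} ({q:.3g}%)" for c, n, q in zip(tbl.index, counts, pct))
        totals = tbl.sum(axis=1)
        pct = 100 * totals / totals.sum()
        cells["Total"] = "; ".join(
            f"{c}: {n} ({q:.3g}%)" for c, n, q in zip(tbl.index, totals, pct)
        )
        if tbl.shape == (2, 2):
            p = fisher_exact_2x2(tbl.to_numpy())
        else:
            p = chisq_rxc(tbl.to_numpy())[2]
        rows.append({"variable": var, "type": "categorical", **cells, "p": p})
    return pd.DataFrame(rows).set_index("variable")
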