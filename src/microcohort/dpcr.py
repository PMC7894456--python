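"""Digital-PCR copy-number quantification for AMY1.

A chip partitions the reaction into thousands of wells; under the Poisson
single-molecule occupancy model the mean template copies per partition is
lambda = -ln(1 - positive fraction). The AMY1 copy number per genome is
then the concentration ratio to the diploid reference gene (RNase P,
assumed 2 copies/genome): CNV = 2 * lambda_AMY1 / lambda_RNaseP.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("microcohort")

REFERENCE_ASSAY = "RNaseP"
TARGET_ASSAY = "AMY1"


def poisson_lambda(positives: int, partitions: int) -> float:
    """Mean copies per partition implied by the positive-partition fraction."""
    if partitions <= 0:
        raise ValueError(f"partitions must be positive, got {partitions}")
    if positives < 0:
        raise ValueError(f"positives must be >= 0, got {positives}")
    if positives >= partitions:
        raise ValueError(
            f"saturated chip: {positives}/{partitions} positive partitions "
            "leave the Poisson estimate undefined"
        )
    return float(-np.log1p(-positives / partitions))


def amy1_cnv(lambda_amy1: float, lambda_rnasep: float, reference_copies: float = 2.0) -> float:
    """Copies of AMY1 per genome from the two per-partition concentrations."""
    if lambda_rnasep <= 0:
        raise ValueError(f"reference lambda must be positive, got {lambda_rnasep}")
    if lambda_amy1 < 0:
        raise ValueError(f"target lambda must be >= 0, got {lambda_amy1}")
    return float(reference_copies * lambda_amy1 / lambda_rnasep)


def estimate_cnv(wells: pd.DataFrame, reference_copies: float = 2.0) -> pd.Series:
    """Per-participant AMY1 CNV from a table of dPCR wells.

    ``wells`` has columns participant, assay (AMY1 / RNaseP), positives,
    partitions. Replicate wells of the same assay are combined by summing
    positives and partitions before the Poisson correction.
    """
    out = {}
    for pid, grp in wells.groupby("participant", sort=False):
        lam = {}
        for assay in (TARGET_ASSAY, REFERENCE_ASSAY):
            sub = grp[grp["assay"] == assay]
            if sub.empty:
                raise ValueError(f"participant {pid!r}: no {assay} wells")
            lam[assay] = poisson_lambda(int(sub["positives"].sum()), int(sub["partitions"].sum()))
        out[pid] = amy1_cnv(lam[TARGET_ASSAY], lam[REFERENCE_ASSAY], reference_copies)
    return pd.Series(out, name="amy1_cnv")


def dichotomize_amy1(values: pd.Series) -> pd.Series:
    """Median split into 'low' / 'high'; values equal to the median go low."""
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("need >= 2 participants to dichotomize")
    if values.nunique() == 1:
        raise ValueError("all AMY1 values identical: median split is degenerate")
    med = float(values.median())
    return pd.Series(np.where(values <= med, "low", "high"), index=values.index, name="amy1_class")
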