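import numpy as np
import pandas as pd
import pytest

from microcohort.io import CountTable
from microcohort.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_counts,
    generate_metadata,
    generate_taxonomy,
)


@pytest.fixture(scope="session")
def small_cohort():
    """20 participants, 60 taxa, modest depth: enough for every stage."""
    cfg = CohortConfig(n_per_group=10, n_taxa=60, depth_median=2000, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """Study-shaped cohort: 30 per ethnicity, gut site only."""
    cfg = CohortConfig(n_per_group=30, n_taxa=150, depth_median=5000, seed=23)
    metadata = generate_metadata(cfg)
    counts, truth = generate_counts(metadata, cfg)
    taxonomy = generate_taxonomy(cfg.n_taxa, seed=cfg.seed)
    site_meta = metadata.copy()
    site_meta.index = counts.samples
    return counts, site_meta, taxonomy, truth


@pytest.fixture
def toy_counts():
    return CountTable(
        pd.DataFrame(
            [[5, 0, 3], [1, 2, 0]],
            index=["s1", "s2"],
            columns=["t1", "t2", "t3"],
        )
    )


@pytest.fixture(scope="session")
def lms_reference():
    """Small synthetic LMS table (not a real growth reference)."""
    rows = []
    for sex in ("F", "M"):
        for age in (72, 84, 96, 108, 120):
            rows.append(
                dict(sex=sex, age_months=age, L=-1.5 + 0.01 * age / 12,
                     M=15.0 + 0.03 * age / 12, S=0.10 + (sex == "M") * 0.01)
            )
    return pd.DataFrame(rows)


def braycurtis_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return np.abs(x - y).sum() / (x + y).sum()
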