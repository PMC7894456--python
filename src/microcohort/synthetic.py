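"""Synthetic cohorts with known ground truth.

Emulates the study design: 60 children (30 African American, 30 European
American), roughly 28% obese, metadata marginals matching the published
cohort table, 16S count tables at sequencing depths log-normal around a
median of 56,439 reads, a random phylogeny over the taxa, and digital-PCR
wells driven by each participant's true AMY1 copy number. Counts follow a
Dirichlet-multinomial with optional multiplicative "spikes" on chosen
taxa, so differential-abundance power and FDR can be measured against a
known truth.

Each generator draws from its own RNG stream, seeded as (config.seed,
fixed offset), so adding outputs never perturbs earlier ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats as st
import skbio

from microcohort.cohort import Z_95TH
from microcohort.io import (
    EDUCATION_LEVELS,
    ETHNICITIES,
    INCOME_BRACKETS,
    OBESITY_CLASSES,
    RANKS,
    SEXES,
    CountTable,
)

# RNG sub-stream offsets, one per generated artifact
_SEED_METADATA, _SEED_TREE, _SEED_COUNTS, _SEED_DPCR = 11, 13, 17, 19

#: Cohort-table marginals of the study population, by ethnicity.
TABLE1_SEX_P = {"AA": (18 / 30, 12 / 30), "EA": (17 / 30, 13 / 30)}  # (F, M)
TABLE1_INCOME_P = {
    "AA": (23 / 30, 0.0, 2 / 30, 5 / 30),
    "EA": (2 / 30, 7 / 30, 8 / 30, 13 / 30),
}
TABLE1_EDUCATION_P = {"AA": (13 / 30, 17 / 30), "EA": (6 / 30, 24 / 30)}  # (no higher, higher)

AGE_MEAN, AGE_SD, AGE_RANGE = 8.56, 1.41, (6.0, 10.0)
AMY1_MEAN, AMY1_SD = 7.11, 2.46
BMI_NONOBESE = (17.37, 2.04)
BMI_OBESE = (23.40, 3.32)
BMIZ_MEAN, BMIZ_SD = 1.11, 1.23
HEIGHT_MEAN, HEIGHT_SD = 134.0, 11.8
LB_PER_KG = 2.20462


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the published study's conditions: 30 children per
    ethnicity, 17/60 obese, sequencing depth median 56,439 reads with a
    log-SD of 0.5 (spanning the printed 9,099-118,425 range), and a sparse
    Dirichlet base concentration of 0.5 per taxon. ``spike_spec`` lists
    (taxon id, metadata column, log2 fold change) effects with binary
    covariates coded 0/1.
    """

    n_per_group: int = 30
    obese_fraction: float = 17 / 60
    n_taxa: int = 1000
    depth_median: float = 56439.0
    depth_log_sd: float = 0.5
    base_concentration: Union[float, np.ndarray] = 0.5
    spike_spec: Sequence[tuple[str, str, float]] = field(default_factory=list)
    dpcr_partitions: int = 20000
    dpcr_lambda_ref: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if not 0 < self.obese_fraction < 1:
            raise ValueError(f"obese_fraction must be in (0,1), got {self.obese_fraction}")
        if self.n_taxa < 2:
            raise ValueError(f"n_taxa must be >= 2, got {self.n_taxa}")
        if self.depth_median <= 0:
            raise ValueError("depth_median must be positive")
        if any(not np.isfinite(lfc) for _, _, lfc in self.spike_spec):
            raise ValueError("spike fold changes must be finite")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated count table."""

    spiked_taxa: dict[str, tuple[str, float]]
    true_size_factors: pd.Series
    true_cnv: pd.Series

    def to_json(self, path) -> None:
        payload = {
            "spiked_taxa": {k: list(v) for k, v in self.spiked_taxa.items()},
            "true_size_factors": self.true_size_factors.to_dict(),
            "true_cnv": self.true_cnv.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return st.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_metadata(config: CohortConfig) -> pd.DataFrame:
    """Participant records matching the study's metadata marginals.

    Ethnicity is balanced by construction; sex, income bracket and
    maternal education are drawn from the per-ethnicity cohort-table
    proportions; age ~ N(8.56, 1.41) truncated to [6, 10] years; AMY1
    CNV ~ N(7.11, 2.46) truncated positive; obesity is Bernoulli with the
    configured fraction, and BMI/BMI-z/height/weight are drawn
    consistently with the assigned class.
    """
    rng = np.random.default_rng([config.seed, _SEED_METADATA])
    n = config.n_per_group
    frames = []
    for eth in ETHNICITIES:
        pids = [f"{eth}{k + 1:03d}" for k in range(n)]
        sex = rng.choice(SEXES, size=n, p=TABLE1_SEX_P[eth])
        income = rng.choice(INCOME_BRACKETS, size=n, p=TABLE1_INCOME_P[eth])
        education = rng.choice(EDUCATION_LEVELS, size=n, p=TABLE1_EDUCATION_P[eth])
        age = _truncnorm(rng, AGE_MEAN, AGE_SD, *AGE_RANGE, size=n)
        amy1 = _truncnorm(rng, AMY1_MEAN, AMY1_SD, 0.0, np.inf, size=n)
        obese = rng.random(n) < config.obese_fraction
        bmi_z = np.where(
            obese,
            _truncnorm(rng, BMIZ_MEAN, BMIZ_SD, Z_95TH, np.inf, size=n),
            _truncnorm(rng, BMIZ_MEAN, BMIZ_SD, -np.inf, Z_95TH, size=n),
        )
        bmi = np.where(
            obese,
            _truncnorm(rng, *BMI_OBESE, 10.0, np.inf, size=n),
            _truncnorm(rng, *BMI_NONOBESE, 10.0, np.inf, size=n),
        )
        height = _truncnorm(rng, HEIGHT_MEAN, HEIGHT_SD, 80.0, np.inf, size=n)
        weight_lb = bmi * (height / 100.0) ** 2 * LB_PER_KG
        frames.append(pd.DataFrame({
            "participant": pids, "ethnicity": eth, "sex": sex,
            "age": age, "weight_lb": weight_lb.round(2),
            "height_cm": height.round(1), "bmi": bmi.round(2),
            "bmi_z": bmi_z.round(3),
            "obesity": np.where(obese, OBESITY_CLASSES[1], OBESITY_CLASSES[0]),
            "income": income, "education": education, "amy1_cnv": amy1.round(3),
        }))
    return pd.concat(frames, ignore_index=True).set_index("participant")


def generate_tree(n_taxa: int, seed: int = 0) -> skbio.TreeNode:
    """Random rooted binary tree over taxon_0..taxon_{n-1}.

    Topology by random sequential joins; every branch length i.i.d.
    Exponential with mean 0.1.
    """
    if n_taxa < 2:
        raise ValueError(f"need at least 2 taxa for a tree, got {n_taxa}")
    rng = np.random.default_rng([seed, _SEED_TREE])
    nodes = [skbio.TreeNode(name=f"taxon_{i}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = skbio.TreeNode(children=[left, right])
        left.length = float(rng.exponential(0.1))
        right.length = float(rng.exponential(0.1))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _covariate_values(metadata: pd.DataFrame, column: str) -> np.ndarray:
    """Numeric (0/1 for binary categoricals) covariate vector for spiking."""
    if column not in metadata.columns:
        raise ValueError(f"spike covariate {column!r} not in metadata")
    s = metadata[column]
    if pd.api.types.is_numeric_dtype(s):
        return s.to_numpy(dtype=float)
    levels = sorted(s.astype(str).unique())
    if len(levels) > 2:
        raise ValueError(f"spike covariate {column!r} has {len(levels)} levels; want <= 2")
    return (s.astype(str) == levels[-1]).to_numpy(dtype=float)


def generate_counts(
    metadata: pd.DataFrame, config: CohortConfig, site: str = "gut"
) -> tuple[CountTable, SyntheticTruth]:
    """Dirichlet-multinomial count table with known spiked effects.

    Per sample: depth ~ LogNormal(ln depth_median, depth_log_sd);
    Dirichlet concentrations start from the base and each spike multiplies
    its taxon's concentration by 2^(lfc * covariate); counts are then
    multinomial at the drawn depth. The truth records the spikes, the
    depth-derived size factors (depths scaled to geometric mean 1) and the
    participants' true AMY1 copy numbers.
    """
    if metadata.empty:
        raise ValueError("metadata is empty")
    site_key = zlib.crc32(site.encode("utf-8"))  # stable across processes
    rng = np.random.default_rng([config.seed, _SEED_COUNTS, site_key])
    m = config.n_taxa
    taxa = [f"taxon_{i}" for i in range(m)]
    base = np.broadcast_to(np.asarray(config.base_concentration, dtype=float), (m,)).copy()
    if (base <= 0).any():
        raise ValueError("base concentration must be positive")
    spikes = {}
    spike_cols = {}
    for taxon, cov, lfc in config.spike_spec:
        if taxon not in set(taxa):
            raise ValueError(f"spiked taxon {taxon!r} not among generated taxa")
        spikes[taxon] = (cov, float(lfc))
        spike_cols[cov] = _covariate_values(metadata, cov)

    n = len(metadata)
    depths = rng.lognormal(np.log(config.depth_median), config.depth_log_sd, size=n)
    depths = np.maximum(depths.round().astype(np.int64), 1)
    counts = np.empty((n, m), dtype=np.int64)
    idx_of = {t: i for i, t in enumerate(taxa)}
    for i in range(n):
        alpha = base.copy()
        for taxon, (cov, lfc) in spikes.items():
            alpha[idx_of[taxon]] *= 2.0 ** (lfc * spike_cols[cov][i])
        comp = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depths[i], comp)
    samples = [f"{pid}_{site}" for pid in metadata.index]
    table = CountTable(pd.DataFrame(counts, index=samples, columns=taxa))
    log_d = np.log(depths.astype(float))
    sf = pd.Series(np.exp(log_d - log_d.mean()), index=samples, name="size_factor")
    cnv = metadata["amy1_cnv"] if "amy1_cnv" in metadata.columns else pd.Series(dtype=float)
    truth = SyntheticTruth(spiked_taxa=spikes, true_size_factors=sf, true_cnv=cnv)
    return table, truth


def generate_taxonomy(n_taxa: int, seed: int = 0, n_genera: Optional[int] = None,
                      ) -> pd.DataFrame:
    """Random but consistent 7-rank lineages for taxon_0..taxon_{n-1}.

    Builds a nested hierarchy (each genus inside one family, each family
    inside one order, ...) so rank aggregation is well-defined; ~5% of
    ASVs get an empty Genus/Species to exercise the unclassified buckets.
    """
    rng = np.random.default_rng([seed, _SEED_TREE, 1])
    if n_genera is None:
        n_genera = max(2, n_taxa // 5)
    sizes = {"Phylum": max(2, n_genera // 16), "Class": max(2, n_genera // 8),
             "Order": max(2, n_genera // 4), "Family": max(2, n_genera // 2),
             "Genus": n_genera}
    parent = {"Class": "Phylum", "Order": "Class", "Family": "Order", "Genus": "Family"}
    assignment = {"Phylum": {f"p{i}": "Bacteria" for i in range(sizes["Phylum"])}}
    for rank in ("Class", "Order", "Family", "Genus"):
        prefix = rank[0].lower()
        parents = list(assignment[parent[rank]])
        assignment[rank] = {
            f"{prefix}{i}": parents[int(rng.integers(len(parents)))]
            for i in range(sizes[rank])
        }
    rows = []
    genera = list(assignment["Genus"])
    for i in range(n_taxa):
        g = genera[int(rng.integers(len(genera)))]
        lineage = {"Kingdom": "Bacteria", "Genus": g, "Species": f"{g}_sp{i}"}
        node, rank = g, "Genus"
        while rank in parent:
            node = assignment[rank][node]
            rank = parent[rank]
            lineage[rank] = node
        if rng.random() < 0.05:  # exercise the unclassified buckets downstream
            lineage["Genus"] = ""
            lineage["Species"] = ""
        rows.append({"taxon": f"taxon_{i}", **{r: lineage.get(r, "") for r in RANKS}})
    return pd.DataFrame(rows).set_index("taxon")


def generate_dpcr(metadata: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Digital-PCR wells for every participant.

    Reference positives ~ Binomial(partitions, 1 - exp(-lambda_ref));
    target lambda = lambda_ref * CNV / 2 with the participant's true CNV.
    """
    if config.dpcr_partitions <= 0:
        raise ValueError(f"dpcr_partitions must be positive, got {config.dpcr_partitions}")
    if config.dpcr_lambda_ref <= 0:
        raise ValueError(f"dpcr_lambda_ref must be positive, got {config.dpcr_lambda_ref}")
    rng = np.random.default_rng([config.seed, _SEED_DPCR])
    n_part = config.dpcr_partitions
    lam_ref = config.dpcr_lambda_ref
    rows = []
    for pid, rec in metadata.iterrows():
        cnv = float(rec["amy1_cnv"])
        lam_t = lam_ref * cnv / 2.0
        pos_ref = int(rng.binomial(n_part, 1.0 - np.exp(-lam_ref)))
        pos_t = int(rng.binomial(n_part, 1.0 - np.exp(-lam_t)))
        rows.append(dict(participant=pid, assay="RNaseP", positives=pos_ref, partitions=n_part))
        rows.append(dict(participant=pid, assay="AMY1", positives=pos_t, partitions=n_part))
    return pd.DataFrame(rows)


@dataclass
class SyntheticCohort:
    metadata: pd.DataFrame
    counts: dict[str, CountTable]
    truth: dict[str, SyntheticTruth]
    taxonomy: pd.DataFrame
    tree: skbio.TreeNode
    dpcr: pd.DataFrame


def generate_cohort(config: CohortConfig, sites: Sequence[str] = ("gut", "oral"),
                    ) -> SyntheticCohort:
    """Generate the full study bundle: metadata, per-site counts with
    truth, taxonomy, tree and dPCR wells."""
    metadata = generate_metadata(config)
    counts, truth = {}, {}
    for site in sites:
        counts[site], truth[site] = generate_counts(metadata, config, site=site)
    taxonomy = generate_taxonomy(config.n_taxa, seed=config.seed)
    tree = generate_tree(config.n_taxa, seed=config.seed)
    dpcr = generate_dpcr(metadata, config)
    return SyntheticCohort(metadata=metadata, counts=counts, truth=truth,
                           taxonomy=taxonomy, tree=tree, dpcr=dpcr)
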