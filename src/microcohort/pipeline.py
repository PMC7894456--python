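"""Study orchestration: derived analysis variables and the full run.

``run_study`` executes, for every body site x variable of interest, the
pooled analysis (ethnicity as covariate) and the per-ethnicity stratified
analyses: alpha-diversity associations, three beta-diversity distances
with PERMANOVA, and differential abundance at the configured ranks. Each
cell writes a TSV; a JSON manifest records seeds, versions and any cell
failures so every cell is reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from microcohort import __version__, alpha as alpha_mod, beta as beta_mod, da as da_mod
from microcohort.cohort import cohort_summary
from microcohort.dpcr import dichotomize_amy1, estimate_cnv
from microcohort.io import (
    INCOME_BRACKETS,
    align,
    read_count_table,
    read_dpcr,
    read_metadata,
    read_taxonomy,
    read_tree,
)

logger = logging.getLogger("microcohort")

LOW_INCOME_BRACKETS = set(INCOME_BRACKETS[:2])  # <= $50,000/year

DEFAULT_VARIABLES = ("ethnicity", "obesity", "amy1_class", "income_low", "education_high")
DEFAULT_METRICS = ("braycurtis", "uunifrac", "wunifrac")


def derive_variables(metadata: pd.DataFrame, wells: Optional[pd.DataFrame] = None,
                     ) -> pd.DataFrame:
    """Add the binary analysis columns used across the study.

    income_low: annual household income at or below $50,000;
    education_high: at least one parent with post-high-school education;
    amy1_class: median split of the AMY1 copy number (from dPCR wells when
    given, else the metadata column).
    """
    out = metadata.copy()
    if "income" in out.columns:
        unknown = set(out["income"]) - set(INCOME_BRACKETS) - {""}
        if unknown:
            raise ValueError(f"unmappable income bracket(s): {sorted(unknown)}")
        out["income_low"] = out["income"].map(
            lambda b: "" if b == "" else ("low" if b in LOW_INCOME_BRACKETS else "high")
        )
    if "education" in out.columns:
        out["education_high"] = out["education"].map(
            {"higher": "yes", "no higher": "no", "": ""}
        )
        if out["education_high"].isna().any():
            bad = sorted(set(out.loc[out["education_high"].isna(), "education"]))
            raise ValueError(f"unmappable education value(s): {bad}")
    if wells is not None:
        cnv = estimate_cnv(wells)
        out["amy1_cnv_dpcr"] = cnv.reindex(out.index)
        out["amy1_class"] = dichotomize_amy1(cnv).reindex(out.index)
    elif "amy1_cnv" in out.columns:
        out["amy1_class"] = dichotomize_amy1(out["amy1_cnv"])
    return out


@dataclass
class StudyConfig:
    """Inputs and knobs for a full study run.

    ``sites`` maps a body-site name to its input paths (counts, taxonomy,
    tree, all per site); metadata and dPCR wells are shared. Pooled
    analyses always adjust for ethnicity; stratified ones never do.
    """

    metadata: str
    sites: dict[str, dict[str, str]]
    dpcr: Optional[str] = None
    variables: Sequence[str] = DEFAULT_VARIABLES
    metrics: Sequence[str] = DEFAULT_METRICS
    ranks: Sequence[str] = ("Phylum", "Family", "Genus")
    rarefaction_depth: Optional[int] = None  # None = minimum sample depth
    n_permutations: int = 999
    fdr_threshold: float = 0.10
    seed: int = 17
    output_dir: str = "study_out"
    figures: bool = False

    def __post_init__(self):
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _alpha_cell(bundle, metadata, variable, covariates, seed, depth):
    rare = alpha_mod.rarefy(bundle.counts, depth=depth, seed=seed)
    metrics = alpha_mod.alpha_table(rare)
    rows = []
    for metric in metrics.columns:
        res = alpha_mod.alpha_association(
            metrics[metric], metadata.loc[metrics.index], variable, covariates
        )
        rows.append(dict(metric=metric, coefficient=res.coefficient, F=res.F, p=res.p))
    return pd.DataFrame(rows), metrics


def _beta_cell(bundle, metadata, variable, covariates, metric, seed, depth, B):
    rare = alpha_mod.rarefy(bundle.counts, depth=depth, seed=seed)
    if metric == "braycurtis":
        dm = beta_mod.bray_curtis(rare)
    elif metric == "uunifrac":
        dm = beta_mod.unifrac(rare, bundle.tree, variant="unweighted")
    elif metric == "wunifrac":
        dm = beta_mod.unifrac(rare, bundle.tree, variant="weighted_normalized")
    else:
        raise ValueError(f"unknown beta metric {metric!r}")
    res = beta_mod.permanova(dm, metadata.loc[list(dm.ids)], variable, covariates,
                             n_permutations=B, seed=seed)
    return pd.DataFrame([dict(metric=metric, pseudo_F=res.pseudo_F, R2=res.r2,
                              p=res.p, n_permutations=res.n_permutations)])


def run_study(config: StudyConfig) -> dict:
    """Run every site x variable analysis cell and write the report bundle.

    A failure in one cell is recorded in the manifest and does not stop
    the remaining cells. Returns the manifest dict.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "n_permutations": config.n_permutations,
                "cells": {}, "errors": {}, "skipped": {}}

    metadata = read_metadata(config.metadata)
    wells = read_dpcr(config.dpcr) if config.dpcr else None
    metadata = derive_variables(metadata, wells)

    try:
        summary = cohort_summary(metadata)
        summary.to_csv(outdir / "cohort_summary.tsv", sep="\t")
        manifest["cells"]["cohort_summary"] = "cohort_summary.tsv"
    except Exception as exc:  # noqa: BLE001 - cell isolation by design
        manifest["errors"]["cohort_summary"] = str(exc)
    if wells is not None:
        estimate_cnv(wells).to_csv(outdir / "amy1_cnv.csv")
        manifest["cells"]["amy1_cnv"] = "amy1_cnv.csv"

    def _pcoa_figure(bundle, site):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        rare = alpha_mod.rarefy(bundle.counts, depth=config.rarefaction_depth,
                                seed=config.seed)
        res = beta_mod.pcoa(beta_mod.bray_curtis(rare), n_axes=2)
        fig, ax = plt.subplots(figsize=(5, 4))
        coords = res.coordinates
        eth = bundle.metadata.loc[coords.index, "ethnicity"]
        for grp, color in (("AA", "tab:red"), ("EA", "tab:blue")):
            sel = coords[eth == grp]
            ax.scatter(sel.iloc[:, 0], sel.iloc[:, 1], label=grp, color=color, s=18)
        ax.set_xlabel(f"PC1 ({100 * res.proportion_explained[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * res.proportion_explained[1]:.1f}%)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(outdir / f"{site}_pcoa_braycurtis.png", dpi=150)
        plt.close(fig)
        return f"{site}_pcoa_braycurtis.png"

    for site, paths in config.sites.items():
        counts = read_count_table(paths["counts"])
        taxonomy = read_taxonomy(paths["taxonomy"]) if "taxonomy" in paths else None
        tree = read_tree(paths["tree"]) if "tree" in paths else None
        # sample ids may carry a site suffix: map to participant ids
        sample_map = {s: s.rsplit("_", 1)[0] if s.rsplit("_", 1)[-1] == site else s
                      for s in counts.samples}
        site_meta = metadata.loc[[sample_map[s] for s in counts.samples]]
        site_meta.index = counts.samples
        bundle = align(counts, site_meta, taxonomy, tree)

        if config.figures:
            try:
                manifest["cells"][f"{site}_pcoa_figure"] = _pcoa_figure(bundle, site)
            except Exception as exc:  # noqa: BLE001
                manifest["errors"][f"{site}_pcoa_figure"] = str(exc)

        strata = [("pooled", bundle, ["ethnicity"]), ]
        for eth in ("AA", "EA"):
            ids = [s for s in bundle.samples if bundle.metadata.loc[s, "ethnicity"] == eth]
            if len(ids) >= 4:
                sub = align(bundle.counts.select_samples(ids), bundle.metadata.loc[ids],
                            taxonomy, tree)
                strata.append((eth, sub, []))

        for variable in config.variables:
            for stratum, sub, covs in strata:
                covariates = [c for c in covs if c != variable]
                if variable not in sub.metadata.columns:
                    manifest["skipped"][f"{site}/{stratum}/{variable}"] = "variable missing"
                    continue
                if sub.metadata[variable].replace("", pd.NA).dropna().nunique() < 2:
                    # e.g. ethnicity inside an ethnicity stratum: nothing to test
                    manifest["skipped"][f"{site}/{stratum}/{variable}"] = "variable constant"
                    continue
                cellname = f"{site}_{stratum}_{variable}"
                try:
                    alpha_res, _ = _alpha_cell(sub, sub.metadata, variable, covariates,
                                               config.seed, config.rarefaction_depth)
                    alpha_res.to_csv(outdir / f"{cellname}_alpha.tsv", sep="\t", index=False)
                    manifest["cells"][f"{cellname}_alpha"] = f"{cellname}_alpha.tsv"
                except Exception as exc:  # noqa: BLE001
                    manifest["errors"][f"{cellname}_alpha"] = str(exc)
                beta_rows = []
                for metric in config.metrics:
                    try:
                        if metric in ("uunifrac", "wunifrac") and sub.tree is None:
                            raise ValueError("UniFrac requested but no tree configured")
                        beta_rows.append(
                            _beta_cell(sub, sub.metadata, variable, covariates, metric,
                                       config.seed, config.rarefaction_depth,
                                       config.n_permutations)
                        )
                    except Exception as exc:  # noqa: BLE001
                        manifest["errors"][f"{cellname}_beta_{metric}"] = str(exc)
                if beta_rows:
                    pd.concat(beta_rows).to_csv(outdir / f"{cellname}_beta.tsv",
                                                sep="\t", index=False)
                    manifest["cells"][f"{cellname}_beta"] = f"{cellname}_beta.tsv"
                try:
                    if sub.taxonomy is None:
                        raise ValueError("differential abundance requires a taxonomy")
                    da_res = da_mod.run_da(
                        sub.counts, sub.taxonomy, sub.metadata, variable, covariates,
                        ranks=config.ranks, n_permutations=config.n_permutations,
                        seed=config.seed, fdr_threshold=config.fdr_threshold,
                    )
                    da_res.to_csv(outdir / f"{cellname}_da.tsv", sep="\t", index=False)
                    manifest["cells"][f"{cellname}_da"] = f"{cellname}_da.tsv"
                except Exception as exc:  # noqa: BLE001
                    manifest["errors"][f"{cellname}_da"] = str(exc)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
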