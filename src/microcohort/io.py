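"""Readers, writers and validation for every on-disk artifact.

All tables are plain text (TSV/CSV, UTF-8, Unix newlines); trees are
Newick. Readers validate strictly and raise rather than coerce; every
writer/reader pair is an inverse on valid inputs. Orientation is fixed:
samples in rows, taxa in columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("microcohort")

#: Taxonomic ranks, coarsest to finest; taxonomy tables carry all seven.
RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")

ETHNICITIES = ("AA", "EA")
SEXES = ("F", "M")
INCOME_BRACKETS = ("<25,000", "25,001-50,000", "50,001-75,000", ">75,001")
EDUCATION_LEVELS = ("no higher", "higher")
OBESITY_CLASSES = ("non-obese", "obese")

#: Metadata columns with a closed vocabulary; empty string means missing.
_VOCABULARIES = {
    "ethnicity": ETHNICITIES,
    "sex": SEXES,
    "income": INCOME_BRACKETS,
    "education": EDUCATION_LEVELS,
    "obesity": OBESITY_CLASSES,
}


class CountTable:
    """Samples x taxa matrix of non-negative integer read counts.

    The central object of every analysis stage. Wraps a pandas DataFrame
    whose index holds sample ids and whose columns hold taxon ids; both
    must be unique, and every cell a non-negative integer.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        arr = data.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            # accept float frames that are exactly integral (e.g. from IO)
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                i, j = np.argwhere((~np.isfinite(arr)) | (arr != np.floor(arr)))[0]
                raise ValueError(
                    f"non-integer count at sample {data.index[i]!r}, "
                    f"taxon {data.columns[j]!r}: {arr[i, j]!r}"
                )
            arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {data.index[i]!r}, "
                f"taxon {data.columns[j]!r}: {arr[i, j]}"
            )
        self._data = pd.DataFrame(
            arr.astype(np.int64), index=data.index.astype(str), columns=data.columns.astype(str)
        )

    # -- accessors ---------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def taxa(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def matrix(self) -> np.ndarray:
        """Counts as an (n_samples, n_taxa) int64 array (a copy)."""
        return self._data.to_numpy(copy=True)

    def to_dataframe(self) -> pd.DataFrame:
        return self._data.copy()

    @property
    def depths(self) -> pd.Series:
        """Per-sample totals (sequencing depths)."""
        return self._data.sum(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def select_samples(self, ids: Sequence[str]) -> "CountTable":
        return CountTable(self._data.loc[list(ids)])

    def select_taxa(self, ids: Sequence[str]) -> "CountTable":
        return CountTable(self._data[list(ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self._data.equals(other._data)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"<CountTable: {n} samples x {m} taxa>"


def read_count_table(path) -> CountTable:
    """Read a TSV count table (header of taxon ids, first column sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.name is None and df.empty:
        raise ValueError(f"{path}: empty count table")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric count at sample {df.index[i]!r}, "
            f"taxon {df.columns[j]!r}: {df.iloc[i, j]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise ValueError(f"{path}: ragged or missing cells in count table")
    return CountTable(numeric)


def write_count_table(table: CountTable, path) -> None:
    df = table.to_dataframe()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_tree(path) -> skbio.TreeNode:
    """Read a rooted Newick tree.

    Missing branch lengths are treated as 0 with a logged warning; the root
    itself is allowed a None length. Leaf labels must be unique.
    """
    tree = skbio.TreeNode.read(str(path), format="newick")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0 or not np.isfinite(node.length):
            raise ValueError(f"{path}: invalid branch length {node.length} on {node.name!r}")
    if n_missing:
        logger.warning("%s: %d branch length(s) missing, treated as 0", path, n_missing)
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError(f"{path}: duplicate leaf labels")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_taxonomy(path) -> pd.DataFrame:
    """Read a TSV taxonomy table: taxon id + the seven rank columns.

    Empty entries (unassigned at that rank) are kept as empty strings.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ValueError(f"{path}: taxonomy is missing rank columns {missing}")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate taxon ids in taxonomy")
    return df[list(RANKS)]


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    out = taxonomy.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the participant metadata CSV into a validated table.

    One row per participant: ethnicity, sex, age (years), weight (lb),
    height (cm), BMI, BMI z-score, obesity class, income bracket, maternal
    education and AMY1 copy number. Missing values are empty strings for
    categorical fields and NaN for numeric ones; closed-vocabulary columns
    are checked against their vocabulary.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate participant ids")
    df.index = df.index.astype(str)
    for col, vocab in _VOCABULARIES.items():
        if col not in df.columns:
            continue
        bad = sorted(set(df[col]) - set(vocab) - {""})
        if bad:
            raise ValueError(f"{path}: column {col!r} has values outside {vocab}: {bad}")
    for col in ("age", "weight_lb", "height_cm", "bmi", "bmi_z", "amy1_cnv"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace("", np.nan))
    if "age" in df.columns:
        ages = df["age"].dropna()
        if ((ages < 0) | (ages > 20)).any():
            raise ValueError(f"{path}: age outside [0, 20]")
    for col in ("weight_lb", "height_cm"):
        if col in df.columns and (df[col].dropna() <= 0).any():
            raise ValueError(f"{path}: non-positive {col}")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "participant"
    out.to_csv(path, lineterminator="\n")


def read_dpcr(path) -> pd.DataFrame:
    """Read digital-PCR wells: participant, assay, positives, partitions."""
    df = pd.read_csv(path, dtype={"participant": str, "assay": str})
    required = {"participant", "assay", "positives", "partitions"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: dPCR table missing columns {sorted(missing)}")
    if (df["partitions"] <= 0).any():
        raise ValueError(f"{path}: non-positive partition counts")
    if ((df["positives"] < 0) | (df["positives"] > df["partitions"])).any():
        raise ValueError(f"{path}: positives outside [0, partitions]")
    return df


def write_dpcr(wells: pd.DataFrame, path) -> None:
    wells.to_csv(path, index=False, lineterminator="\n")


@dataclass
class StudyBundle:
    """Aligned study inputs: counts, metadata and optional taxonomy/tree.

    Sample order follows the count table; metadata is restricted and
    reordered to match. Construct via :func:`align`.
    """

    counts: CountTable
    metadata: pd.DataFrame
    taxonomy: Optional[pd.DataFrame] = None
    tree: Optional[skbio.TreeNode] = None

    @property
    def samples(self) -> list[str]:
        return self.counts.samples


def align(
    counts: CountTable,
    metadata: pd.DataFrame,
    taxonomy: Optional[pd.DataFrame] = None,
    tree: Optional[skbio.TreeNode] = None,
) -> StudyBundle:
    """Intersect and order samples, and validate taxon coverage.

    Samples are restricted to the intersection of count-table and metadata
    ids, in count-table order; dropped ids are logged. Every count-table
    taxon must appear in the taxonomy (if given) and as a tree leaf (if a
    tree is given). Idempotent.
    """
    meta_ids = set(metadata.index.astype(str))
    shared = [s for s in counts.samples if s in meta_ids]
    if not shared:
        raise ValueError("no samples shared between count table and metadata")
    dropped_counts = [s for s in counts.samples if s not in meta_ids]
    dropped_meta = [s for s in metadata.index.astype(str) if s not in set(counts.samples)]
    if dropped_counts:
        logger.warning("align: dropped %d count-table sample(s) without metadata: %s",
                       len(dropped_counts), dropped_counts)
    if dropped_meta:
        logger.warning("align: dropped %d metadata row(s) without counts: %s",
                       len(dropped_meta), dropped_meta)
    counts = counts.select_samples(shared)
    metadata = metadata.loc[shared]

    if taxonomy is not None:
        missing = [t for t in counts.taxa if t not in taxonomy.index]
        if missing:
            raise ValueError(f"taxa missing from taxonomy: {missing[:10]}"
                             + ("..." if len(missing) > 10 else ""))
        taxonomy = taxonomy.loc[counts.taxa]
    if tree is not None:
        leaves = {t.name for t in tree.tips()}
        missing = [t for t in counts.taxa if t not in leaves]
        if missing:
            raise ValueError(f"taxa missing from tree: {missing[:10]}"
                             + ("..." if len(missing) > 10 else ""))
    return StudyBundle(counts=counts, metadata=metadata, taxonomy=taxonomy, tree=tree)
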