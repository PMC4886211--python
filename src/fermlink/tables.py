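"""Tabular containers and preprocessing for abundance and flavour data.

The abundance table holds genus-level profiles (rows) across fermentation
samples (columns) with a kingdom label per genus; the flavour table holds
compound concentrations with a category annotation (sugar, organic acid,
amino acid, volatile) and a subcategory for volatiles.  Preprocessing
follows the standard workflow for this kind of study: conversion to
relative abundance, selection of the top-n genera per kingdom by total
abundance, per-flavour min-max normalization, and sample alignment of the
two blocks with the metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fermlink._version import __version__ as _pkg_version

KINGDOMS = ("bacteria", "fungi")
CATEGORIES = ("sugar", "organic_acid", "amino_acid", "volatile")
VOLATILE_SUBCATEGORIES = (
    "alcohols", "acids", "esters", "ketones", "aldehydes", "heterocycles", "others",
)


class TableError(ValueError):
    """Raised for malformed or inconsistent input tables."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise TableError(f"duplicate {what} identifier(s): {dup}")


def _check_numeric_nonneg(df: pd.DataFrame, what: str) -> None:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        raise TableError(f"non-numeric cells in {what} column(s) {list(bad)}")
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise TableError(
            f"missing/non-numeric cell in {what} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise TableError(
            f"negative value in {what} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )


@dataclass
class AbundanceTable:
    """Genus-by-sample abundance matrix with kingdom labels.

    ``values`` is a taxa x samples DataFrame of counts or proportions;
    ``kingdom`` maps each taxon to ``bacteria`` or ``fungi``.  When
    ``is_relative`` every sample column sums to one.
    """

    values: pd.DataFrame
    kingdom: pd.Series
    is_relative: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "taxon")
        _check_unique(self.values.columns, "sample")
        _check_numeric_nonneg(self.values, "abundance table")
        self.kingdom = self.kingdom.reindex(self.values.index)
        if self.kingdom.isna().any():
            missing = self.kingdom.index[self.kingdom.isna()].tolist()
            raise TableError(f"kingdom label missing for taxa: {missing}")
        bad = set(self.kingdom.unique()) - set(KINGDOMS)
        if bad:
            raise TableError(f"unknown kingdom label(s): {sorted(bad)}")
        if self.is_relative:
            sums = self.values.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise TableError("is_relative set but sample sums deviate from 1")

    @property
    def taxa(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class FlavourTable:
    """Flavour-by-sample concentration matrix with category annotations."""

    values: pd.DataFrame
    category: pd.Series
    subcategory: pd.Series | None = None
    is_normalized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "flavour")
        _check_unique(self.values.columns, "sample")
        _check_numeric_nonneg(self.values, "flavour table")
        self.category = self.category.reindex(self.values.index)
        if self.category.isna().any():
            missing = self.category.index[self.category.isna()].tolist()
            raise TableError(f"category missing for flavours: {missing}")
        bad = set(self.category.unique()) - set(CATEGORIES)
        if bad:
            raise TableError(f"unknown flavour category(s): {sorted(bad)}")
        if self.subcategory is None:
            self.subcategory = pd.Series("", index=self.values.index)
        else:
            self.subcategory = self.subcategory.reindex(self.values.index).fillna("")
        vol = self.category == "volatile"
        # "" marks an unspecified subcategory, which is allowed
        bad_sub = (set(self.subcategory[vol].unique())
                   - set(VOLATILE_SUBCATEGORIES) - {""})
        if bad_sub:
            raise TableError(f"unknown volatile subcategory(s): {sorted(bad_sub)}")
        if self.is_normalized:
            arr = self.values.to_numpy()
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise TableError("is_normalized set but values fall outside [0, 1]")

    @property
    def flavours(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class SampleMetadata:
    """Per-sample covariates: day, batch, stage label and process variables."""

    table: pd.DataFrame

    REQUIRED = ("day", "batch")
    NUMERIC = ("titratable_acidity", "alcohol", "temperature")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise TableError(f"metadata missing required column {col!r}")
        # negative days mark raw-material reference samples taken before
        # fermentation starts; they are excluded from prevalence counting
        dup = self.table.duplicated(subset=["batch", "day"])
        if dup.any():
            raise TableError(
                f"duplicate (batch, day) combination for samples "
                f"{self.table.index[dup].tolist()}"
            )

    @property
    def samples(self) -> pd.Index:
        return self.table.index


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _comment() -> str:
    return f"# fermlink v{_pkg_version}\n"


def read_abundance(path: str | Path) -> AbundanceTable:
    """Read a tab-separated abundance table.

    Layout: comment lines starting with ``#``, then a header row
    ``taxon_id  kingdom  <sample ids...>`` followed by one row per taxon.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    if df.columns[0] != "taxon_id" or df.columns[1] != "kingdom":
        raise TableError(
            f"abundance header must start with 'taxon_id\\tkingdom', "
            f"got {list(df.columns[:2])}"
        )
    df = df.set_index("taxon_id")
    kingdom = df.pop("kingdom")
    values = df.apply(pd.to_numeric, errors="coerce")
    sums = values.sum(axis=0).to_numpy()
    return AbundanceTable(values, kingdom, is_relative=bool(np.allclose(sums, 1.0, atol=1e-6)))


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    out = table.values.copy()
    out.insert(0, "kingdom", table.kingdom)
    out.index.name = "taxon_id"
    with open(path, "w") as fh:
        fh.write(_comment())
        out.to_csv(fh, sep="\t")


def read_flavours(path: str | Path) -> FlavourTable:
    """Read a comma-separated flavour table with category/subcategory columns."""
    df = pd.read_csv(path, comment="#", dtype={0: str, 1: str, 2: str})
    expected = ["flavour_id", "category", "subcategory"]
    if list(df.columns[:3]) != expected:
        raise TableError(f"flavour header must start with {expected}, got {list(df.columns[:3])}")
    df = df.set_index("flavour_id")
    category = df.pop("category")
    subcategory = df.pop("subcategory").fillna("")
    values = df.apply(pd.to_numeric, errors="coerce")
    arr = values.to_numpy()
    normalized = bool(arr.size and arr.min() >= -1e-9 and arr.max() <= 1 + 1e-9)
    return FlavourTable(values, category, subcategory, is_normalized=normalized)


def write_flavours(table: FlavourTable, path: str | Path) -> None:
    out = table.values.copy()
    out.insert(0, "subcategory", table.subcategory)
    out.insert(0, "category", table.category)
    out.index.name = "flavour_id"
    with open(path, "w") as fh:
        fh.write(_comment())
        out.to_csv(fh)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, comment="#", index_col="sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    with open(path, "w") as fh:
        fh.write(_comment())
        out.to_csv(fh)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample relative abundance (columns sum to one).

    Already-relative tables pass through unchanged.  An all-zero sample
    column is an error because its composition is undefined.
    """
    if table.is_relative:
        return AbundanceTable(table.values.copy(), table.kingdom.copy(), is_relative=True)
    sums = table.values.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise TableError(f"sample(s) with zero total abundance: {zero.index.tolist()}")
    rel = table.values.div(sums, axis=1)
    return AbundanceTable(rel, table.kingdom.copy(), is_relative=True)


def clr_transform(table: AbundanceTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform of a count table (taxa x samples).

    ``log(x + pseudocount)`` minus the per-sample mean of logs.  The CLR is
    the natural scale for latent-factor modelling of compositional counts:
    it removes the per-sample closure constant that relative abundance
    carries, so linear structure in log-space is recovered linearly.
    Requires a counts table (not relative abundance).
    """
    if table.is_relative:
        raise TableError("clr_transform expects counts, not relative abundance")
    logs = np.log(table.values.to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=table.taxa, columns=table.samples)


def select_top_taxa(table: AbundanceTable, n_per_kingdom: int) -> AbundanceTable:
    """Keep the ``n_per_kingdom`` most abundant genera within each kingdom.

    Abundance rank is the row sum over samples.  Ties are broken
    lexicographically by taxon identifier so the selection is reproducible
    across platforms.  Original row order is preserved among survivors.
    If a kingdom holds fewer taxa than requested, all are kept and a
    warning is emitted.
    """
    if n_per_kingdom < 1:
        raise TableError("n_per_kingdom must be >= 1")
    keep: list[str] = []
    sums = table.values.sum(axis=1)
    for kd in KINGDOMS:
        members = table.taxa[table.kingdom == kd]
        if len(members) == 0:
            continue
        if len(members) < n_per_kingdom:
            warnings.warn(
                f"kingdom {kd!r} has only {len(members)} taxa "
                f"(requested {n_per_kingdom}); keeping all",
                stacklevel=2,
            )
        ranked = sorted(members, key=lambda t: (-sums[t], t))
        keep.extend(ranked[:n_per_kingdom])
    keep_set = set(keep)
    surviving = [t for t in table.taxa if t in keep_set]
    # dropping rows breaks the sum-to-one closure, so the subset of a
    # relative table is no longer marked relative (no re-normalization here)
    still_relative = table.is_relative and len(surviving) == len(table.taxa)
    return AbundanceTable(
        table.values.loc[surviving],
        table.kingdom.loc[surviving],
        is_relative=still_relative,
    )


def min_max_normalize(table: FlavourTable) -> FlavourTable:
    """Map every flavour row to [0, 1] via (x - min) / (max - min).

    Constant rows (max == min) become all zeros with a warning; their
    correlation with anything is undefined and downstream modules exclude
    them from edges.
    """
    arr = table.values.to_numpy(dtype=float)
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    const = span[:, 0] == 0
    if const.any():
        warnings.warn(
            f"constant flavour row(s) normalized to zero: "
            f"{table.flavours[const].tolist()}",
            stacklevel=2,
        )
    span[const] = 1.0
    norm = (arr - lo) / span
    norm[const] = 0.0
    return FlavourTable(
        pd.DataFrame(norm, index=table.flavours, columns=table.samples),
        table.category.copy(),
        table.subcategory.copy(),
        is_normalized=True,
    )


def align_samples(
    abundance: AbundanceTable,
    flavours: FlavourTable,
    metadata: SampleMetadata,
) -> tuple[AbundanceTable, FlavourTable, SampleMetadata]:
    """Restrict all three tables to their common samples, ordered by (batch, day).

    Samples present in one table but not the others are dropped with a
    warning; an empty intersection is an error.
    """
    common = (
        set(abundance.samples) & set(flavours.samples) & set(metadata.samples)
    )
    if not common:
        raise TableError("no samples shared between abundance, flavours and metadata")
    union = set(abundance.samples) | set(flavours.samples) | set(metadata.samples)
    dropped = union - common
    if dropped:
        warnings.warn(f"dropping unmatched sample(s): {sorted(dropped)}", stacklevel=2)
    meta = metadata.table.loc[metadata.table.index.isin(common)]
    order = meta.sort_values(["batch", "day"], kind="mergesort").index
    return (
        AbundanceTable(
            abundance.values[order], abundance.kingdom.copy(),
            is_relative=abundance.is_relative,
        ),
        FlavourTable(
            flavours.values[order], flavours.category.copy(),
            flavours.subcategory.copy(), is_normalized=flavours.is_normalized,
        ),
        SampleMetadata(metadata.table.loc[order]),
    )
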