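"""Reading, validation, filtering and aggregation of surname-by-region counts.

The central container is :class:`SurnameCountTable`, a validated long-format
table of (surname, region, count) records: ``count`` is the number of bearers
of a surname registered in a region.  Absent pairs mean zero bearers; the raw
data this emulates are extremely sparse, so a long/tidy representation is the
natural one.  A wide surname × region matrix is available on demand via
:meth:`SurnameCountTable.to_matrix`.

All text I/O is UTF-8: diacritics in surnames are load-bearing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import MappingError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("surname", "region", "count")


@dataclass(frozen=True)
class SurnameCountTable:
    """Validated bearer counts per (surname, region).

    Invariants enforced at construction:

    * (surname, region) pairs are unique;
    * every count is a strictly positive integer.

    Parameters
    ----------
    df : pandas.DataFrame
        Long-format frame with columns ``surname``, ``region``, ``count``.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        if len(df):
            counts = df["count"]
            if not pd.api.types.is_integer_dtype(counts):
                as_float = pd.to_numeric(counts, errors="coerce")
                if as_float.isna().any() or (as_float != as_float.round()).any():
                    raise ValidationError("counts must be integers")
                df = df.assign(count=as_float.astype(np.int64))
            if (df["count"] <= 0).any():
                bad = df.loc[df["count"] <= 0].head(3)
                raise ValidationError(
                    f"counts must be strictly positive; offending rows:\n{bad}"
                )
            dup = df.duplicated(subset=["surname", "region"])
            if dup.any():
                pairs = df.loc[dup, ["surname", "region"]].head(3)
                raise SchemaError(
                    f"duplicate (surname, region) pairs, e.g.:\n{pairs}"
                )
        df = df.astype({"surname": "str", "region": "str", "count": np.int64})
        object.__setattr__(self, "df", df)

    # -- derived totals ----------------------------------------------------

    @property
    def surname_totals(self) -> pd.Series:
        """Country-wide bearer count per surname."""
        return self.df.groupby("surname", sort=True)["count"].sum()

    @property
    def region_totals(self) -> pd.Series:
        """Total bearers (of surnames in the table) per region."""
        return self.df.groupby("region", sort=True)["count"].sum()

    @property
    def grand_total(self) -> int:
        return int(self.df["count"].sum())

    @property
    def surnames(self) -> list[str]:
        return sorted(self.df["surname"].unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.df["region"].unique())

    @property
    def n_surnames(self) -> int:
        return self.df["surname"].nunique()

    @property
    def n_regions(self) -> int:
        return self.df["region"].nunique()

    def __len__(self) -> int:
        return len(self.df)

    def to_matrix(self) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
        """Return (counts, surnames, regions): a sparse surname × region matrix
        with rows/columns in sorted label order."""
        surnames = np.asarray(self.surnames)
        regions = np.asarray(self.regions)
        si = pd.Index(surnames).get_indexer(self.df["surname"])
        ri = pd.Index(regions).get_indexer(self.df["region"])
        mat = sparse.coo_matrix(
            (self.df["count"].to_numpy(), (si, ri)),
            shape=(len(surnames), len(regions)),
            dtype=np.int64,
        ).tocsr()
        return mat, surnames, regions


@dataclass(frozen=True)
class RegionTable:
    """Region metadata: identifier, optional name, optional parent region
    (e.g. a NUTS 3 administrative region containing the micro-region), and
    optional population."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        if "region" not in df.columns:
            raise SchemaError("region table requires a 'region' column")
        for col in ("name", "parent_region", "population"):
            if col not in df.columns:
                df = df.assign(**{col: pd.NA})
        if df["region"].duplicated().any():
            raise SchemaError("region identifiers must be unique")
        if df["population"].notna().any():
            pops = pd.to_numeric(df["population"].dropna(), errors="raise")
            if (pops < 0).any():
                raise ValidationError("region populations must be >= 0")
        df = df.astype({"region": "str"}).reset_index(drop=True)
        object.__setattr__(self, "df", df)

    def parent_of(self) -> dict[str, str]:
        """Mapping region -> parent_region for rows where a parent is set."""
        sub = self.df.dropna(subset=["parent_region"])
        return dict(zip(sub["region"], sub["parent_region"].astype(str)))


# -- readers / writers -----------------------------------------------------


def read_counts(path: str | Path, delimiter: str = ",", encoding: str = "utf-8") -> SurnameCountTable:
    """Read a long-format (surname, region, count) table from delimited text.

    Duplicate pairs and non-positive or non-integer counts are errors, not
    silently repaired.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, delimiter=delimiter, encoding=encoding, dtype={0: str})
    table = SurnameCountTable(df)
    logger.info(
        "read %d records (%d surnames x %d regions, %d bearers) from %s",
        len(table), table.n_surnames, table.n_regions, table.grand_total, path,
    )
    return table


def write_counts(table: SurnameCountTable, path: str | Path, delimiter: str = ",") -> None:
    """Write the table back to delimited text (UTF-8, sorted for determinism)."""
    out = table.df.sort_values(["surname", "region"], kind="mergesort")
    out.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def read_regions(path: str | Path, delimiter: str = ",") -> RegionTable:
    """Read region metadata (region, name, parent_region, population)."""
    return RegionTable(pd.read_csv(path, delimiter=delimiter, encoding="utf-8", dtype={"region": str, "parent_region": str}))


def read_mapping(path: str | Path, delimiter: str = ",") -> dict[str, str]:
    """Read a fine-region -> coarse-region aggregation map from a two-column
    CSV (fine_region, coarse_region)."""
    df = pd.read_csv(path, delimiter=delimiter, encoding="utf-8", dtype=str)
    for col in ("fine_region", "coarse_region"):
        if col not in df.columns:
            raise SchemaError(f"mapping file requires column '{col}'")
    if df["fine_region"].duplicated().any():
        raise SchemaError("mapping assigns some fine region twice")
    return dict(zip(df["fine_region"], df["coarse_region"]))


# -- filters ---------------------------------------------------------------


def filter_feminine(table: SurnameCountTable, suffixes: Sequence[str] = ("á",)) -> SurnameCountTable:
    """Drop surnames ending in any of the given suffixes.

    Czech feminine surname derivatives almost always end in "-á"
    (Novák/Nováková), and male and female variants share nearly identical
    spatial distributions, so one form suffices.  The filter is purely
    orthographic — it inspects the final characters of the name.
    """
    if not suffixes:
        raise ValidationError("suffix list must be non-empty")
    mask = ~table.df["surname"].str.endswith(tuple(suffixes))
    out = SurnameCountTable(table.df.loc[mask])
    logger.info(
        "feminine-suffix filter %s: %d -> %d surnames",
        list(suffixes), table.n_surnames, out.n_surnames,
    )
    return out


def filter_min_bearers(table: SurnameCountTable, min_total: int) -> SurnameCountTable:
    """Keep surnames whose country-wide bearer total is >= ``min_total``.

    A cut of "more than 49 bearers" is therefore ``min_total=50``.  Rare
    surnames are removed because their co-occurrences are dominated by chance.
    """
    if min_total < 1:
        raise ValidationError("min_total must be >= 1")
    totals = table.surname_totals
    keep = totals.index[totals >= min_total]
    out = SurnameCountTable(table.df.loc[table.df["surname"].isin(keep)])
    logger.info(
        "min-bearers filter (>= %d): %d -> %d surnames",
        min_total, table.n_surnames, out.n_surnames,
    )
    return out


def exclude_regions(table: SurnameCountTable, region_ids: Iterable[str]) -> SurnameCountTable:
    """Drop all records in the listed regions (e.g. the largest cities, where
    chance co-occurrence adds noise).  Surnames left with no region at all
    disappear from the table; they are logged."""
    region_ids = set(map(str, region_ids))
    if not region_ids:
        return table
    kept = table.df.loc[~table.df["region"].isin(region_ids)]
    lost = set(table.df["surname"].unique()) - set(kept["surname"].unique())
    if lost:
        logger.warning(
            "excluding regions %s orphaned %d surname(s): %s",
            sorted(region_ids), len(lost), sorted(lost)[:10],
        )
    out = SurnameCountTable(kept)
    logger.info(
        "region exclusion %s: %d -> %d regions, %d -> %d surnames",
        sorted(region_ids), table.n_regions, out.n_regions,
        table.n_surnames, out.n_surnames,
    )
    return out


def aggregate_to(table: SurnameCountTable, mapping: Mapping[str, str]) -> SurnameCountTable:
    """Sum counts from fine regions into coarse regions per ``mapping``.

    Every region present in the table must be mapped; totals are conserved
    exactly (integer addition).
    """
    present = set(table.df["region"].unique())
    unmapped = present - set(map(str, mapping.keys()))
    if unmapped:
        raise MappingError(f"regions not covered by mapping: {sorted(unmapped)[:10]}")
    coarse = table.df["region"].map({str(k): str(v) for k, v in mapping.items()})
    agg = (
        table.df.assign(region=coarse)
        .groupby(["surname", "region"], as_index=False, sort=True)["count"]
        .sum()
    )
    out = SurnameCountTable(agg)
    assert out.grand_total == table.grand_total
    logger.info("aggregation: %d fine -> %d coarse regions", len(present), out.n_regions)
    return out
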