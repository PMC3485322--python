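"""Location quotients and binary concentration sets.

The location quotient of surname *i* in region *r* is

    LQ_ir = (F_ir / F_r) / (F_i / F)

where ``F_ir`` is the number of bearers of *i* in *r*, ``F_r`` the region
total, ``F_i`` the surname total and ``F`` the grand total.  LQ > 1 means the
surname is over-represented in the region relative to its national share —
we say it *concentrates* there.  The set of regions where a surname
concentrates (its concentration set) is the raw material for every pairwise
relatedness measure downstream.

Both matrices are stored sparsely: an absent entry is an exact zero (no
bearers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import UndefinedStatisticError, ValidationError
from .io_model import RegionTable, SurnameCountTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LQMatrix:
    """Sparse surname × region matrix of location quotients.

    ``values[i, r] == 0`` exactly when the surname has no bearers there.
    For each surname, the region-share-weighted mean of LQ over regions is
    identically 1 (weights = region total / grand total).
    """

    values: sparse.csr_matrix = field(repr=False)
    surnames: np.ndarray
    regions: np.ndarray
    region_weights: np.ndarray  # region share of grand total, sums to 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, surname: str) -> np.ndarray:
        idx = int(np.searchsorted(self.surnames, surname))
        if idx >= len(self.surnames) or self.surnames[idx] != surname:
            raise KeyError(surname)
        return self.values[idx].toarray().ravel()

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (surname, region, lq) frame of the stored entries."""
        coo = self.values.tocoo()
        return pd.DataFrame(
            {
                "surname": self.surnames[coo.row],
                "region": self.regions[coo.col],
                "lq": coo.data,
            }
        ).sort_values(["surname", "region"], ignore_index=True, kind="mergesort")


@dataclass(frozen=True)
class ConcentrationMatrix:
    """Boolean surname × region indicator of LQ strictly above a threshold.

    Each surname's concentration set is necessarily a subset of the regions
    where it has at least one bearer.
    """

    indicator: sparse.csr_matrix = field(repr=False)  # int8 0/1
    surnames: np.ndarray
    regions: np.ndarray
    threshold: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.indicator.shape

    @property
    def set_sizes(self) -> np.ndarray:
        """|A_i| for every surname, in row order."""
        return np.asarray(self.indicator.sum(axis=1)).ravel().astype(np.int64)

    def concentration_set(self, surname: str) -> set[str]:
        idx = int(np.searchsorted(self.surnames, surname))
        if idx >= len(self.surnames) or self.surnames[idx] != surname:
            raise KeyError(surname)
        row = self.indicator.getrow(idx)
        return {str(r) for r in self.regions[row.indices]}

    def to_dataframe(self) -> pd.DataFrame:
        coo = self.indicator.tocoo()
        return pd.DataFrame(
            {"surname": self.surnames[coo.row], "region": self.regions[coo.col]}
        ).sort_values(["surname", "region"], ignore_index=True, kind="mergesort")


def location_quotients(table: SurnameCountTable) -> LQMatrix:
    """Compute LQ for every (surname, region) with at least one bearer.

    Reference totals are taken over the table as given, i.e. after whatever
    filtering produced it.  Regions with zero total cannot occur (the table
    only stores positive counts).
    """
    if len(table) == 0:
        raise ValidationError("cannot compute location quotients of an empty table")
    counts, surnames, regions = table.to_matrix()
    f_i = np.asarray(counts.sum(axis=1)).ravel().astype(np.float64)  # surname totals
    f_r = np.asarray(counts.sum(axis=0)).ravel().astype(np.float64)  # region totals
    grand = f_i.sum()
    # LQ_ir = F_ir * F / (F_r * F_i): scale rows by F/F_i and columns by 1/F_r
    coo = counts.tocoo()
    data = coo.data * grand / (f_r[coo.col] * f_i[coo.row])
    lq = sparse.coo_matrix((data, (coo.row, coo.col)), shape=counts.shape).tocsr()
    return LQMatrix(
        values=lq,
        surnames=surnames,
        regions=regions,
        region_weights=f_r / grand,
    )


def concentration_sets(lq: LQMatrix, threshold: float = 1.0) -> ConcentrationMatrix:
    """Binarize an LQ matrix with a strict comparison ``LQ > threshold``.

    Surnames whose concentration set comes out empty are retained (they simply
    contribute zeros to every pairwise measure); their number is logged.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    coo = lq.values.tocoo()
    keep = coo.data > threshold
    ind = sparse.coo_matrix(
        (np.ones(keep.sum(), dtype=np.int8), (coo.row[keep], coo.col[keep])),
        shape=lq.shape,
    ).tocsr()
    n_empty = int((np.asarray(ind.sum(axis=1)).ravel() == 0).sum())
    if n_empty:
        logger.info("%d surname(s) have an empty concentration set at LQ > %g", n_empty, threshold)
    return ConcentrationMatrix(indicator=ind, surnames=lq.surnames, regions=lq.regions, threshold=float(threshold))


def max_lq_region(
    lq: LQMatrix,
    regions: RegionTable | None = None,
    counts: SurnameCountTable | None = None,
    attribute_to_parent: bool = False,
) -> dict[str, str]:
    """Attribute each surname to the region of its maximum LQ.

    Ties are broken by the larger bearer count in the tied regions (requires
    ``counts``), then by lexicographic region id — deterministic and
    data-driven.  With ``attribute_to_parent`` the arg-max region is then
    mapped to its parent (e.g. administrative NUTS 3 region), which is how
    nodes are usually coloured in surname-space maps.  Surnames with an
    all-zero LQ row get the attribution ``"none"``.
    """
    parent: dict[str, str] = {}
    if attribute_to_parent:
        if regions is None:
            raise ValidationError("parent-level attribution requires a region table")
        parent = regions.parent_of()
        missing = set(lq.regions) - set(parent)
        if missing:
            raise ValidationError(
                f"parent_region undefined for region(s): {sorted(missing)[:5]}"
            )
    count_lookup: dict[tuple[int, int], int] = {}
    if counts is not None:
        mat, s_lbl, r_lbl = counts.to_matrix()
        if list(s_lbl) == list(lq.surnames) and list(r_lbl) == list(lq.regions):
            ccoo = mat.tocoo()
            count_lookup = {(i, j): int(v) for i, j, v in zip(ccoo.row, ccoo.col, ccoo.data)}

    out: dict[str, str] = {}
    for i, surname in enumerate(lq.surnames):
        row = lq.values.getrow(i)
        if row.nnz == 0:
            out[surname] = "none"
            continue
        best = row.data.max()
        tied_cols = row.indices[np.isclose(row.data, best, rtol=0, atol=0)]
        if len(tied_cols) > 1:
            tied_cols = sorted(
                tied_cols,
                key=lambda c: (-count_lookup.get((i, int(c)), 0), str(lq.regions[c])),
            )
        col = int(tied_cols[0])
        region = str(lq.regions[col])
        out[surname] = parent.get(region, region) if attribute_to_parent else region
    return out


def group_concentration_share(
    conc: ConcentrationMatrix, group: set[str] | list[str], region: str
) -> float:
    """Fraction of a surname group concentrated in one region.

    This is the statistic behind community "concentration maps": a value of
    1.0 means every surname in the group has LQ above threshold in that
    region.
    """
    group = list(dict.fromkeys(group))
    if not group:
        raise ValidationError("group must be non-empty")
    region_idx = int(np.searchsorted(conc.regions, region))
    if region_idx >= len(conc.regions) or conc.regions[region_idx] != region:
        raise UndefinedStatisticError(f"region {region!r} not in universe")
    s_index = pd.Index(conc.surnames)
    rows = s_index.get_indexer(group)
    if (rows < 0).any():
        unknown = [g for g, r in zip(group, rows) if r < 0]
        raise UndefinedStatisticError(f"surname(s) not in universe: {unknown[:5]}")
    col = conc.indicator[:, region_idx].toarray().ravel()
    return float(col[rows].sum() / len(group))
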