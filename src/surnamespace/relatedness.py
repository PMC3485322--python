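"""Pairwise revealed-relatedness measures between surnames.

Two surnames are deemed related to the extent that they concentrate in the
same regions.  With ``A_i`` the concentration set of surname *i*:

* Jaccard:            ``J_ij = |A_i ∩ A_j| / |A_i ∪ A_j|``
* conditional Dice:   ``D_{i|j} = |A_i ∩ A_j| / |A_j|`` — the probability
  that *i* concentrates in a region given that *j* does;
* symmetric Dice:     ``D_ij = min(D_{i|j}, D_{j|i}) = |A_i ∩ A_j| / max(|A_i|, |A_j|)``.

Both symmetric measures live in [0, 1], reach 1 exactly when the two sets are
identical and non-empty, and satisfy ``J_ij <= D_ij`` because
``|A ∪ B| >= max(|A|, |B|)``.

The full pairwise matrix is extremely sparse in practice (most pairs share no
region), so only non-zero values are materialized.  Intersection counts are
computed as a boolean matrix product of the concentration matrix with its
transpose, evaluated in surname blocks so peak memory is bounded; the result
is identical to a per-pair set intersection regardless of block size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import sparse

from .concentration import ConcentrationMatrix
from .errors import LookupError_, UndefinedStatisticError, ValidationError

logger = logging.getLogger(__name__)


class LinkRecord(NamedTuple):
    """One undirected relatedness link; the pair is stored in lexicographic
    order so that a link set has a canonical representation."""

    surname_i: str
    surname_j: str
    value: float


@dataclass(frozen=True)
class ProximityMatrix:
    """Sparse symmetric surname × surname matrix of relatedness values.

    Only strictly positive values are stored, once per unordered pair
    (``i < j`` as row indices into ``surnames``).  The diagonal
    (self-relatedness) is undefined and never stored.
    """

    surnames: np.ndarray
    i: np.ndarray = field(repr=False)  # int row indices, i < j
    j: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    measure: str  # "jaccard" | "dice_sym"
    concentration_threshold: float
    n_regions: int

    def __post_init__(self) -> None:
        if len(self.i) and not (self.i < self.j).all():
            raise ValidationError("pair indices must satisfy i < j")

    @property
    def n_surnames(self) -> int:
        return len(self.surnames)

    @property
    def n_stored(self) -> int:
        return len(self.values)

    @property
    def max_value(self) -> float:
        return float(self.values.max()) if len(self.values) else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (surname_i, surname_j, value), canonical pair order,
        sorted by descending value then pair labels."""
        df = pd.DataFrame(
            {
                "surname_i": self.surnames[self.i],
                "surname_j": self.surnames[self.j],
                "value": self.values,
            }
        )
        swap = df["surname_i"] > df["surname_j"]
        df.loc[swap, ["surname_i", "surname_j"]] = df.loc[
            swap, ["surname_j", "surname_i"]
        ].to_numpy()
        return df.sort_values(
            ["value", "surname_i", "surname_j"],
            ascending=[False, True, True],
            ignore_index=True,
            kind="mergesort",
        )

    def links(self) -> list[LinkRecord]:
        return [
            LinkRecord(r.surname_i, r.surname_j, float(r.value))
            for r in self.to_dataframe().itertuples(index=False)
        ]

    def get(self, a: str, b: str) -> float:
        """Stored value for an unordered pair (0.0 if unstored)."""
        index = pd.Index(self.surnames)
        ia, ib = index.get_indexer([a, b])
        if ia < 0 or ib < 0:
            raise LookupError_(f"unknown surname in pair ({a!r}, {b!r})")
        lo, hi = min(ia, ib), max(ia, ib)
        mask = (self.i == lo) & (self.j == hi)
        return float(self.values[mask][0]) if mask.any() else 0.0


def _pair_arrays(
    conc: ConcentrationMatrix, block_size: int = 2048
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangular (i, j, |A_i ∩ A_j|) for all pairs with non-empty
    intersection, via block-wise sparse matrix products."""
    B = conc.indicator.astype(np.int32).tocsr()
    n = B.shape[0]
    rows, cols, inters = [], [], []
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        prod = (B[start:stop] @ B.T).tocoo()
        gi = prod.row + start
        keep = prod.col > gi  # strict upper triangle, excludes diagonal
        rows.append(gi[keep])
        cols.append(prod.col[keep])
        inters.append(prod.data[keep])
    if not rows:
        empty = np.array([], dtype=np.int64)
        return empty, empty.copy(), empty.copy()
    return (
        np.concatenate(rows).astype(np.int64),
        np.concatenate(cols).astype(np.int64),
        np.concatenate(inters).astype(np.int64),
    )


def jaccard_all(conc: ConcentrationMatrix, block_size: int = 2048) -> ProximityMatrix:
    """All pairwise Jaccard values J_ij = |A_i ∩ A_j| / |A_i ∪ A_j|.

    Pairs with empty intersection (including any pair involving an empty
    concentration set) have J = 0 and are not stored.
    """
    if conc.shape[0] < 2:
        raise ValidationError("need at least 2 surnames")
    i, j, inter = _pair_arrays(conc, block_size)
    sizes = conc.set_sizes
    union = sizes[i] + sizes[j] - inter
    values = inter / union
    order = np.lexsort((j, i))
    return ProximityMatrix(
        surnames=conc.surnames,
        i=i[order],
        j=j[order],
        values=values[order],
        measure="jaccard",
        concentration_threshold=conc.threshold,
        n_regions=conc.shape[1],
    )


def dice_symmetric_all(conc: ConcentrationMatrix, block_size: int = 2048) -> ProximityMatrix:
    """All pairwise symmetric Dice values D_ij = |A_i ∩ A_j| / max(|A_i|, |A_j|),
    i.e. the smaller of the two conditional co-concentration probabilities."""
    if conc.shape[0] < 2:
        raise ValidationError("need at least 2 surnames")
    i, j, inter = _pair_arrays(conc, block_size)
    sizes = conc.set_sizes
    values = inter / np.maximum(sizes[i], sizes[j])
    order = np.lexsort((j, i))
    return ProximityMatrix(
        surnames=conc.surnames,
        i=i[order],
        j=j[order],
        values=values[order],
        measure="dice_sym",
        concentration_threshold=conc.threshold,
        n_regions=conc.shape[1],
    )


def dice_conditional(conc: ConcentrationMatrix, i: str, j: str) -> float:
    """D_{i|j} = |A_i ∩ A_j| / |A_j|: the probability that surname ``i``
    concentrates in a region given that ``j`` concentrates there.

    Undefined (raises) when ``A_j`` is empty — the scalar form favours
    correctness where the matrix form favours sparsity.
    """
    a_i = conc.concentration_set(i)
    a_j = conc.concentration_set(j)
    if not a_j:
        raise UndefinedStatisticError(
            f"D_{{i|j}} undefined: surname {j!r} has an empty concentration set"
        )
    return len(a_i & a_j) / len(a_j)


def pair_count(n_surnames: int, ordered: bool = False) -> int:
    """Number of surname pairs: n(n-1)/2 unordered (default), n(n-1) ordered."""
    if n_surnames < 2:
        raise ValidationError("need at least 2 surnames")
    n = int(n_surnames)
    return n * (n - 1) if ordered else n * (n - 1) // 2


def top_links(
    prox: ProximityMatrix,
    mode: str,
    param: float | int,
) -> list[LinkRecord]:
    """Select the strongest links.

    mode="threshold"       keep values >= param (the threshold *d*);
    mode="top_k"           keep the param highest values, including every
                           value tied at the cut (so more than K may return);
    mode="fraction_of_max" keep values >= param * max stored value.
    """
    if prox.n_stored == 0:
        return []
    df = prox.to_dataframe()
    if mode == "threshold":
        cut = float(param)
    elif mode == "fraction_of_max":
        if not (0 < param <= 1):
            raise ValidationError("fraction_of_max param must be in (0, 1]")
        cut = float(param) * prox.max_value
    elif mode == "top_k":
        k = int(param)
        if k <= 0:
            raise ValidationError("top_k param must be positive")
        if k >= len(df):
            cut = float(df["value"].min())
        else:
            cut = float(df["value"].iloc[k - 1])
            n_at_cut = int((df["value"] >= cut).sum())
            if n_at_cut > k:
                logger.info("top_k: %d ties at the cut, returning %d links", n_at_cut - k, n_at_cut)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    sel = df.loc[df["value"] >= cut]
    return [LinkRecord(r.surname_i, r.surname_j, float(r.value)) for r in sel.itertuples(index=False)]


def rank_size(prox: ProximityMatrix, floor: float = 0.0) -> pd.DataFrame:
    """Rank-size table of stored values >= ``floor``: ranks 1..n, values
    descending.  Used to eyeball where the heavy-tailed distribution of
    relatedness values flattens, i.e. to choose the network threshold."""
    vals = np.sort(prox.values[prox.values >= floor])[::-1]
    return pd.DataFrame({"rank": np.arange(1, len(vals) + 1), "value": vals})


def compare_link_sets(prox_a: ProximityMatrix, prox_b: ProximityMatrix, k: int) -> float:
    """Jaccard overlap of the surname sets incident to each matrix's top-K
    links.  Used to check that Jaccard- and Dice-based spaces highlight
    largely the same names."""
    if k <= 0:
        raise ValidationError("K must be positive")
    if list(prox_a.surnames) != list(prox_b.surnames):
        raise ValidationError("matrices must share the same surname universe")

    def incident(prox: ProximityMatrix) -> set[str]:
        names: set[str] = set()
        for rec in top_links(prox, "top_k", k):
            names.add(rec.surname_i)
            names.add(rec.surname_j)
        return names

    sa, sb = incident(prox_a), incident(prox_b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def nearest_neighbours(prox: ProximityMatrix, surname: str, k: int = 1) -> list[tuple[str, float]]:
    """The k partners with the highest relatedness to ``surname``, descending;
    ties broken lexicographically by partner name."""
    index = pd.Index(prox.surnames)
    idx = index.get_indexer([surname])[0]
    if idx < 0:
        raise LookupError_(f"unknown surname {surname!r}")
    mask_i = prox.i == idx
    mask_j = prox.j == idx
    partners = np.concatenate([prox.j[mask_i], prox.i[mask_j]])
    vals = np.concatenate([prox.values[mask_i], prox.values[mask_j]])
    if len(partners) == 0:
        return []
    names = prox.surnames[partners]
    order = np.lexsort((names, -vals))
    return [(str(names[o]), float(vals[o])) for o in order[:k]]
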