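"""Shared fixtures: small hand-checkable surname tables and random-instance
generators used by the oracle-equivalence and property tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from surnamespace import SurnameCountTable
from surnamespace.concentration import ConcentrationMatrix


def make_table(rows: list[tuple[str, str, int]]) -> SurnameCountTable:
    return SurnameCountTable(
        pd.DataFrame(rows, columns=["surname", "region", "count"])
    )


@pytest.fixture
def two_by_two() -> SurnameCountTable:
    """Counts [[8, 2], [2, 8]]: LQ of surname A in region r1 is
    (8/10)/(10/20) = 1.6 by direct evaluation."""
    return make_table([("A", "r1", 8), ("A", "r2", 2), ("B", "r1", 2), ("B", "r2", 8)])


def conc_from_sets(sets: dict[str, set[str]], regions: list[str], threshold: float = 1.0) -> ConcentrationMatrix:
    """Build a ConcentrationMatrix directly from explicit concentration sets."""
    surnames = np.array(sorted(sets))
    region_arr = np.array(sorted(regions))
    r_index = {r: k for k, r in enumerate(region_arr)}
    rows, cols = [], []
    for i, s in enumerate(surnames):
        for r in sets[s]:
            rows.append(i)
            cols.append(r_index[r])
    ind = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(surnames), len(region_arr)),
    ).tocsr()
    return ConcentrationMatrix(indicator=ind, surnames=surnames, regions=region_arr, threshold=threshold)


def random_conc(rng: np.random.Generator, n_surnames: int, n_regions: int, density: float = 0.3) -> ConcentrationMatrix:
    """Random boolean concentration matrix for oracle-equivalence tests."""
    mat = (rng.random((n_surnames, n_regions)) < density).astype(np.int8)
    surnames = np.array([f"S{i:04d}" for i in range(n_surnames)])
    regions = np.array([f"R{j:03d}" for j in range(n_regions)])
    return ConcentrationMatrix(
        indicator=sparse.csr_matrix(mat), surnames=surnames, regions=regions, threshold=1.0
    )


def random_table(rng: np.random.Generator, n_surnames: int, n_regions: int) -> SurnameCountTable:
    """Random positive count table: every surname gets bearers in a random
    non-empty subset of regions."""
    rows = []
    for i in range(n_surnames):
        k = rng.integers(1, n_regions + 1)
        regs = rng.choice(n_regions, size=k, replace=False)
        for r in regs:
            rows.append((f"S{i:04d}", f"R{r:03d}", int(rng.integers(1, 200))))
    return make_table(rows)


# --- hand-countable two-stage pipeline fixture -----------------------------
#
# Fine regions r1..r6 aggregate pairwise into coarse c1..c3.  Two planted
# pairs (Alpha, Beta) -> block c1 and (Gamma, Delta) -> block c2, one
# ubiquitous surname, one rare surname (filtered at min 5 bearers), one
# feminine form (filtered by suffix).
PIPELINE_ROWS: list[tuple[str, str, int]] = [
    ("Alpha", "r1", 10), ("Alpha", "r2", 10),
    ("Beta", "r1", 8), ("Beta", "r2", 8), ("Beta", "r3", 2),
    ("Gamma", "r3", 10), ("Gamma", "r4", 10),
    ("Delta", "r3", 8), ("Delta", "r4", 8), ("Delta", "r5", 2),
    ("Ubiq", "r1", 5), ("Ubiq", "r2", 5), ("Ubiq", "r3", 5),
    ("Ubiq", "r4", 5), ("Ubiq", "r5", 5), ("Ubiq", "r6", 5),
    ("Rare", "r1", 3),
    ("Nováková", "r1", 20),
]

PIPELINE_MAPPING = {"r1": "c1", "r2": "c1", "r3": "c2", "r4": "c2", "r5": "c3", "r6": "c3"}


@pytest.fixture
def pipeline_fixture(tmp_path):
    """Write the toy fixture to disk and return (counts_path, mapping_path)."""
    counts = tmp_path / "counts.csv"
    pd.DataFrame(PIPELINE_ROWS, columns=["surname", "region", "count"]).to_csv(
        counts, index=False, encoding="utf-8"
    )
    mapping = tmp_path / "mapping.csv"
    pd.DataFrame(
        sorted(PIPELINE_MAPPING.items()), columns=["fine_region", "coarse_region"]
    ).to_csv(mapping, index=False, encoding="utf-8")
    return counts, mapping
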