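"""Pairwise revealed-relatedness measures checked against an independent
per-pair set-algebra oracle, plus ranking/threshold/lookup utilities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surnamespace import (
    compare_link_sets,
    dice_conditional,
    dice_symmetric_all,
    jaccard_all,
    nearest_neighbours,
    pair_count,
    rank_size,
    top_links,
)
from surnamespace.errors import LookupError_, UndefinedStatisticError, ValidationError

from conftest import conc_from_sets, random_conc


def oracle_pairs(conc):
    """Naive oracle: J and D for every pair by explicit set algebra."""
    sets = {s: conc.concentration_set(s) for s in conc.surnames}
    out = {}
    for a, b in itertools.combinations(sorted(sets), 2):
        inter = len(sets[a] & sets[b])
        union = len(sets[a] | sets[b])
        j = inter / union if union else 0.0
        d = inter / max(len(sets[a]), len(sets[b])) if inter else 0.0
        out[(a, b)] = (j, d)
    return out


def stored(prox):
    return {
        (min(a, b), max(a, b)): v
        for a, b, v in zip(
            prox.surnames[prox.i], prox.surnames[prox.j], prox.values
        )
    }


class TestJaccard:
    def test_identical_sets(self):
        conc = conc_from_sets({"A": {"r1", "r2"}, "B": {"r1", "r2"}}, ["r1", "r2", "r3"])
        assert stored(jaccard_all(conc))[("A", "B")] == 1.0

    def test_disjoint_sets_unstored(self):
        conc = conc_from_sets({"A": {"r1"}, "B": {"r2"}}, ["r1", "r2"])
        assert stored(jaccard_all(conc)) == {}

    def test_set_algebra_example(self):
        conc = conc_from_sets(
            {"A": {"r1", "r2", "r3"}, "B": {"r2", "r3", "r4"}}, ["r1", "r2", "r3", "r4"]
        )
        assert stored(jaccard_all(conc))[("A", "B")] == pytest.approx(2 / 4)

    def test_needs_two_surnames(self):
        with pytest.raises(ValidationError):
            jaccard_all(conc_from_sets({"A": {"r1"}}, ["r1"]))


class TestDice:
    def test_conditional_containment(self):
        conc = conc_from_sets({"A": {"r1", "r2", "r3"}, "B": {"r1", "r2"}}, ["r1", "r2", "r3"])
        assert dice_conditional(conc, "A", "B") == 1.0

    def test_conditional_half(self):
        conc = conc_from_sets(
            {"A": {"r1", "r2", "r5"}, "B": {"r1", "r2", "r3", "r4"}},
            ["r1", "r2", "r3", "r4", "r5"],
        )
        assert dice_conditional(conc, "A", "B") == pytest.approx(2 / 4)

    def test_conditional_undefined_on_empty_set(self):
        conc = conc_from_sets({"A": {"r1"}, "B": set()}, ["r1", "r2"])
        with pytest.raises(UndefinedStatisticError):
            dice_conditional(conc, "A", "B")

    def test_symmetric_identical(self):
        conc = conc_from_sets({"A": {"r1", "r2"}, "B": {"r1", "r2"}}, ["r1", "r2"])
        assert stored(dice_symmetric_all(conc))[("A", "B")] == 1.0

    def test_symmetric_min_of_conditionals(self):
        # |A|=3, |B|=4, intersection 2: min(2/4, 2/3) = 0.5
        conc = conc_from_sets(
            {"A": {"r1", "r2", "r5"}, "B": {"r1", "r2", "r3", "r4"}},
            ["r1", "r2", "r3", "r4", "r5"],
        )
        assert stored(dice_symmetric_all(conc))[("A", "B")] == pytest.approx(0.5)
        assert stored(dice_symmetric_all(conc))[("A", "B")] == pytest.approx(
            min(dice_conditional(conc, "A", "B"), dice_conditional(conc, "B", "A"))
        )

    def test_symmetric_subset(self):
        # |A|=2 inside |B|=8: 2/8 = 0.25
        regions = [f"r{i}" for i in range(8)]
        conc = conc_from_sets({"A": {"r0", "r1"}, "B": set(regions)}, regions)
        assert stored(dice_symmetric_all(conc))[("A", "B")] == pytest.approx(0.25)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_match_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        conc = random_conc(rng, int(rng.integers(3, 60)), int(rng.integers(2, 30)))
        expect = oracle_pairs(conc)
        got_j = stored(jaccard_all(conc))
        got_d = stored(dice_symmetric_all(conc))
        for pair, (j, d) in expect.items():
            assert got_j.get(pair, 0.0) == j
            assert got_d.get(pair, 0.0) == d

    @pytest.mark.parametrize("block_size", [1, 3, 7, 1000])
    def test_block_size_does_not_change_results(self, block_size):
        rng = np.random.default_rng(42)
        conc = random_conc(rng, 40, 12)
        ref_j = stored(jaccard_all(conc))
        ref_d = stored(dice_symmetric_all(conc))
        assert stored(jaccard_all(conc, block_size=block_size)) == ref_j
        assert stored(dice_symmetric_all(conc, block_size=block_size)) == ref_d

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_inequalities_and_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        conc = random_conc(rng, int(rng.integers(3, 40)), int(rng.integers(2, 15)))
        sets = {s: conc.concentration_set(s) for s in conc.surnames}
        got_j = stored(jaccard_all(conc))
        got_d = stored(dice_symmetric_all(conc))
        for pair in set(got_j) | set(got_d):
            j, d = got_j.get(pair, 0.0), got_d.get(pair, 0.0)
            assert 0 <= j <= d <= 1
            a, b = sets[pair[0]], sets[pair[1]]
            assert d == len(a & b) / max(len(a), len(b))
            if j == 1.0:
                assert a == b and a  # J = D = 1 iff identical non-empty sets
                assert d == 1.0

    def test_region_relabeling_leaves_values_unchanged(self):
        rng = np.random.default_rng(5)
        conc = random_conc(rng, 20, 10)
        relabeled = conc_from_sets(
            {
                s: {f"z{r}" for r in conc.concentration_set(s)}
                for s in conc.surnames
            },
            [f"z{r}" for r in conc.regions],
        )
        assert stored(dice_symmetric_all(conc)) == stored(dice_symmetric_all(relabeled))

    def test_adding_shared_region_increases_measures(self):
        before = conc_from_sets({"A": {"r1", "r2"}, "B": {"r2", "r3"}}, ["r1", "r2", "r3", "r4"])
        after = conc_from_sets(
            {"A": {"r1", "r2", "r4"}, "B": {"r2", "r3", "r4"}}, ["r1", "r2", "r3", "r4"]
        )
        j0 = stored(jaccard_all(before))[("A", "B")]
        j1 = stored(jaccard_all(after))[("A", "B")]
        d0 = stored(dice_symmetric_all(before))[("A", "B")]
        d1 = stored(dice_symmetric_all(after))[("A", "B")]
        assert j1 > j0 and d1 >= d0


class TestPairCount:
    def test_reference_unordered_count(self):
        assert pair_count(15487) == 119_915_841

    def test_smallest(self):
        assert pair_count(2) == 1

    def test_ordered(self):
        assert pair_count(5660, ordered=True) == 32_029_940

    def test_too_few(self):
        with pytest.raises(ValidationError):
            pair_count(1)


class TestTopLinksAndRanking:
    @pytest.fixture
    def prox(self):
        conc = conc_from_sets(
            {
                "A": {"r1", "r2", "r3", "r4"},
                "B": {"r1", "r2", "r3", "r4"},  # A-B = 1.0
                "C": {"r1", "r2", "r3", "r5"},  # A-C, B-C = 3/4 (dice)
                "D": {"r1", "r5", "r6", "r7"},
            },
            [f"r{i}" for i in range(1, 8)],
        )
        return dice_symmetric_all(conc)

    def test_threshold_keeps_at_or_above(self, prox):
        links = top_links(prox, "threshold", 0.75)
        assert {(l.surname_i, l.surname_j) for l in links} == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_top_k_larger_than_link_count(self, prox):
        assert len(top_links(prox, "top_k", 1000)) == prox.n_stored

    def test_top_k_includes_ties_at_cut(self, prox):
        links = top_links(prox, "top_k", 2)  # values 1.0, 0.75, 0.75, ...
        assert len(links) == 3

    def test_fraction_of_max(self):
        # max D = 7/8 = 0.875, so fraction 0.5 cuts at 0.4375
        regions = [f"r{i}" for i in range(1, 11)]
        conc = conc_from_sets(
            {
                "A": {f"r{i}" for i in range(1, 9)},
                "B": {f"r{i}" for i in range(1, 8)} | {"r9"},
                "C": {"r1", "r9", "r10"},
            },
            regions,
        )
        prox = dice_symmetric_all(conc)
        assert prox.max_value == pytest.approx(0.875)
        links = top_links(prox, "fraction_of_max", 0.5)
        assert {(l.surname_i, l.surname_j) for l in links} == {("A", "B")}
        assert all(l.value >= 0.4375 for l in links)

    def test_rank_size_floor_and_order(self, prox):
        rs = rank_size(prox, floor=0.5)
        assert list(rs["rank"]) == list(range(1, len(rs) + 1))
        assert (rs["value"].diff().dropna() <= 0).all()
        assert (rs["value"] >= 0.5).all()

    def test_rank_size_empty_after_floor(self, prox):
        assert len(rank_size(prox, floor=2.0)) == 0


class TestCompareLinkSets:
    def test_identical_matrices(self):
        rng = np.random.default_rng(0)
        conc = random_conc(rng, 20, 10)
        prox = dice_symmetric_all(conc)
        assert compare_link_sets(prox, prox, 10) == 1.0

    def test_hand_example(self):
        # top-1 link incident sets {A, B} vs {A, C} -> overlap 1/3
        conc1 = conc_from_sets(
            {"A": {"r1"}, "B": {"r1"}, "C": {"r2"}}, ["r1", "r2", "r3"]
        )
        conc2 = conc_from_sets(
            {"A": {"r2"}, "B": {"r3"}, "C": {"r2"}}, ["r1", "r2", "r3"]
        )
        val = compare_link_sets(jaccard_all(conc1), jaccard_all(conc2), 1)
        assert val == pytest.approx(1 / 3)

    def test_k_must_be_positive(self):
        rng = np.random.default_rng(0)
        prox = dice_symmetric_all(random_conc(rng, 5, 5))
        with pytest.raises(ValidationError):
            compare_link_sets(prox, prox, 0)


class TestNearestNeighbours:
    @pytest.fixture
    def prox(self):
        conc = conc_from_sets(
            {
                "Vlček": {"r1", "r2"},
                "Wolf": {"r1", "r2"},
                "Novák": {"r1", "r3"},
                "Alone": {"r9"},
            },
            [f"r{i}" for i in range(1, 10)],
        )
        return dice_symmetric_all(conc)

    def test_argmax_partner(self, prox):
        assert nearest_neighbours(prox, "Vlček", 1) == [("Wolf", 1.0)]

    def test_no_links_gives_empty(self, prox):
        assert nearest_neighbours(prox, "Alone", 3) == []

    def test_tie_broken_lexicographically(self):
        conc = conc_from_sets(
            {"X": {"r1", "r2"}, "B": {"r1", "r2"}, "A": {"r1", "r2"}},
            ["r1", "r2"],
        )
        prox = dice_symmetric_all(conc)
        assert nearest_neighbours(prox, "X", 1) == [("A", 1.0)]

    def test_unknown_surname(self, prox):
        with pytest.raises(LookupError_):
            nearest_neighbours(prox, "Ghost", 1)
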