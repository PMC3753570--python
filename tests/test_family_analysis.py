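from fractions import Fraction
from itertools import combinations

import numpy as np

from logicfam import (
    EnumerationConfig,
    LogicModel,
    enumerate_family,
    hyperedge_frequencies,
    mutually_exclusive_pairs,
    mutually_inclusive_groups,
    score,
    swap_effect,
)
from logicfam.analysis import ExclusivePair
from logicfam.enumeration import ModelFamily
from logicfam.model import Score


def family_from_masks(hg, masks, dataset=None, precision=2):
    """Assemble a ModelFamily directly from bitmasks (scores recomputed)."""
    models = [LogicModel(m, hg) for m in masks]
    if dataset is not None:
        scores = [score(m, dataset, precision=precision) for m in models]
    else:
        scores = [Score(0, 1, m.size, precision) for m in models]
    mse_opt = min(s.mse for s in scores)
    size_opt = min(s.size for s in scores if s.mse == mse_opt)
    return ModelFamily(hg, models, scores, mse_opt, size_opt, EnumerationConfig(size_bound=99))


class TestFrequencies:
    def test_single_model_family(self, toy1):
        fam = family_from_masks(toy1["hg"], [toy1["truth"].mask], toy1["dataset"])
        rep = hyperedge_frequencies(fam)
        for h in toy1["hg"].hyperedges:
            expected = 1 if h.id in toy1["truth"].selected_ids else 0
            assert rep.frequencies[h.id] == expected

    def test_direct_count(self, toy1):
        # family {{e1,e3},{e2,e3}} -> e3: 1, e1: 1/2, e2: 1/2
        hg = toy1["hg"]
        fam = family_from_masks(hg, [0b1010, 0b1100])
        rep = hyperedge_frequencies(fam)
        assert rep.frequencies[3] == 1
        assert rep.frequencies[1] == rep.frequencies[2] == Fraction(1, 2)
        assert rep.frequencies[0] == 0

    def test_partition_covers_all_hyperedges(self, toy1, toy1_noisy):
        fam = enumerate_family(
            toy1["hg"], toy1_noisy, EnumerationConfig(fit_tolerance=0.10, size_bound=10)
        )
        rep = hyperedge_frequencies(fam)
        ids = set(rep.always) | set(rep.never) | set(rep.variable)
        assert ids == set(range(toy1["hg"].n_hyperedges))
        assert not (set(rep.always) & set(rep.never))

    def test_bookkeeping_identity(self, toy1, toy1_noisy):
        # sum of frequencies == mean selected-gate count
        fam = enumerate_family(
            toy1["hg"], toy1_noisy, EnumerationConfig(fit_tolerance=0.10, size_bound=10)
        )
        rep = hyperedge_frequencies(fam)
        total = sum(rep.frequencies, Fraction(0))
        mean_gates = Fraction(sum(len(m.selected_ids) for m in fam), len(fam))
        assert total == mean_gates


class TestInclusiveGroups:
    def test_equivalence_classes(self, toy1):
        hg = toy1["hg"]
        fam = family_from_masks(hg, [0b1010, 0b1100])
        groups = {g for g in map(frozenset, mutually_inclusive_groups(fam))}
        # e1 and e2 have distinct columns; e3 is always present like nothing else;
        # e0, e4, e5 are always absent together
        assert frozenset({1}) in groups and frozenset({2}) in groups
        assert frozenset({3}) in groups
        assert frozenset({0, 4, 5}) in groups

    def test_groups_partition_hyperedges(self, toy1, toy1_noisy):
        fam = enumerate_family(
            toy1["hg"], toy1_noisy, EnumerationConfig(fit_tolerance=0.10, size_bound=10)
        )
        groups = mutually_inclusive_groups(fam)
        flat = sorted(i for g in groups for i in g)
        assert flat == list(range(toy1["hg"].n_hyperedges))


class TestExclusivePairs:
    def test_by_definition_example(self, toy1):
        hg = toy1["hg"]
        fam = family_from_masks(hg, [0b1010, 0b1100])
        pairs = mutually_exclusive_pairs(fam)
        assert [(p.group_a, p.group_b) for p in pairs] == [((1,), (2,))]
        assert pairs[0].freq_a == pairs[0].freq_b == Fraction(1, 2)

    def test_always_present_gate_not_paired(self, toy1):
        # family {{e1},{e1,e2}}: e1 always present, e2 sometimes -> no pair
        fam = family_from_masks(toy1["hg"], [0b0010, 0b0110])
        assert mutually_exclusive_pairs(fam) == []

    def test_matches_cooccurrence_brute_force(self, toy1, toy1_noisy):
        fam = enumerate_family(
            toy1["hg"], toy1_noisy, EnumerationConfig(fit_tolerance=0.10, size_bound=10)
        )
        pm = fam.presence_matrix()
        reported = {
            (p.group_a, p.group_b) for p in mutually_exclusive_pairs(fam)
        }
        # exhaustive co-occurrence: group representatives with complementary columns
        groups = mutually_inclusive_groups(fam)
        expected = set()
        for ga, gb in combinations(groups, 2):
            ca, cb = pm[:, ga[0]], pm[:, gb[0]]
            if np.all(ca + cb == 1) and 0 < ca.sum() < len(fam):
                expected.add(tuple(sorted((ga, gb))))
        assert {tuple(sorted(p)) for p in reported} == expected

    def test_verified_exactly_one_side_per_member(self, toy1, toy1_noisy):
        fam = enumerate_family(
            toy1["hg"], toy1_noisy, EnumerationConfig(fit_tolerance=0.10, size_bound=10)
        )
        for p in mutually_exclusive_pairs(fam):
            for m in fam:
                in_a = all(i in m for i in p.group_a)
                in_b = all(i in m for i in p.group_b)
                assert in_a != in_b


class TestSwapEffect:
    def test_score_equivalent_pair_has_zero_deltas(self, toy1):
        # two interchangeable gates for c on data where both fit equally
        hg = toy1["hg"]
        ds = toy1["dataset"].copy_with(values=toy1["dataset"].values.copy())
        # make c ambiguous: observed 0.5 whenever exactly one of a,b is on
        ds.values[1, 0] = 0.5
        ds.values[2, 0] = 0.5
        by = {str(h): h.id for h in hg.hyperedges}
        m_a = LogicModel.from_ids(hg, [by["+a->c"]])
        m_b = LogicModel.from_ids(hg, [by["+b->c"]])
        fam = family_from_masks(hg, [m_a.mask, m_b.mask], ds)
        pair = mutually_exclusive_pairs(fam)[0]
        recs = swap_effect(fam, pair, ds)
        assert recs and all(r.mse_delta == 0 for r in recs)

    def test_differing_condition_fraction(self, toy1):
        hg = toy1["hg"]
        ds = toy1["dataset"]
        by = {str(h): h.id for h in hg.hyperedges}
        m_a = LogicModel.from_ids(hg, [by["+a->c"]])
        m_b = LogicModel.from_ids(hg, [by["+a;+b->c"]])
        fam = family_from_masks(hg, [m_a.mask, m_b.mask], ds)
        pair = mutually_exclusive_pairs(fam)[0]
        recs = swap_effect(fam, pair, ds)
        # c = a vs c = a AND b differ only when a=1, b=0: 1 of 4 conditions
        assert [r.differing_condition_fraction for r in recs] == [Fraction(1, 4)]

    def test_deltas_match_independent_rescoring(self, toy1, toy1_noisy):
        fam = enumerate_family(
            toy1["hg"], toy1_noisy, EnumerationConfig(fit_tolerance=0.10, size_bound=10)
        )
        for pair in mutually_exclusive_pairs(fam):
            a_mask = sum(1 << i for i in pair.group_a)
            b_mask = sum(1 << i for i in pair.group_b)
            for rec in swap_effect(fam, pair, toy1_noisy):
                m = fam.models[rec.model_index]
                swapped = LogicModel((m.mask & ~a_mask) | b_mask, toy1["hg"])
                assert rec.mse_after == score(swapped, toy1_noisy).mse
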