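"""Discriminating-experiment design over a set of behaviors (GTTs).

A condition *separates* a pair of behaviors if their tables differ in at
least one readout there (undefined predictions never separate — they carry
no observable value). Finding the fewest experiments that separate every
pair is a set-cover problem over GTT pairs; alongside a provably minimum
cover (branch-and-bound), a greedy cover and single best experiments
(most pairs separated, then fewest stimulations, then fewest inhibitions)
are provided.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .behaviors import GTT

__all__ = [
    "SeparationInstance",
    "DesignResult",
    "ExperimentRanking",
    "build_separation",
    "minimal_discriminating_set",
    "best_single_experiments",
    "write_experiments_csv",
]

EXACT_CONDITION_CAP = 5000


@dataclass
class SeparationInstance:
    """Which GTT pairs each candidate condition separates."""

    gtts: Sequence[GTT]
    conditions: tuple  # condition indices considered
    pair_sets: dict  # condition index -> frozenset of (i, j) GTT pairs separated
    diff_counts: dict  # (condition, (i, j)) -> number of differing readouts
    inseparable_pairs: tuple  # pairs no candidate condition separates

    @property
    def all_pairs(self) -> frozenset:
        n = len(self.gtts)
        return frozenset(combinations(range(n), 2))

    @property
    def separable_pairs(self) -> frozenset:
        return self.all_pairs - frozenset(self.inseparable_pairs)


def build_separation(gtts: Sequence[GTT],
                     conditions: Optional[Sequence[int]] = None) -> SeparationInstance:
    """Compute the condition -> separated-pairs incidence for a GTT set."""
    if len(gtts) < 2:
        raise ValueError("need at least two GTTs to discriminate")
    ref = gtts[0]
    conds = tuple(conditions) if conditions is not None else tuple(range(ref.n_conditions))
    tables = np.stack([g.table for g in gtts])  # (G, C, R)
    pair_sets: dict = {}
    diff_counts: dict = {}
    pairs = list(combinations(range(len(gtts)), 2))
    for c in conds:
        seps = []
        for (i, j) in pairs:
            a, b = tables[i, c], tables[j, c]
            ndiff = int(np.sum((a != b) & (a >= 0) & (b >= 0)))
            if ndiff:
                seps.append((i, j))
                diff_counts[(c, (i, j))] = ndiff
        if seps:
            pair_sets[c] = frozenset(seps)
    covered = frozenset().union(*pair_sets.values()) if pair_sets else frozenset()
    inseparable = tuple(p for p in pairs if p not in covered)
    return SeparationInstance(gtts, conds, pair_sets, diff_counts, inseparable)


@dataclass
class DesignResult:
    """A discriminating experiment set with provenance of its optimality."""

    conditions: tuple  # chosen condition indices
    mode: str  # "exact" or "greedy"
    covered_pairs: frozenset
    inseparable_pairs: tuple
    greedy_size: int
    lower_bound: int
    exact: bool  # True when the size is a proven minimum

    def __len__(self):
        return len(self.conditions)


def _greedy_cover(pair_sets: dict, universe: frozenset) -> list:
    chosen: list = []
    remaining = set(universe)
    while remaining:
        best_c, best_gain = None, -1
        for c in sorted(pair_sets):
            gain = len(pair_sets[c] & remaining)
            if gain > best_gain:
                best_c, best_gain = c, gain
        if best_gain <= 0:
            break
        chosen.append(best_c)
        remaining -= pair_sets[best_c]
    return chosen


def _disjoint_pair_lower_bound(pair_sets: dict, universe: frozenset) -> int:
    # pairs whose covering-condition sets are pairwise disjoint each need their own condition
    covers: dict = {p: set() for p in universe}
    for c, ps in pair_sets.items():
        for p in ps:
            if p in covers:
                covers[p].add(c)
    used: set = set()
    bound = 0
    for p in sorted(universe, key=lambda p: (len(covers[p]), p)):
        if covers[p] and not (covers[p] & used):
            bound += 1
            used |= covers[p]
    return bound


def _exact_cover(pair_sets: dict, universe: frozenset, upper: list) -> list:
    # dominance pruning: drop conditions whose pair set is a subset of another's
    conds = sorted(pair_sets)
    kept = []
    for c in conds:
        dominated = any(
            (pair_sets[c] < pair_sets[d]) or (pair_sets[c] == pair_sets[d] and d < c)
            for d in conds
            if d != c
        )
        if not dominated:
            kept.append(c)
    psets = {c: pair_sets[c] for c in kept}

    best = list(upper)

    covers: dict = {p: [c for c in kept if p in psets[c]] for p in universe}

    def dfs(chosen, remaining):
        nonlocal best
        if not remaining:
            if len(chosen) < len(best):
                best = list(chosen)
            return
        lb = _disjoint_pair_lower_bound(psets, frozenset(remaining))
        if len(chosen) + lb >= len(best):
            return
        # branch on the hardest uncovered pair
        pivot = min(remaining, key=lambda p: (len(covers[p]), p))
        for c in covers[pivot]:
            if c in chosen:
                continue
            dfs(chosen + [c], remaining - psets[c])

    dfs([], set(universe))
    return best


def minimal_discriminating_set(gtts: Sequence[GTT], mode: str = "exact",
                               conditions: Optional[Sequence[int]] = None) -> DesignResult:
    """Smallest set of conditions separating every separable GTT pair.

    ``mode="greedy"``: iterative max-new-pairs cover. ``mode="exact"``:
    branch-and-bound set cover seeded with the greedy solution; falls back
    to greedy (with the lower bound reported and ``exact=False``) when the
    candidate-condition count after dominance pruning exceeds the cap.
    Pairs no condition separates are reported and excluded.
    """
    if mode not in ("exact", "greedy"):
        raise ValueError(f"unknown mode {mode!r}")
    inst = build_separation(gtts, conditions)
    universe = inst.separable_pairs
    if not universe:
        return DesignResult((), mode, frozenset(), inst.inseparable_pairs, 0, 0, True)
    greedy = _greedy_cover(inst.pair_sets, universe)
    lb = _disjoint_pair_lower_bound(inst.pair_sets, universe)
    if mode == "greedy":
        return DesignResult(tuple(sorted(greedy)), "greedy", universe,
                            inst.inseparable_pairs, len(greedy), lb,
                            exact=len(greedy) == lb)
    if len(inst.pair_sets) > EXACT_CONDITION_CAP:
        return DesignResult(tuple(sorted(greedy)), "greedy", universe,
                            inst.inseparable_pairs, len(greedy), lb,
                            exact=len(greedy) == lb)
    exact = _exact_cover(inst.pair_sets, universe, greedy)
    return DesignResult(tuple(sorted(exact)), "exact", universe,
                        inst.inseparable_pairs, len(greedy), lb, exact=True)


@dataclass
class ExperimentRanking:
    """One top-ranked condition with its per-GTT predicted readouts."""

    condition_index: int
    input_bits: tuple
    n_pairs_separated: int
    n_stimuli_on: int
    n_inhibitors_on: int
    predictions: tuple  # per GTT, tuple of readout values
    pair_diff_counts: dict  # (i, j) -> differing readout count at this condition


def best_single_experiments(gtts: Sequence[GTT],
                            conditions: Optional[Sequence[int]] = None) -> list:
    """All conditions at the top of the (pairs desc, stimuli asc, inhibitors asc) order.

    The simplest maximally informative single experiments for the given
    behaviors, with the readouts each behavior predicts there.
    """
    inst = build_separation(gtts, conditions)
    ref = gtts[0]
    records = []
    for c in inst.conditions:
        pairs = inst.pair_sets.get(c, frozenset())
        bits = ref.condition_bits(c)
        stim_bits, inh_bits = bits[: ref.n_stimuli], bits[ref.n_stimuli :]
        records.append(
            (
                -len(pairs),
                sum(stim_bits),
                sum(inh_bits),
                c,
                bits,
                pairs,
            )
        )
    records.sort(key=lambda r: r[:4])
    top_key = records[0][:3]
    out = []
    for (negp, ns, ni, c, bits, pairs) in records:
        if (negp, ns, ni) != top_key:
            break
        out.append(
            ExperimentRanking(
                condition_index=c,
                input_bits=bits,
                n_pairs_separated=-negp,
                n_stimuli_on=ns,
                n_inhibitors_on=ni,
                predictions=tuple(tuple(int(v) for v in g.table[c]) for g in gtts),
                pair_diff_counts={p: inst.diff_counts[(c, p)] for p in pairs},
            )
        )
    return out


def write_experiments_csv(gtts: Sequence[GTT], rankings: Sequence[ExperimentRanking], path) -> None:
    ref = gtts[0]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        header = list(ref.inputs) + ["n_pairs_separated"] + [
            f"gtt{i}:{r}" for i in range(len(gtts)) for r in ref.readouts
        ]
        writer.writerow(header)
        for rec in rankings:
            row = list(rec.input_bits) + [rec.n_pairs_separated]
            for preds in rec.predictions:
                row.extend(preds)
            writer.writerow(row)
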