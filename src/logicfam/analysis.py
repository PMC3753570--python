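"""Structural statistics over a model family.

With the complete family in hand, each candidate gate has an exact presence
frequency: gates present in every member are expected to be functional,
gates absent from every member are not, and the rest are unidentifiable
from the data. Gates whose presence patterns are identical across the
family are *mutually inclusive* modules; two modules of which exactly one
appears in every member are *mutually exclusive* — interchangeable
alternatives whose combinations inflate the family size.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .enumeration import ModelFamily
from .model import LogicModel, score, simulate
from .types import Dataset

__all__ = [
    "FrequencyReport",
    "ExclusivePair",
    "SwapRecord",
    "hyperedge_frequencies",
    "mutually_inclusive_groups",
    "mutually_exclusive_pairs",
    "swap_effect",
    "write_frequency_csv",
    "write_exclusive_pairs_csv",
]


@dataclass
class FrequencyReport:
    """Per-hyperedge presence frequency across the family, partitioned by class."""

    frequencies: list  # of Fraction, indexed by hyperedge id
    always: tuple  # hyperedge ids with frequency 1
    never: tuple  # frequency 0
    variable: tuple  # strictly between

    def classify(self, hyperedge_id: int) -> str:
        if hyperedge_id in self.always:
            return "always"
        if hyperedge_id in self.never:
            return "never"
        return "variable"


@dataclass(frozen=True)
class ExclusivePair:
    """Two mutually inclusive gate groups of which exactly one appears per model."""

    group_a: tuple  # hyperedge ids
    group_b: tuple
    freq_a: Fraction
    freq_b: Fraction


@dataclass
class SwapRecord:
    """Effect of replacing module A by module B in one family member."""

    model_index: int
    mse_before: Fraction
    mse_after: Fraction
    differing_condition_fraction: Fraction

    @property
    def mse_delta(self) -> Fraction:
        return self.mse_after - self.mse_before


def hyperedge_frequencies(family: ModelFamily) -> FrequencyReport:
    """Exact presence frequency of every hyperedge over the family."""
    if not family.models:
        raise ValueError("family is empty")
    pm = family.presence_matrix()
    n = pm.shape[0]
    counts = pm.sum(axis=0)
    freqs = [Fraction(int(c), n) for c in counts]
    always = tuple(i for i, f in enumerate(freqs) if f == 1)
    never = tuple(i for i, f in enumerate(freqs) if f == 0)
    variable = tuple(i for i, f in enumerate(freqs) if 0 < f < 1)
    return FrequencyReport(freqs, always, never, variable)


def mutually_inclusive_groups(family: ModelFamily) -> list:
    """Maximal gate sets with identical presence columns (always co-present/co-absent).

    Equivalence classes of the column-identity relation, as id tuples, ordered
    by smallest member id. Includes the all-present and all-absent classes.
    """
    pm = family.presence_matrix()
    by_column: dict = {}
    for g in range(pm.shape[1]):
        by_column.setdefault(pm[:, g].tobytes(), []).append(g)
    return sorted((tuple(ids) for ids in by_column.values()), key=lambda t: t[0])


def mutually_exclusive_pairs(family: ModelFamily) -> list:
    """Pairs of inclusive groups of which exactly one is present in every member.

    Only pairs where both sides occur in some but not all members are
    reported (frequencies sum to 1 by construction: the presence columns are
    complementary).
    """
    pm = family.presence_matrix()
    n = pm.shape[0]
    groups = mutually_inclusive_groups(family)
    by_column = {pm[:, g[0]].tobytes(): g for g in groups}
    pairs = []
    seen = set()
    for g in groups:
        col = pm[:, g[0]]
        c = int(col.sum())
        if c == 0 or c == n:
            continue
        comp = (1 - col).astype(pm.dtype)
        other = by_column.get(comp.tobytes())
        if other is None:
            continue
        key = tuple(sorted((g[0], other[0])))
        if key in seen:
            continue
        seen.add(key)
        a, b = (g, other) if g[0] < other[0] else (other, g)
        pairs.append(
            ExclusivePair(a, b, Fraction(int(pm[:, a[0]].sum()), n),
                          Fraction(int(pm[:, b[0]].sum()), n))
        )
    return pairs


def _module_mask(ids) -> int:
    m = 0
    for i in ids:
        m |= 1 << i
    return m


def swap_effect(family: ModelFamily, pair: ExclusivePair, dataset: Dataset,
                precision: Optional[int] = None) -> list:
    """Rescore every member containing module A with A replaced by B.

    Reports, per swap, the exact MSE change and the fraction of the
    dataset's experimental conditions whose readout predictions change.
    """
    hg = family.hypergraph
    precision = precision if precision is not None else family.config.precision
    a_mask = _module_mask(pair.group_a)
    b_mask = _module_mask(pair.group_b)
    records = []
    for mi, (model, sc) in enumerate(zip(family.models, family.scores)):
        if model.mask & a_mask != a_mask:
            continue
        swapped = LogicModel((model.mask & ~a_mask) | b_mask, hg)
        new_score = score(swapped, dataset, precision=precision,
                          max_steps=family.config.max_steps)
        differing = 0
        for cond in dataset.conditions:
            p0 = simulate(model, cond, max_steps=family.config.max_steps)
            p1 = simulate(swapped, cond, max_steps=family.config.max_steps)
            if any(p0[r] != p1[r] for r in dataset.readouts):
                differing += 1
        records.append(
            SwapRecord(
                model_index=mi,
                mse_before=sc.mse,
                mse_after=new_score.mse,
                differing_condition_fraction=Fraction(differing, dataset.n_conditions),
            )
        )
    return records


def write_frequency_csv(family: ModelFamily, report: FrequencyReport, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "target", "sources", "frequency", "class"])
        for h in family.hypergraph.hyperedges:
            writer.writerow(
                [h.id, h.target, h.token(), repr(float(report.frequencies[h.id])),
                 report.classify(h.id)]
            )


def write_exclusive_pairs_csv(family: ModelFamily, pairs: Sequence[ExclusivePair], path) -> None:
    hg = family.hypergraph
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["side_a", "freq_a", "side_b", "freq_b"])
        for p in pairs:
            writer.writerow([
                "|".join(str(hg.hyperedges[i]) for i in p.group_a),
                repr(float(p.freq_a)),
                "|".join(str(hg.hyperedges[i]) for i in p.group_b),
                repr(float(p.freq_b)),
            ])
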