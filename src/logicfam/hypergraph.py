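"""Expansion of a compressed PKN into the signed hypergraph of candidate gates.

Because the exact logic gates are usually unknown, every AND gate compatible
with the network structure is generated: for a node t with signed regulator
set R(t), each non-empty, sign-consistent subset S of R(t) (up to a size
cap) yields one hyperedge S -> t. A logic model then ORs a selected subset
of these gates per target (sum-of-products form), so the hypergraph is the
search space of the combinatorial optimization: 2^|E| candidate models.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

from .types import PKN, Roles

__all__ = [
    "Hyperedge",
    "ExpandedHypergraph",
    "expand",
    "search_space_size",
    "write_hypergraph_csv",
    "read_hypergraph_csv",
]


def _source_key(src):
    node, sign = src
    return (node, sign)


@dataclass(frozen=True)
class Hyperedge:
    """One candidate AND gate: a set of signed sources jointly regulating a target."""

    target: str
    sources: frozenset  # of (node, +1|-1)
    id: int

    def __post_init__(self):
        if not self.sources:
            raise ValueError("hyperedge sources must be non-empty")
        nodes = [n for (n, _) in self.sources]
        if len(set(nodes)) != len(nodes):
            raise ValueError(f"hyperedge to {self.target} has a sign-contradictory source")

    @property
    def sorted_sources(self) -> tuple:
        return tuple(sorted(self.sources, key=_source_key))

    @property
    def cardinality(self) -> int:
        return len(self.sources)

    def token(self) -> str:
        return ";".join(("+" if s > 0 else "-") + n for (n, s) in self.sorted_sources)

    def __str__(self):
        return f"{self.token()}->{self.target}"


@dataclass(frozen=True)
class ExpandedHypergraph:
    """The candidate gate space H = (V, E) with canonical hyperedge ids 0..|E|-1."""

    nodes: tuple
    hyperedges: tuple  # of Hyperedge, id == position
    roles: Roles

    def __post_init__(self):
        for i, h in enumerate(self.hyperedges):
            if h.id != i:
                raise ValueError("hyperedge ids must equal their canonical position")

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)

    def gates_for(self, target: str) -> tuple:
        return tuple(h for h in self.hyperedges if h.target == target)

    @property
    def targets(self) -> tuple:
        return tuple(sorted({h.target for h in self.hyperedges}))


def _canonical_order(raw: Iterable) -> list:
    # sort by target, then lexicographically on the sorted signed-source tuple
    return sorted(raw, key=lambda ts: (ts[0], tuple(_source_key(s) for s in ts[1])))


def expand(pkn: PKN, max_gate_size: Optional[int] = 4) -> ExpandedHypergraph:
    """Generate all candidate AND gates compatible with the (compressed) PKN.

    ``max_gate_size`` caps the number of inputs per gate; ``None`` means
    unbounded, yielding 2^r - 1 gates for a target with r sign-consistent
    regulators. Subsets containing a node with both signs (p AND NOT p,
    always false) are excluded.
    """
    if max_gate_size is not None and max_gate_size < 1:
        raise ValueError("max_gate_size must be >= 1 (or None for unbounded)")
    raw = []
    for t in pkn.sorted_nodes:
        regs = sorted(pkn.regulators(t), key=_source_key)
        if not regs:
            continue
        cap = len(regs) if max_gate_size is None else min(max_gate_size, len(regs))
        for k in range(1, cap + 1):
            for subset in combinations(regs, k):
                nodes = [n for (n, _) in subset]
                if len(set(nodes)) != len(nodes):
                    continue
                raw.append((t, frozenset(subset)))
    ordered = _canonical_order(raw)
    hyperedges = tuple(
        Hyperedge(target=t, sources=srcs, id=i) for i, (t, srcs) in enumerate(ordered)
    )
    return ExpandedHypergraph(tuple(pkn.sorted_nodes), hyperedges, pkn.roles)


def search_space_size(hg: ExpandedHypergraph) -> int:
    """Number of candidate logic models, 2^|E|, as an exact integer."""
    return 1 << hg.n_hyperedges


def write_hypergraph_csv(hg: ExpandedHypergraph, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "target", "sources"])
        for h in hg.hyperedges:
            writer.writerow([h.id, h.target, h.token()])


def read_hypergraph_csv(path, roles: Roles, nodes: Optional[Iterable[str]] = None) -> ExpandedHypergraph:
    hyperedges = []
    seen_nodes = set(roles.designated)
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sources = []
            for tok in row["sources"].split(";"):
                sign = 1 if tok[0] == "+" else -1
                sources.append((tok[1:], sign))
            h = Hyperedge(row["target"], frozenset(sources), int(row["id"]))
            hyperedges.append(h)
            seen_nodes.add(h.target)
            seen_nodes.update(n for (n, _) in sources)
    hyperedges.sort(key=lambda h: h.id)
    all_nodes = tuple(sorted(set(nodes) | seen_nodes)) if nodes else tuple(sorted(seen_nodes))
    return ExpandedHypergraph(all_nodes, tuple(hyperedges), roles)
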