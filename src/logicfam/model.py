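"""Logic models: hyperedge subsets, quasi-steady-state simulation and exact scoring.

A model selects a subset of the candidate hyperedges; each target's update
rule is the OR over its selected AND gates (sum-of-products). Simulation
clamps the experimental inputs (stimulated stimuli to 1, absent stimuli to
0, inhibited nodes to 0 overriding their formula), starts every other node
at 0 and applies synchronous updates until a fixpoint — the quasi steady
state compared against early-time measurements. Under feedback the system
may not settle; nodes still changing after the update budget are reported
as *undefined* and penalized in scoring with the worst squared residual.

Scoring is exact: observations are discretized onto the integer grid
0..10^p and the sum of squared residuals is an integer scaled by 10^(2p),
so ties and tolerance thresholds in the enumeration are decided without
floating-point error.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np

from .hypergraph import ExpandedHypergraph
from .io import discretize_scaled
from .types import Condition, Dataset

__all__ = ["LogicModel", "Score", "simulate", "score", "model_size", "default_max_steps"]


def default_max_steps(hg: ExpandedHypergraph) -> int:
    return 3 * len(hg.nodes)


@dataclass(frozen=True)
class LogicModel:
    """A subset of candidate hyperedges, stored as a bitmask over canonical ids."""

    mask: int
    hypergraph: ExpandedHypergraph

    def __post_init__(self):
        if self.mask < 0 or self.mask >= (1 << self.hypergraph.n_hyperedges):
            raise ValueError("model bitmask out of range for this hypergraph")

    @classmethod
    def from_ids(cls, hypergraph: ExpandedHypergraph, ids: Iterable[int]) -> "LogicModel":
        mask = 0
        for i in ids:
            mask |= 1 << i
        return cls(mask, hypergraph)

    @classmethod
    def empty(cls, hypergraph: ExpandedHypergraph) -> "LogicModel":
        return cls(0, hypergraph)

    @property
    def selected_ids(self) -> tuple:
        return tuple(i for i in range(self.hypergraph.n_hyperedges) if self.mask >> i & 1)

    @property
    def selected(self) -> tuple:
        return tuple(self.hypergraph.hyperedges[i] for i in self.selected_ids)

    def bitvector(self) -> tuple:
        return tuple((self.mask >> i) & 1 for i in range(self.hypergraph.n_hyperedges))

    @property
    def size(self) -> int:
        return sum(h.cardinality for h in self.selected)

    def __contains__(self, hyperedge_id: int) -> bool:
        return bool(self.mask >> hyperedge_id & 1)


@dataclass(frozen=True)
class Score:
    """Exact fit of a model: integer scaled SSE, entries compared, and size."""

    sse_scaled: int
    n_compared: int
    size: int
    precision: int

    @property
    def mse(self) -> Fraction:
        if self.n_compared == 0:
            raise ZeroDivisionError("score compared zero entries")
        return Fraction(self.sse_scaled, self.n_compared * 10 ** (2 * self.precision))

    @property
    def key(self) -> tuple:
        """Lexicographic objective: minimize MSE first, then size."""
        return (self.mse, self.size)

    def __str__(self):
        return f"MSE={float(self.mse):.6g} size={self.size}"


@lru_cache(maxsize=64)
def _compiled(hg: ExpandedHypergraph):
    index = {n: i for i, n in enumerate(hg.nodes)}
    gates = tuple(
        (index[h.target], tuple((index[n], s) for (n, s) in h.sorted_sources))
        for h in hg.hyperedges
    )
    stimuli = tuple(sorted(index[n] for n in hg.roles.stimuli if n in index))
    readouts = {n: index[n] for n in hg.roles.readouts if n in index}
    return index, gates, stimuli, readouts


def _clamps(hg: ExpandedHypergraph, condition: Condition) -> dict:
    index, _, stimuli, _ = _compiled(hg)
    clamped = {i: 0 for i in stimuli}
    for s in condition.stimulus_on:
        clamped[index[s]] = 1
    for n in condition.inhibitor_on:
        clamped[index[n]] = 0  # drug blocks activity regardless of stimulation
    return clamped


def _step(state, targets, clamped):
    new = [0] * len(state)
    for t, gate_list in targets.items():
        v = 0
        for srcs in gate_list:
            if all(state[i] if s > 0 else 1 - state[i] for (i, s) in srcs):
                v = 1
                break
        new[t] = v
    for i, v in clamped.items():
        new[i] = v
    return new


def simulate(model: LogicModel, condition: Condition, max_steps: Optional[int] = None) -> dict:
    """Quasi-steady-state prediction of every node under one condition.

    Returns ``{node: 0 | 1 | None}`` where ``None`` marks a node that did not
    stabilize (possible only with feedback loops). The update budget is
    ``max_steps`` synchronous steps (default 3x the node count); if no
    fixpoint is reached, a second window of the same length is run and nodes
    that change during it are undefined while constant nodes keep their
    value. On acyclic hypergraphs a fixpoint is always reached.
    """
    hg = model.hypergraph
    condition.validate(hg.roles)
    _, gates, _, _ = _compiled(hg)
    n = len(hg.nodes)
    steps = max_steps if max_steps is not None else default_max_steps(hg)
    clamped = _clamps(hg, condition)

    targets: dict = {}
    for gid in range(hg.n_hyperedges):
        if model.mask >> gid & 1:
            t, srcs = gates[gid]
            if t not in clamped:
                targets.setdefault(t, []).append(srcs)
    # non-clamped nodes with no selected gate keep the default value 0
    state = [0] * n
    for i, v in clamped.items():
        state[i] = v

    converged = False
    for _ in range(steps):
        new = _step(state, targets, clamped)
        if new == state:
            converged = True
            break
        state = new
    changed = [False] * n
    if not converged:
        for _ in range(steps):
            new = _step(state, targets, clamped)
            for i in range(n):
                if new[i] != state[i]:
                    changed[i] = True
            state = new

    return {
        node: (None if changed[i] else state[i]) for i, node in enumerate(hg.nodes)
    }


def score(model: LogicModel, dataset: Dataset, precision: int = 2,
          max_steps: Optional[int] = None) -> Score:
    """Exact (MSE, size) fit of a model to a single-time dataset.

    Residuals are taken between the Boolean prediction and the observation
    discretized at ``precision`` digits; missing observations are skipped and
    undefined predictions contribute the maximum squared residual of 1.
    """
    hg = model.hypergraph
    missing_nodes = [r for r in dataset.readouts if r not in hg.nodes]
    if missing_nodes:
        raise ValueError(f"dataset readouts not in hypergraph: {missing_nodes}")
    scale = 10 ** precision
    scale2 = scale * scale
    sse = 0
    n_compared = 0
    for cond, row in zip(dataset.conditions, dataset.values):
        pred = simulate(model, cond, max_steps=max_steps)
        for r, x in zip(dataset.readouts, row):
            if np.isnan(x):
                continue
            n_compared += 1
            p = pred[r]
            if p is None:
                sse += scale2
            else:
                d = discretize_scaled(float(x), precision)
                sse += (p * scale - d) ** 2
    if n_compared == 0:
        raise ValueError("dataset has no non-missing entries to compare")
    return Score(sse_scaled=sse, n_compared=n_compared, size=model.size, precision=precision)


def model_size(model: LogicModel) -> int:
    """Parsimony objective: sum over selected gates of the number of gate inputs."""
    return model.size
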