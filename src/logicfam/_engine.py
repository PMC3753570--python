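"""Bit-parallel simulation engine: evaluate many models at once.

The synchronous-update semantics are identical to :func:`logicfam.model.simulate`
but vectorized with numpy over a batch of model bitmasks, which is what makes
a complete scan of the 2^|E| search space tractable for moderate |E|. The
scalar implementation in :mod:`logicfam.model` is the reference; agreement of
the two routes is asserted by the test suite.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .hypergraph import ExpandedHypergraph
from .io import discretize_scaled
from .model import _compiled, default_max_steps
from .types import Condition, Dataset

__all__ = ["batch_states", "batch_readout_predictions", "batch_scores", "gate_cardinalities"]


def gate_cardinalities(hg: ExpandedHypergraph) -> np.ndarray:
    return np.array([h.cardinality for h in hg.hyperedges], dtype=np.int64)


def _selection_bits(masks: np.ndarray, n_gates: int):
    return [(masks >> g) & 1 != 0 for g in range(n_gates)]


def batch_states(hg: ExpandedHypergraph, masks: np.ndarray, condition: Condition,
                 max_steps: Optional[int] = None):
    """Simulate every model in ``masks`` under ``condition``.

    Returns ``(states, changed)``: two (n_nodes, n_models) boolean arrays,
    the final node values and whether each node was still changing during
    the post-budget window (i.e. is undefined for that model).
    """
    index, gates, stimuli, _ = _compiled(hg)
    masks = np.asarray(masks, dtype=np.int64)
    m = masks.shape[0]
    n = len(hg.nodes)
    steps = max_steps if max_steps is not None else default_max_steps(hg)

    clamped = {i: 0 for i in stimuli}
    for s in condition.stimulus_on:
        clamped[index[s]] = 1
    for nd in condition.inhibitor_on:
        clamped[index[nd]] = 0

    sel = _selection_bits(masks, hg.n_hyperedges)
    per_target: dict = {}
    for gid, (t, srcs) in enumerate(gates):
        if t not in clamped:
            per_target.setdefault(t, []).append((gid, srcs))

    state = np.zeros((n, m), dtype=bool)
    for i, v in clamped.items():
        state[i, :] = bool(v)

    def step(cur):
        new = np.zeros_like(cur)
        for t, gate_list in per_target.items():
            acc = new[t]
            for gid, srcs in gate_list:
                term = sel[gid].copy()
                for (i, s) in srcs:
                    term &= cur[i] if s > 0 else ~cur[i]
                acc |= term
            new[t] = acc
        for i, v in clamped.items():
            new[i, :] = bool(v)
        return new

    converged = False
    for _ in range(steps):
        new = step(state)
        if np.array_equal(new, state):
            converged = True
            break
        state = new
    changed = np.zeros((n, m), dtype=bool)
    if not converged:
        for _ in range(steps):
            new = step(state)
            changed |= new != state
            state = new
    return state, changed


def batch_readout_predictions(hg: ExpandedHypergraph, masks: np.ndarray, condition: Condition,
                              readouts, max_steps: Optional[int] = None) -> np.ndarray:
    """Per-model readout predictions: (n_models, n_readouts) int8, -1 = undefined."""
    index = _compiled(hg)[0]
    states, changed = batch_states(hg, masks, condition, max_steps=max_steps)
    idxs = [index[r] for r in readouts]
    out = states[idxs].astype(np.int8).T.copy()
    out[changed[idxs].T] = -1
    return out


def batch_scores(hg: ExpandedHypergraph, dataset: Dataset, masks: np.ndarray,
                 precision: int = 2, max_steps: Optional[int] = None):
    """Exact scaled SSE and size for every model in ``masks``.

    Returns ``(sse, size, n_compared)`` with integer arrays matching
    :func:`logicfam.model.score` entry for entry.
    """
    index = _compiled(hg)[0]
    masks = np.asarray(masks, dtype=np.int64)
    scale = 10 ** precision
    scale2 = scale * scale
    sse = np.zeros(masks.shape[0], dtype=np.int64)
    n_compared = 0
    for cond, row in zip(dataset.conditions, dataset.values):
        states, changed = batch_states(hg, masks, cond, max_steps=max_steps)
        for r, x in zip(dataset.readouts, row):
            if np.isnan(x):
                continue
            n_compared += 1
            d = discretize_scaled(float(x), precision)
            i = index[r]
            res = np.where(states[i], (scale - d) ** 2, d * d).astype(np.int64)
            res[changed[i]] = scale2
            sse += res
    if n_compared == 0:
        raise ValueError("dataset has no non-missing entries to compare")
    cards = gate_cardinalities(hg)
    size = np.zeros(masks.shape[0], dtype=np.int64)
    for g in range(hg.n_hyperedges):
        size += ((masks >> g) & 1) * cards[g]
    return sse, size, n_compared
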