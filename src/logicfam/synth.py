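"""Synthetic study generator: toy PKNs, ground-truth models and noisy datasets.

Emulates the structure of a perturbation phospho-proteomics study: a signed
(by default acyclic) prior network with designated stimuli, drug-inhibitable
nodes and measured readouts; a hidden ground-truth logic model; and bounded
measurements produced by simulating the truth under a panel of input
combinations and adding truncated Gaussian noise. Everything is reproducible
from the seed, and the emitted SIF/MIDAS files are consumed unchanged by the
readers in :mod:`logicfam.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Optional, Union

import numpy as np

from .hypergraph import ExpandedHypergraph, expand
from .model import LogicModel, simulate
from .network import compress
from .types import Condition, Dataset, PKN, Roles

__all__ = ["SynthConfig", "generate_pkn", "generate_truth_and_data", "generate_instance"]


@dataclass(frozen=True)
class SynthConfig:
    """Shape and noise of a synthetic study.

    Defaults give a small signed DAG with a handful of perturbable inputs
    and measured sinks, measurements under every input combination, and no
    noise; ``noise_sd`` is the standard deviation of additive Gaussian noise
    truncated to [0, 1], with 0.05 a realistic bench value for normalized
    phospho-measurements.
    """

    n_nodes: int = 10
    n_stimuli: int = 3
    n_inhibitables: int = 1
    n_readouts: int = 3
    edge_prob: float = 0.3
    neg_sign_prob: float = 0.25
    allow_cycles: bool = False
    cycle_edge_prob: float = 0.05
    max_gate_size: Optional[int] = 3
    noise_sd: float = 0.0
    n_conditions: Union[int, str] = "all"
    time: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_stimuli + self.n_readouts > self.n_nodes:
            raise ValueError("n_stimuli + n_readouts must not exceed n_nodes")
        for p in (self.edge_prob, self.neg_sign_prob, self.cycle_edge_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sample_pkn_once(cfg: SynthConfig, rng: np.random.Generator) -> PKN:
    names = [f"n{i:02d}" for i in range(cfg.n_nodes)]  # index order = topological order
    edges = set()
    for i in range(cfg.n_nodes):
        for j in range(i + 1, cfg.n_nodes):
            if rng.random() < cfg.edge_prob:
                sign = -1 if rng.random() < cfg.neg_sign_prob else 1
                edges.add((names[i], sign, names[j]))
            if cfg.allow_cycles and rng.random() < cfg.cycle_edge_prob:
                sign = -1 if rng.random() < cfg.neg_sign_prob else 1
                edges.add((names[j], sign, names[i]))
    stimuli = names[: cfg.n_stimuli]
    readouts = names[cfg.n_nodes - cfg.n_readouts :]
    middle = [n for n in names if n not in stimuli and n not in readouts]
    pool = middle if len(middle) >= cfg.n_inhibitables else middle + readouts
    inhibitables = sorted(
        rng.choice(pool, size=cfg.n_inhibitables, replace=False)
    ) if cfg.n_inhibitables else []
    roles = Roles.of(stimuli, inhibitables, readouts)
    return PKN(frozenset(names), frozenset(edges), roles)


def _has_stimulus_readout_path(pkn: PKN) -> bool:
    adj: dict = {}
    for (u, _, v) in pkn.edges:
        adj.setdefault(u, set()).add(v)
    for s in pkn.roles.stimuli:
        seen, stack = {s}, [s]
        while stack:
            x = stack.pop()
            if x in pkn.roles.readouts:
                return True
            for y in adj.get(x, ()):
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
    return False


def generate_pkn(cfg: SynthConfig, max_attempts: int = 200) -> PKN:
    """Random signed digraph (a DAG unless ``allow_cycles``) with assigned roles.

    Resamples the edge set (deterministically from the seed) until some
    stimulus has a directed path to some readout; raises if the configuration
    admits none (e.g. ``edge_prob=0``).
    """
    rng = np.random.default_rng(cfg.seed)
    for _ in range(max_attempts):
        pkn = _sample_pkn_once(cfg, rng)
        if _has_stimulus_readout_path(pkn):
            return pkn
    raise ValueError(
        "could not generate a PKN with a stimulus->readout path "
        f"in {max_attempts} attempts (edge_prob={cfg.edge_prob})"
    )


def _sample_truth(hg: ExpandedHypergraph, rng: np.random.Generator) -> LogicModel:
    # one gate per target guaranteed, occasionally a second; small gates favored
    ids = []
    for t in hg.targets:
        gates = hg.gates_for(t)
        weights = np.array([0.5 ** g.cardinality for g in gates])
        weights /= weights.sum()
        n_pick = 1 + (rng.random() < 0.25 and len(gates) > 1)
        picked = rng.choice(len(gates), size=min(n_pick, len(gates)), replace=False, p=weights)
        ids.extend(gates[i].id for i in np.atleast_1d(picked))
    return LogicModel.from_ids(hg, ids)


def _input_assignments(roles: Roles, cfg: SynthConfig, rng: np.random.Generator):
    inputs = tuple(sorted(roles.stimuli)) + tuple(
        s for s in sorted(roles.inhibitables) if s not in roles.stimuli
    )
    k = len(inputs)
    if cfg.n_conditions == "all":
        if k > 14:
            raise ValueError(f"'all' conditions with {k} inputs is 2^{k}; pass an integer")
        assignments = list(product((0, 1), repeat=k))
    else:
        n = min(int(cfg.n_conditions), 1 << k)
        chosen = rng.choice(1 << k, size=n, replace=False)
        assignments = [tuple((int(c) >> (k - 1 - i)) & 1 for i in range(k)) for c in sorted(chosen)]
    conds = []
    for bits in assignments:
        on = {inp for inp, b in zip(inputs, bits) if b}
        conds.append(Condition.of(on & roles.stimuli, on & roles.inhibitables))
    return conds


def generate_truth_and_data(pkn: PKN, cfg: SynthConfig):
    """Sample a ground-truth model on the expanded PKN and measure it.

    Returns ``(hypergraph, truth_model, dataset)``. Observations are the
    truth's quasi-steady-state readout values under each condition plus
    truncated Gaussian noise; a prediction that fails to settle (possible
    only with cycles) is recorded as a missing measurement.
    """
    compressed, _ = compress(pkn)
    hg = expand(compressed, max_gate_size=cfg.max_gate_size)
    if hg.n_hyperedges == 0:
        raise ValueError("expanded hypergraph is empty; no gates to sample a truth from")
    rng = np.random.default_rng((cfg.seed * 1_000_003 + 7) % (1 << 31))
    truth = _sample_truth(hg, rng)
    conditions = _input_assignments(pkn.roles, cfg, rng)
    readouts = sorted(pkn.roles.readouts)
    values = np.empty((len(conditions), len(readouts)))
    for i, cond in enumerate(conditions):
        pred = simulate(truth, cond)
        for j, r in enumerate(readouts):
            v = pred[r]
            if v is None:
                values[i, j] = np.nan
            else:
                x = float(v)
                if cfg.noise_sd > 0:
                    x = float(np.clip(x + rng.normal(0.0, cfg.noise_sd), 0.0, 1.0))
                values[i, j] = x
    dataset = Dataset(conditions, readouts, values, time=cfg.time)
    return hg, truth, dataset


def generate_instance(cfg: SynthConfig, max_hyperedges: Optional[int] = None,
                      max_seed_probes: int = 200):
    """Convenience: PKN + expanded hypergraph + truth + dataset in one call.

    With ``max_hyperedges`` set, derived seeds are probed (deterministically)
    until the expanded hypergraph is small enough — handy for exhaustive
    cross-checks that need a bounded search space.
    """
    probe = cfg
    for attempt in range(max_seed_probes):
        pkn = generate_pkn(probe)
        hg, truth, dataset = generate_truth_and_data(pkn, probe)
        if max_hyperedges is None or 0 < hg.n_hyperedges <= max_hyperedges:
            return pkn, hg, truth, dataset
        probe = replace(probe, seed=(probe.seed * 7_919 + 1) % (1 << 31))
    raise ValueError(
        f"no instance with <= {max_hyperedges} hyperedges found in {max_seed_probes} probes"
    )
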