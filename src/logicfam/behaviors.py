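"""Global Truth Tables: the input-output behavior of logic models.

A model's GTT is its predicted readout vector under *every* possible
experimental condition — each of the 2^k on/off assignments of the k input
nodes (all stimuli plus all inhibitable nodes). Two models with the same
GTT are experimentally indistinguishable no matter their structure, so a
large model family can be grouped into far fewer behaviors. Conditions on
which every behavior agrees are the family's *core predictions*; behaviors
can be compared and clustered by Hamming distance between their tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from . import _engine
from .enumeration import ModelFamily
from .model import LogicModel, simulate
from .types import Condition, Roles

__all__ = [
    "GTT",
    "input_nodes",
    "input_conditions",
    "compute_gtt",
    "group_by_gtt",
    "core_predictions",
    "cluster_gtts",
    "dendrogram_newick",
    "write_gtt_csv",
]

DEFAULT_INPUT_CAP = 20


def input_nodes(roles: Roles) -> tuple:
    """Canonical input order: sorted stimuli, then sorted inhibitables."""
    return tuple(sorted(roles.stimuli)) + tuple(
        s for s in sorted(roles.inhibitables) if s not in roles.stimuli
    )


def _condition_from_bits(inputs, bits, roles: Roles) -> Condition:
    on = {inp for inp, b in zip(inputs, bits) if b}
    return Condition.of(on & roles.stimuli, on & roles.inhibitables)


def input_conditions(roles: Roles, input_cap: int = DEFAULT_INPUT_CAP) -> list:
    """All 2^k input assignments in canonical binary order (input 0 most significant)."""
    inputs = input_nodes(roles)
    k = len(inputs)
    if k > input_cap:
        raise ValueError(
            f"{k} inputs would give 2^{k} conditions, above the cap of 2^{input_cap}"
        )
    return [_condition_from_bits(inputs, bits, roles) for bits in product((0, 1), repeat=k)]


@dataclass
class GTT:
    """One input-output behavior and the family members exhibiting it.

    ``table`` is a (2^k, n_readouts) int8 array in canonical binary condition
    order; entries are 0, 1 or -1 (undefined — models that fail to settle
    are a distinct, in-principle-observable behavior).
    """

    inputs: tuple
    readouts: tuple
    table: np.ndarray
    members: tuple = ()
    n_stimuli: int = 0  # the first n_stimuli entries of ``inputs`` are stimuli

    def key(self) -> bytes:
        return self.table.tobytes()

    @property
    def n_conditions(self) -> int:
        return self.table.shape[0]

    def condition_bits(self, idx: int) -> tuple:
        k = len(self.inputs)
        return tuple((idx >> (k - 1 - i)) & 1 for i in range(k))

    def __eq__(self, other):
        return (
            isinstance(other, GTT)
            and self.inputs == other.inputs
            and self.readouts == other.readouts
            and np.array_equal(self.table, other.table)
        )


def compute_gtt(model: LogicModel, max_steps: Optional[int] = None,
                input_cap: int = DEFAULT_INPUT_CAP) -> GTT:
    """Simulate the model under every input assignment, restricted to readouts."""
    hg = model.hypergraph
    roles = hg.roles
    inputs = input_nodes(roles)
    readouts = tuple(sorted(roles.readouts))
    conditions = input_conditions(roles, input_cap=input_cap)
    table = np.empty((len(conditions), len(readouts)), dtype=np.int8)
    for ci, cond in enumerate(conditions):
        pred = simulate(model, cond, max_steps=max_steps)
        for j, r in enumerate(readouts):
            v = pred[r]
            table[ci, j] = -1 if v is None else v
    return GTT(inputs, readouts, table, n_stimuli=len(roles.stimuli))


def group_by_gtt(family: ModelFamily, max_steps: Optional[int] = None,
                 input_cap: int = DEFAULT_INPUT_CAP) -> list:
    """Partition a family by behavior.

    Returns one GTT per distinct table, each carrying the member model
    indices, ordered by (min member MSE, member count descending, table
    bytes). Simulation is bit-parallel across the family per condition.
    """
    if not family.models:
        raise ValueError("family is empty")
    hg = family.hypergraph
    roles = hg.roles
    inputs = input_nodes(roles)
    readouts = tuple(sorted(roles.readouts))
    conditions = input_conditions(roles, input_cap=input_cap)
    masks = family.masks
    n_models = len(masks)
    tables = np.empty((n_models, len(conditions), len(readouts)), dtype=np.int8)
    for ci, cond in enumerate(conditions):
        tables[:, ci, :] = _engine.batch_readout_predictions(
            hg, masks, cond, readouts, max_steps=max_steps
        )
    groups: dict = {}
    for mi in range(n_models):
        groups.setdefault(tables[mi].tobytes(), []).append(mi)
    out = []
    for key, members in groups.items():
        table = np.frombuffer(key, dtype=np.int8).reshape(len(conditions), len(readouts)).copy()
        out.append(GTT(inputs, readouts, table, tuple(members), n_stimuli=len(roles.stimuli)))
    mses = [s.mse for s in family.scores]
    out.sort(key=lambda g: (min(mses[i] for i in g.members), -len(g.members), g.key()))
    return out


def core_predictions(gtts: Sequence[GTT]):
    """Conditions on which all behaviors agree on every readout.

    Returns a list of ``(condition_index, readout_value_tuple)`` pairs; the
    shared values may include -1 (agreed-undefined).
    """
    if not gtts:
        raise ValueError("need at least one GTT")
    ref = gtts[0]
    agree = np.ones(ref.n_conditions, dtype=bool)
    for g in gtts[1:]:
        agree &= np.all(g.table == ref.table, axis=1)
    return [(int(ci), tuple(int(v) for v in ref.table[ci])) for ci in np.flatnonzero(agree)]


def gtt_distance_matrix(gtts: Sequence[GTT]) -> np.ndarray:
    """Pairwise Hamming distances (count of differing table entries)."""
    flat = np.stack([g.table.reshape(-1) for g in gtts])
    n = flat.shape[0]
    dist = np.zeros((n, n), dtype=float)
    for i in range(n):
        dist[i] = np.sum(flat != flat[i], axis=1)
    return dist


def cluster_gtts(gtts: Sequence[GTT]):
    """Average-linkage agglomerative clustering of behaviors.

    Distance is the Hamming count over the concatenated prediction vectors.
    Returns a scipy linkage matrix; leaf i is ``gtts[i]``.
    """
    if len(gtts) < 2:
        raise ValueError("clustering needs at least two GTTs")
    dist = gtt_distance_matrix(gtts)
    return linkage(squareform(dist, checks=False), method="average")


def dendrogram_newick(z: np.ndarray, labels: Optional[Sequence[str]] = None) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(z)
    n_leaves = tree.count
    if labels is None:
        labels = [f"GTT{i}" for i in range(n_leaves)]

    def render(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0) if parent_dist is not None else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        if parent_dist is None:
            return f"({left},{right});"
        return f"({left},{right}):{length:g}"

    return render(tree, None)


def write_gtt_csv(gtts: Sequence[GTT], path) -> None:
    """Wide per-group table: one row per condition, one block of columns per GTT."""
    if not gtts:
        raise ValueError("no GTTs to write")
    ref = gtts[0]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        header = list(ref.inputs) + [
            f"gtt{i}:{r}" for i in range(len(gtts)) for r in ref.readouts
        ]
        writer.writerow(header)
        for ci in range(ref.n_conditions):
            row = list(ref.condition_bits(ci))
            for g in gtts:
                row.extend(int(v) for v in g.table[ci])
            writer.writerow(row)
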