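"""Core domain types: prior knowledge networks, experimental roles, conditions, datasets.

A PKN is a signed directed graph G = (V, A) over protein species. Node roles
come from the experimental setup: *stimuli* can be set active (ligands),
*inhibitables* can be clamped inactive by a small-molecule inhibitor, and
*readouts* are the measured species. A Condition is one perturbation (which
stimuli are on, which inhibitors are applied); a Dataset is the n x m matrix
of normalized measurements of m readouts under n conditions at one
acquisition time, with missing entries represented as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["Roles", "PKN", "Condition", "Dataset"]


@dataclass(frozen=True)
class Roles:
    """Experimental role designation of PKN nodes."""

    stimuli: frozenset = frozenset()
    inhibitables: frozenset = frozenset()
    readouts: frozenset = frozenset()

    @classmethod
    def of(
        cls,
        stimuli: Iterable[str] = (),
        inhibitables: Iterable[str] = (),
        readouts: Iterable[str] = (),
    ) -> "Roles":
        return cls(frozenset(stimuli), frozenset(inhibitables), frozenset(readouts))

    @property
    def designated(self) -> frozenset:
        return self.stimuli | self.inhibitables | self.readouts

    @property
    def inputs(self) -> frozenset:
        """Nodes that can be perturbed experimentally (stimulated or inhibited)."""
        return self.stimuli | self.inhibitables


@dataclass(frozen=True)
class PKN:
    """Signed directed graph of known causal interactions, with node roles.

    ``edges`` is a frozenset of ``(source, sign, target)`` triples with sign
    in {+1, -1}. Parallel edges of opposite sign are allowed (they encode
    both an activating and an inhibiting influence); duplicates are not.
    """

    nodes: frozenset
    edges: frozenset  # of (source, +1|-1, target)
    roles: Roles = field(default_factory=Roles)

    def __post_init__(self):
        for (u, s, v) in self.edges:
            if s not in (1, -1):
                raise ValueError(f"edge sign must be +1 or -1, got {s!r} on {u}->{v}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge {u}->{v} references undeclared node")
        missing = self.roles.designated - self.nodes
        if missing:
            raise ValueError(f"role-designated nodes not in network: {sorted(missing)}")

    def with_roles(self, roles: Roles) -> "PKN":
        """Return a copy with roles attached (nodes missing from the graph are added)."""
        return PKN(self.nodes | roles.designated, self.edges, roles)

    def regulators(self, node: str) -> frozenset:
        """Signed regulator set {(source, sign)} of ``node``."""
        return frozenset((u, s) for (u, s, v) in self.edges if v == node)

    @property
    def sorted_nodes(self) -> tuple:
        return tuple(sorted(self.nodes))

    @property
    def sorted_edges(self) -> tuple:
        return tuple(sorted(self.edges))


@dataclass(frozen=True)
class Condition:
    """One experimental perturbation: stimuli set to 1 and nodes clamped to 0."""

    stimulus_on: frozenset = frozenset()
    inhibitor_on: frozenset = frozenset()

    @classmethod
    def of(cls, stimulus_on: Iterable[str] = (), inhibitor_on: Iterable[str] = ()) -> "Condition":
        return cls(frozenset(stimulus_on), frozenset(inhibitor_on))

    def validate(self, roles: Roles) -> None:
        bad_s = self.stimulus_on - roles.stimuli
        bad_i = self.inhibitor_on - roles.inhibitables
        if bad_s:
            raise ValueError(f"condition stimulates non-stimulus nodes: {sorted(bad_s)}")
        if bad_i:
            raise ValueError(f"condition inhibits non-inhibitable nodes: {sorted(bad_i)}")


@dataclass
class Dataset:
    """Measurements of ``readouts`` under ``conditions`` at one acquisition time.

    ``values`` is an (n_conditions, n_readouts) float array; missing
    measurements are NaN and are excluded from scoring. Raw (unnormalized)
    values are allowed at read time; scoring requires the unit interval,
    established by :func:`logicfam.io.normalize`.
    """

    conditions: list  # of Condition
    readouts: list  # of node names, column order
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.conditions), len(self.readouts)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.conditions)} conditions x {len(self.readouts)} readouts"
            )

    def in_unit_interval(self) -> bool:
        finite = self.values[~np.isnan(self.values)]
        return bool(finite.size == 0 or (finite.min() >= 0 and finite.max() <= 1))

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_readouts(self) -> int:
        return len(self.readouts)

    def copy_with(self, **kw) -> "Dataset":
        cur = dict(
            conditions=list(self.conditions),
            readouts=list(self.readouts),
            values=self.values.copy(),
            time=self.time,
        )
        cur.update(kw)
        return Dataset(**cur)
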