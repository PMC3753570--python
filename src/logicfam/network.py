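"""PKN compression.

Before gate expansion the network is reduced to the part that can actually
be confronted with the data: nodes that are neither observable (no directed
path to any readout) nor controllable (unreachable from every stimulus and
inhibitable) carry no information, and undesignated pass-through nodes can
be collapsed, composing edge signs along the path. Designated nodes
(stimuli, inhibitables, readouts) are never removed.
"""

from __future__ import annotations

import networkx as nx

from .types import PKN

__all__ = ["compress"]


def _digraph(edges) -> nx.DiGraph:
    g = nx.DiGraph()
    for (u, _, v) in edges:
        g.add_edge(u, v)
    return g


def _reachability_keep(nodes, edges, roles):
    """Nodes that are designated, or both observable and controllable."""
    g = _digraph(edges)
    g.add_nodes_from(nodes)
    observable = set()
    for r in roles.readouts:
        if r in g:
            observable |= nx.ancestors(g, r)
            observable.add(r)
    controllable = set()
    for s in roles.inputs:
        if s in g:
            controllable |= nx.descendants(g, s)
            controllable.add(s)
    return roles.designated | (observable & controllable & set(nodes))


def compress(pkn: PKN):
    """Compress a role-annotated PKN.

    Returns ``(compressed_pkn, warnings)``. Removes non-observable and
    non-controllable undesignated nodes, then iteratively collapses
    undesignated nodes, replacing each path u -> x -> w by a direct edge
    whose sign is the product of the two signs. A node whose collapse would
    create a self-loop is kept (preserves fixpoint semantics). Parallel
    edges of equal sign merge; opposite signs are both kept.
    """
    roles = pkn.roles
    if not roles.readouts and not roles.inputs:
        raise ValueError("compress requires role-designated nodes (stimuli/inhibitables/readouts)")

    nodes = set(pkn.nodes)
    edges = set(pkn.edges)

    def prune():
        keep = _reachability_keep(nodes, edges, roles)
        dropped = nodes - keep
        if dropped:
            nodes.difference_update(dropped)
            for e in [e for e in edges if e[0] in dropped or e[2] in dropped]:
                edges.discard(e)
        return bool(dropped)

    prune()
    while True:
        collapsed = False
        for x in sorted(nodes - roles.designated):
            ins = [(u, s) for (u, s, v) in edges if v == x]
            outs = [(w, s) for (u, s, w) in edges if u == x]
            if any(u == x for u, _ in ins) or any(w == x for w, _ in outs):
                continue  # self-loop on x: collapsing would lose the feedback
            if any(u == w for (u, _) in ins for (w, _) in outs):
                continue  # collapse would create a self-loop u -> u
            for (u, s1) in ins:
                for (w, s2) in outs:
                    edges.add((u, s1 * s2, w))
            for e in [e for e in edges if e[0] == x or e[2] == x]:
                edges.discard(e)
            nodes.discard(x)
            collapsed = True
            break
        pruned = prune()
        if not collapsed and not pruned:
            break

    warnings = []
    for r in sorted(roles.readouts):
        if not any(v == r for (_, _, v) in edges):
            warnings.append(f"readout {r!r} has no remaining regulators after compression")
    return PKN(frozenset(nodes), frozenset(edges), roles), warnings
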