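"""Independent oracles: exhaustive per-model brute force through the scalar API.

These deliberately avoid the vectorized enumeration backend: every candidate
model is scored one at a time via ``logicfam.model.score`` (the scalar
reference semantics), so family enumeration can be checked against a second,
structurally different route.
"""

from fractions import Fraction

from logicfam.model import LogicModel, score


def brute_force_scores(hg, dataset, precision=2):
    """Score of every one of the 2^|E| models, keyed by bitmask."""
    return {
        mask: score(LogicModel(mask, hg), dataset, precision=precision)
        for mask in range(1 << hg.n_hyperedges)
    }


def brute_force_optimum(scores):
    """Exact lexicographic (MSE, size) optimum over a score table."""
    best = min(s.key for s in scores.values())
    return best  # (mse: Fraction, size: int)


def brute_force_family(hg, dataset, eps, size_bound="optimal", precision=2):
    """Set of bitmasks within tolerance: MSE <= (1+eps)*MSE_opt, size <= bound."""
    scores = brute_force_scores(hg, dataset, precision=precision)
    mse_opt, size_opt = brute_force_optimum(scores)
    eps = Fraction(repr(float(eps)))
    bound = size_opt if size_bound == "optimal" else int(size_bound)
    limit = (1 + eps) * mse_opt
    return {
        mask
        for mask, s in scores.items()
        if s.mse <= limit and s.size <= bound
    }, (mse_opt, size_opt)


def formula_value(model, values, node):
    """Evaluate a node's SOP formula on a given assignment (None-propagating)."""
    terms = [h for h in model.selected if h.target == node]
    if not terms:
        return 0
    any_none = False
    for h in terms:
        lits = []
        for (src, sign) in h.sorted_sources:
            v = values[src]
            if v is None:
                lits.append(None)
            else:
                lits.append(v if sign > 0 else 1 - v)
        if any(l == 0 for l in lits):
            continue  # term is false regardless of unknowns
        if all(l == 1 for l in lits):
            return 1
        any_none = True
    return None if any_none else 0
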