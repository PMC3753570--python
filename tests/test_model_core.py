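import random
from fractions import Fraction

import numpy as np
import pytest

from logicfam import (
    Condition,
    Dataset,
    LogicModel,
    PKN,
    Roles,
    compress,
    expand,
    model_size,
    score,
    simulate,
)
from _oracles import formula_value


@pytest.fixture
def toy_model(toy1):
    return toy1["truth"]  # c = a, d = c AND NOT b


class TestSimulate:
    def test_two_step_propagation(self, toy_model):
        pred = simulate(toy_model, Condition.of({"a"}))
        assert (pred["c"], pred["d"]) == (1, 1)

    def test_not_literal(self, toy_model):
        pred = simulate(toy_model, Condition.of({"a", "b"}))
        assert (pred["c"], pred["d"]) == (1, 0)

    def test_inhibitor_clamp_overrides_formula(self, toy1):
        pkn = toy1["pkn"]
        roles = Roles.of(pkn.roles.stimuli, {"c"}, pkn.roles.readouts)
        hg = expand(compress(pkn.with_roles(roles))[0], None)
        by_str = {str(h): h.id for h in hg.hyperedges}
        model = LogicModel.from_ids(hg, [by_str["+a->c"], by_str["-b;+c->d"]])
        pred = simulate(model, Condition.of({"a"}, {"c"}))
        assert (pred["c"], pred["d"]) == (0, 0)

    def test_unstimulated_stimuli_are_zero(self, toy_model):
        pred = simulate(toy_model, Condition.of())
        assert (pred["a"], pred["b"], pred["c"], pred["d"]) == (0, 0, 0, 0)

    def test_node_without_selected_gate_defaults_to_zero(self, toy1):
        empty = LogicModel.empty(toy1["hg"])
        pred = simulate(empty, Condition.of({"a", "b"}))
        assert pred["c"] == 0 and pred["d"] == 0

    def test_feedback_oscillation_is_undefined(self):
        # negative feedback x -> NOT x oscillates under synchronous updates
        pkn = PKN(
            frozenset("axr"),
            frozenset({("a", 1, "x"), ("x", -1, "x"), ("x", 1, "r")}),
            Roles.of(stimuli=["a"], readouts=["r"]),
        )
        hg = expand(pkn, None)  # no compression: keep the self-loop
        by_str = {str(h): h.id for h in hg.hyperedges}
        model = LogicModel.from_ids(hg, [by_str["-x->x"], by_str["+x->r"]])
        pred = simulate(model, Condition.of({"a"}))
        assert pred["x"] is None and pred["r"] is None

    def test_acyclic_always_converges_and_fixpoint_holds(self):
        rng = random.Random(23)
        for trial in range(60):
            n = rng.randint(4, 8)
            names = [f"n{i}" for i in range(n)]
            edges = set()
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        edges.add((names[i], rng.choice([1, -1]), names[j]))
            roles = Roles.of(stimuli=names[:2], readouts=names[-2:])
            pkn = PKN(frozenset(names), frozenset(edges), roles)
            hg = expand(pkn, 2)
            if hg.n_hyperedges == 0:
                continue
            mask = rng.getrandbits(hg.n_hyperedges)
            model = LogicModel(mask, hg)
            cond = Condition.of({s for s in roles.stimuli if rng.random() < 0.5})
            pred = simulate(model, cond)
            assert all(v is not None for v in pred.values())  # acyclic: converges
            # fixpoint: substituting values into every formula reproduces them
            for node in names:
                if node in roles.stimuli:
                    continue
                assert pred[node] == formula_value(model, pred, node)

    def test_fixpoint_property_with_feedback(self):
        # when a cyclic simulation converges, the values satisfy the formulas
        rng = random.Random(7)
        checked = 0
        for trial in range(80):
            n = rng.randint(4, 7)
            names = [f"n{i}" for i in range(n)]
            edges = set()
            for i in range(n):
                for j in range(n):
                    if i != j and rng.random() < 0.25:
                        edges.add((names[i], rng.choice([1, -1]), names[j]))
            roles = Roles.of(stimuli=names[:1], readouts=names[-1:])
            pkn = PKN(frozenset(names), frozenset(edges), roles)
            hg = expand(pkn, 2)
            if hg.n_hyperedges == 0:
                continue
            model = LogicModel(rng.getrandbits(hg.n_hyperedges), hg)
            cond = Condition.of(roles.stimuli)
            pred = simulate(model, cond)
            if any(v is None for v in pred.values()):
                continue
            for node in names:
                if node in roles.stimuli:
                    continue
                assert pred[node] == formula_value(model, pred, node)
            checked += 1
        assert checked > 10


class TestScore:
    def test_arithmetic_example(self, toy1):
        hg = toy1["hg"]
        # model predicting c=1, d=0 whenever a on: compare against 0.91, 0.10
        by_str = {str(h): h.id for h in hg.hyperedges}
        model = LogicModel.from_ids(hg, [by_str["+a->c"]])
        ds = Dataset([Condition.of({"a"})], ["c", "d"], np.array([[0.91, 0.10]]))
        s = score(model, ds, precision=2)
        assert s.mse == Fraction(81 + 100, 2 * 10_000)  # (0.0081 + 0.01) / 2
        assert float(s.mse) == pytest.approx(0.00905)

    def test_perfect_fit_is_zero(self, toy1):
        s = score(toy1["truth"], toy1["dataset"], precision=2)
        assert s.mse == 0 and s.size == 3

    def test_empty_model_on_zero_data(self, toy1):
        ds = toy1["dataset"].copy_with(values=np.zeros_like(toy1["dataset"].values))
        s = score(LogicModel.empty(toy1["hg"]), ds)
        assert s.mse == 0 and s.size == 0

    def test_missing_entries_excluded(self, toy1):
        vals = toy1["dataset"].values.copy()
        vals[0, 0] = np.nan
        s = score(toy1["truth"], toy1["dataset"].copy_with(values=vals))
        assert s.n_compared == vals.size - 1

    def test_all_missing_is_error(self, toy1):
        vals = np.full_like(toy1["dataset"].values, np.nan)
        with pytest.raises(ValueError, match="non-missing"):
            score(toy1["truth"], toy1["dataset"].copy_with(values=vals))

    def test_undefined_prediction_penalized_as_one(self):
        pkn = PKN(
            frozenset("axr"),
            frozenset({("a", 1, "x"), ("x", -1, "x"), ("x", 1, "r")}),
            Roles.of(stimuli=["a"], readouts=["r"]),
        )
        hg = expand(pkn, None)
        by_str = {str(h): h.id for h in hg.hyperedges}
        model = LogicModel.from_ids(hg, [by_str["-x->x"], by_str["+x->r"]])
        ds = Dataset([Condition.of({"a"})], ["r"], np.array([[0.0]]))
        s = score(model, ds, precision=2)
        assert s.mse == 1  # worst residual for the oscillating readout

    def test_invariant_under_row_and_column_permutation(self, toy1):
        ds = toy1["dataset"]
        rng = np.random.default_rng(3)
        rows = rng.permutation(ds.n_conditions)
        cols = rng.permutation(ds.n_readouts)
        permuted = Dataset(
            [ds.conditions[i] for i in rows],
            [ds.readouts[j] for j in cols],
            ds.values[np.ix_(rows, cols)],
            time=ds.time,
        )
        for mask in range(1 << toy1["hg"].n_hyperedges):
            m = LogicModel(mask, toy1["hg"])
            assert score(m, ds) == score(m, permuted)


class TestSize:
    def test_examples(self, toy1):
        hg = toy1["hg"]
        by_str = {str(h): h.id for h in hg.hyperedges}
        assert model_size(LogicModel.empty(hg)) == 0
        m = LogicModel.from_ids(hg, [by_str["+a->c"], by_str["+a;+b->c"]])
        assert model_size(m) == 3

    def test_adding_a_gate_never_decreases_size(self, toy1):
        hg = toy1["hg"]
        for mask in range(1 << hg.n_hyperedges):
            base = model_size(LogicModel(mask, hg))
            for g in range(hg.n_hyperedges):
                if not mask >> g & 1:
                    assert model_size(LogicModel(mask | 1 << g, hg)) > base
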