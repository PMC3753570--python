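import numpy as np
import pytest

from logicfam import (
    Condition,
    Dataset,
    LogicModel,
    PKN,
    Roles,
    compress,
    expand,
    simulate,
)


def toy1_pkn():
    """Two stimuli a, b feeding readouts c and d; 6 candidate gates after expansion."""
    return PKN(
        frozenset("abcd"),
        frozenset({("a", 1, "c"), ("b", 1, "c"), ("c", 1, "d"), ("b", -1, "d")}),
        Roles.of(stimuli=["a", "b"], readouts=["c", "d"]),
    )


@pytest.fixture(scope="session")
def toy1():
    """The 6-hyperedge toy instance with noise-free data from a known truth.

    Truth: c = a, d = c AND NOT b. Data covers all four stimulus combinations.
    """
    pkn = toy1_pkn()
    compressed, _ = compress(pkn)
    hg = expand(compressed, max_gate_size=None)
    by_str = {str(h): h.id for h in hg.hyperedges}
    truth = LogicModel.from_ids(hg, [by_str["+a->c"], by_str["-b;+c->d"]])
    conditions = [Condition.of(set(s)) for s in ["", "a", "b", "ab"]]
    values = []
    for cond in conditions:
        pred = simulate(truth, cond)
        values.append([float(pred["c"]), float(pred["d"])])
    dataset = Dataset(conditions, ["c", "d"], np.array(values), time=10.0)
    return {"pkn": pkn, "hg": hg, "truth": truth, "dataset": dataset}


@pytest.fixture
def toy1_noisy(toy1):
    """TOY1 with two ambiguous observations near 0.5.

    Near-0.5 values make competing predictions score similarly, so the
    10%-tolerance family is strictly larger than the zero-tolerance one.
    """
    ds = toy1["dataset"]
    vals = ds.values.copy()
    vals[2, 0] = 0.48  # readout c under stimulus b (truth predicts 0)
    vals[1, 1] = 0.52  # readout d under stimulus a (truth predicts 1)
    return ds.copy_with(values=vals)
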