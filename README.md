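# logicfam

Exhaustive learning and characterization of Boolean logic model families for
signaling networks.

## The problem

Signal transduction can be modeled by confronting a **prior knowledge
network** (PKN) — a signed directed graph *G = (V, A)* of known causal
interactions between proteins — with a **perturbation phospho-proteomics
dataset**: measurements *x<sub>i</sub><sup>j</sup>* ∈ [0, 1] of *m* readout
proteins under *n* experimental conditions, each condition fixing a set of
*stimuli* (ligands set active) and *inhibitors* (drugs clamping a kinase
inactive).

Because the exact logic gates are unknown, the compressed PKN is *expanded*
into a signed hypergraph *H = (V, E)*: one candidate hyperedge per
sign-consistent regulator subset of each node, i.e. one AND gate. A **logic
model** selects a subset of these gates; each node's update rule is the OR of
its selected AND gates (sum-of-products form). A model is simulated to its
quasi steady state under each condition (synchronous updates from the clamped
inputs) and scored by the mean squared error

&nbsp;&nbsp;MSE = (1 / nm) Σ<sub>i,j</sub> (x<sub>i</sub><sup>j</sup> − p<sub>i</sub><sup>j</sup>)²

against the discretized observations, with model *size* Σ<sub>gates</sub>
|inputs| as the parsimony objective. Learning is the lexicographic discrete
optimization: minimize MSE, then size, over all 2^|E| gate subsets.

The point of this package is not one fitted model but the **complete
family**: every model with MSE ≤ (1 + ε)·MSE<sub>opt</sub> (ε accounts for
experimental error) and size within a bound. Over that family it computes:

- exact per-gate **presence frequencies** (always / never / variable gates),
- **mutually inclusive** gate modules and **mutually exclusive** module
  pairs (interchangeable mechanisms that inflate the family combinatorially),
- **Global Truth Tables** (GTTs): each model's predicted readouts under all
  2^k input combinations — models sharing a GTT are experimentally
  indistinguishable,
- **core predictions** (conditions where every behavior agrees) and
  hierarchical clustering of behaviors,
- **discriminating experiments**: a provably minimum set of conditions
  separating every pair of behaviors (a set cover over GTT pairs), plus the
  simplest maximally informative single experiments.

Enumeration is exact and complete: models are scored with integer
arithmetic on the discretization grid (no floating-point ties) by a
bit-parallel scan of the search space, cross-checked in the test suite
against a per-model brute force.

## Worked example

Generate a synthetic study (a signed DAG, a hidden ground-truth model, and a
noisy 8-condition measurement panel), then learn and characterize the family:

```
$ logicfam synth --seed 28 --n-nodes 10 --n-stimuli 3 --n-readouts 2 \
    --n-inhibitables 1 --edge-prob 0.35 --max-gate-size 3 \
    --noise-sd 0.05 --n-conditions 8 --max-hyperedges 18 -o study
synthetic study written to study (18 candidate hyperedges)

$ logicfam preprocess study/network.sif study/data.csv --max-gate-size 3 -o hypergraph.csv
6 nodes, 7 edges after compression; 18 hyperedges; search space 2^18 = 262144

$ logicfam learn study/network.sif study/data.csv --max-gate-size 3 --fit-tolerance 0.1 -o run
2 models within tolerance (MSE_opt=0.0007125, size_opt=3); written to run

$ logicfam analyze run study/data.csv
1 always / 15 never / 2 variable hyperedges; 1 exclusive pairs

$ logicfam behaviors run study/data.csv
1 GTTs over 2 models; 16/16 core conditions
```

Reading the output: of 262 144 candidate models, exactly two fit the data
within 10% of the optimal MSE at optimal size. They differ in one mutually
exclusive gate pair (`run/exclusive_pairs.csv`):

```
side_a,freq_a,side_b,freq_b
+n01;+n02->n09,0.5,+n02;-n08->n09,0.5
```

— two interchangeable mechanisms for activating `n09`. Both models have the
*same* Global Truth Table (1 GTT, and all 16 input combinations are core
predictions), so no experiment on these inputs and readouts can tell them
apart: deciding which mechanism is functional requires measuring or
perturbing new species. This is the method's central output — not a single
network, but the precise extent of what the data does and does not
determine.

All outputs are machine-readable: `run/family.csv` (one 0/1 row per model
over canonical hyperedge ids, with exact scores), `metadata.json`,
`frequencies.csv`, `gtt_groups.csv`, `core_predictions.json`,
`gtt_dendrogram.nwk`, `experiments.csv`, `discriminating_set.json`.

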