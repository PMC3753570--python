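# Methods

## Model semantics

A logic model over the expanded hypergraph assigns each node the update rule

    v(t) = OR over selected gates g with target t of AND over (s, sign) in g of lit(s, sign)

where `lit(s, +1) = v(s)` and `lit(s, -1) = NOT v(s)`. Gates containing a
node with both signs (p AND NOT p) are never generated — they are constantly
false. A node with no selected incoming gate is constantly 0 unless clamped.

Simulation of a condition clamps all stimuli (1 if stimulated, 0 otherwise)
and clamps inhibited nodes to 0 — the drug blocks the kinase's *activity*,
overriding its formula — then starts every free node at 0 and applies
synchronous updates until a fixpoint. The fixpoint is the quasi steady
state compared against early-time measurements; at a fixpoint every free
node satisfies its formula exactly, which the test suite asserts on random
models.

**Non-convergence.** With feedback loops a synchronous trajectory may enter
a limit cycle. The update budget is `max_steps = 3 x |V|` steps; if no
fixpoint is reached, a second window of the same length is run and any node
that changes during the window is reported *undefined*, while nodes constant
over the window keep their value. This rule is deterministic, identical in
the scalar and bit-parallel engines, and exact for acyclic hypergraphs
(which converge within |V| steps). Undefined predictions are penalized in
scoring with the maximum squared residual 1 — a conservative choice that
keeps the objective total on cyclic networks — and participate in GTT
equality as a third symbol, since two models differing only in whether they
settle are in principle experimentally distinguishable. A window shorter
than a long limit cycle could misclassify a node as stable; with the 3|V|
default we have not observed this on the scales tested.

## Exact scoring

Observations are discretized onto the integer grid 0..10^p (default p = 2,
i.e. a 0.01 grid; ties round half away from zero). The sum of squared
residuals is then an integer scaled by 10^(2p), so optimality, ties, and
tolerance thresholds are decided in exact arithmetic: a model is in the
family iff `sse <= floor((1 + eps) * sse_opt)` with `eps` taken as the exact
decimal fraction (0.1 means exactly 1/10). Missing measurements are excluded
from the residual sum, never imputed. The tolerance is multiplicative on
MSE and absolute on size; `size_bound="optimal"` resolves to the optimal
size, which together with the MSE bound means the zero-tolerance family is
exactly the set of lexicographic optima.

## Enumeration backend

The learning objective does not decompose over hyperedges — gates cascade
through the network, so the fit contribution of one gate depends on every
other selection. The native backend therefore makes no pruning claims: it
is a complete, exact scan of all 2^|E| selections, evaluated in bit-parallel
numpy batches (models are bitmask integers; one boolean array per node holds
that node's state across the whole batch, and each synchronous step is a few
vectorized AND/OR operations per gate). Chunking keeps memory flat
(default chunk 2^20 models); the scan is capped at |E| = 26 by default and
fails loudly beyond it. An external complete-solver backend is an interface
extension point (`backend="external-solver"`), not bundled; instances at
the published case-study scale (|E| = 130) require one.

Correctness of the scan rests on a dual-route check: the scalar
implementation (`logicfam.model.simulate` / `score`) is the reference
semantics, and the test suite asserts entry-for-entry agreement of the
vectorized engine with it, plus set-equality of the enumerated family with
a per-model brute force on dozens of random instances across tolerances.

Models are output in canonical bit-vector lexicographic order (gate 0
first), making runs byte-identical and diffs meaningful. A safety cap
(default 10^6 family members) aborts enumerations whose tolerance admits
combinatorially exploding families, with instructions to tighten it.

## Compression and expansion

Compression removes undesignated nodes that cannot influence any readout or
cannot be reached from any stimulus/inhibitable, then iteratively collapses
remaining undesignated nodes, multiplying edge signs along u -> x -> w
(cross product over all in/out pairs). A collapse that would create a
self-loop is skipped and the node kept — removing it would change fixpoint
semantics. Parallel edges of equal sign merge; opposite signs are both kept
(they yield distinct literals). Designated nodes are never removed; a
readout left without regulators is kept and reported as a warning.
Published compression routines for this problem differ in details (e.g.
treatment of multi-in/multi-out intermediates); reproducing a specific
tool's gate count exactly may require matching its variant.

Expansion emits, per node, every non-empty sign-consistent regulator subset
up to `max_gate_size` (default 4; `None` for unbounded, giving 2^r - 1 gates
for r regulators). The cap that produced the published case-study count is
not stated in the original report, so it is configurable and recorded in
run metadata. Hyperedge ids are canonical — sorted by (target, signed
source tuple) — and invariant under input file line order.

## Behaviors and experiment design

The GTT input space is every on/off assignment of all stimuli and all
inhibitables (2^k conditions, canonical binary order, capped at k = 20),
including conditions that inhibit unmeasured species. Behavior grouping is
bit-parallel across the family per condition. Hierarchical clustering of
GTTs uses average linkage on Hamming counts over the concatenated prediction
vectors (linkage choice is ours; the merge heights, not the rendering, are
the output — trees are written as Newick).

A condition separates a GTT pair if the tables differ there in at least one
readout with both values defined; undefined predictions never separate
(conservative: a non-settling prediction promises no observable value).
Pair-level separation counts 1 per condition regardless of how many readouts
differ; per-readout difference counts are reported alongside. The minimum
discriminating set is found by branch-and-bound set cover (branch on the
uncovered pair with fewest covering conditions; greedy solution as incumbent;
disjoint-pair lower bound; dominance pruning of conditions whose pair set is
contained in another's), exhaustively verified in tests against subset
search. Beyond 5000 candidate conditions after pruning only the greedy
cover and the lower bound are reported, flagged as not proven minimal.

## Synthetic studies

The generator emulates the structure the method assumes: a signed DAG
(optionally with feedback) over topologically ordered nodes, sources as
stimuli, sinks as readouts, inhibitables sampled from intermediate nodes; a
hidden ground-truth model sampled with one gate per target (occasionally
two) biased toward small gates so that the size objective is informative;
and measurements obtained by simulating the truth under a panel of input
assignments, plus additive Gaussian noise truncated to [0, 1]
(`noise_sd = 0.05` is our bench default for normalized phospho data; the
10% MSE tolerance is the conventional allowance for that error). A
non-settling truth prediction is emitted as a missing measurement. Panels
may cover all 2^k input combinations or a random subset — real perturbation
panels probe a small fraction of the input space, and partial panels are
what produces non-identifiable (tied) models at desk scale.

What passing tests on these studies show: the enumeration is complete, the
truth's behavior is always among the optima on noise-free data, and is
recovered in a large majority of noisy instances. What they do not show:
real phospho-proteomics error is not truncated-Gaussian (it has systematic
components and intermediate activation levels), real PKNs are far denser,
and desk-scale instances (|E| <= ~18 in tests, chosen to keep the
brute-force oracle affordable) cannot exhibit the thousands-strong families
seen at case-study scale.

## Problem sizes used by the bundled checks

The test suite cross-checks enumeration against brute force on 50+ random
instances of up to 14 hyperedges across tolerances {0, 0.02, 0.1}, checks
noise-free truth recovery on 20 instances (up to 16 hyperedges), fixpoint
correctness on 1000 random simulations, and design minimality on 40 random
instances of up to 6 behaviors. `scripts/acceptance.py` runs a reference
study with up to 18 hyperedges plus the same oracle checks at reduced
counts. These sizes are the package's own choice of a desk-scale testbed;
all are configurable.

## Known limitations

- The native backend is exhaustive; |E| > 26 needs an external complete
  solver behind the provided interface.
- Synchronous-update limit cycles are classified by a finite window (see
  above), not by exact cycle detection.
- Only pairwise mutual exclusivity is reported (k-tuples of modules with
  k > 2 are not searched).
- Normalization offers min-max scaling and a strict passthrough; saturation
  (Hill/EC50) transforms of raw intensities are out of scope.
- MIDAS handling follows the column-prefix dialect with the trailing-"i"
  inhibitor convention; multi-cell-line files beyond ignoring the CellLine
  column are out of scope.
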