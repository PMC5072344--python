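# Methods

## Model and update semantics

A network is an ordered node list with one Boolean rule per regulated node;
nodes without a rule are external inputs and hold whatever value the
initial state assigns them. Updates are **synchronous and deterministic**:
every regulated node evaluates its rule on the previous state
simultaneously. Under this scheme the state space is a functional graph, so
every trajectory is eventually periodic and the attractor taxonomy is
exactly {point, cycle}. Asynchronous and multi-valued semantics are out of
scope by design; the phenotype definitions below (e.g. a node "50 % ON" in
an alternating cycle, Rho oscillation) are only meaningful under
deterministic synchronous update.

Rules are compiled to truth tables over their parents (≤ 16 parents by
default). This makes logical equivalence decidable by enumeration — the
parser/serializer round-trip is tested as truth-table equality, not string
equality — and makes the update a table lookup.

**Pinning** holds a node at 0/1 regardless of its rule and models both
mutations (loss = pin 0, gain = pin 1) and therapeutic control. Pins are
overrides, never rule rewrites: serialization emits them as a separate
`@pin` section so the underlying logic is preserved. When pins are applied
on top of existing pins the later application wins with a warning — this
supports control-on-top-of-mutation experiments, where a control could in
principle revisit a node (mutated nodes are nevertheless excluded from the
control search space, see below).

## Attractor landscape

`find_attractor` follows a trajectory with visited-state hashing (states
packed to integers, one bit per node) and returns the cycle between the
first repeat, canonicalized by rotating the cycle to start at its smallest
packed state; the canonical key is rotation-invariant by construction.

`enumerate_landscape` computes exact basins for networks with ≤ 20 free
(non-pinned) nodes: all 2^f states are built at once, successors are
computed in one vectorized sweep, and attractors are found by pointer
chasing in the functional graph. It is the brute-force oracle for the
sampling path.

`sample_landscape` estimates basins from uniformly drawn initial states
(free nodes uniform, pinned nodes held). Because the dynamics are
deterministic, trajectories that meet share their future: the sampler
memoizes successor pointers and attractor assignments across samples, so
each distinct state costs one rule evaluation ever. This is an exact
optimization — the returned counts are identical in distribution (and,
given a seed, identical in value) to walking every sample independently.

The input condition (growth inputs ON: EGF, ECM, Wnt; stress/damage inputs
OFF) is applied as pins before sampling, mirroring a constant extracellular
environment.

Default sample size is 10,000 initial states per landscape, with the
sampling seed recorded in the result; the mutation sweep spawns an
independent child seed per stage from one root seed, so stages are
independent but the sweep is reproducible end to end.

## Phenotype classification

Classification reads only the attractor's marker-node columns:

- **proliferative** — the attractor is cyclic and the cyclins switch ON in
  cell-cycle order. "Onset" is an index where a cyclin goes 0→1 between
  consecutive cycle steps (circularly). The test asks for one onset per
  cyclin and a rotation placing them in the order D, E, A, B (ties
  allowed). A CyclinD that is constitutively ON has no onset but still
  leads the cascade: it is treated as a wildcard anchored at CyclinE. This
  is the weakest reading that makes both a regulated cascade and a
  constitutively driven one proliferative — without the wildcard, the
  abnormal case (CyclinD never OFF) could not be proliferative at all,
  contradicting its definition.
- **normal regulation** — proliferative and CyclinD is *not* ON in every
  cycle state; constitutive CyclinD marks oncogene-like, abnormal drive.
- **metastatic** — E-cadherin OFF in every state, MMP ON in every state
  (strict quantifier; an "ON in ≥ half the states" variant would be easy to
  add but the strict default is reproducible), and Rho non-constant over
  the cycle. A point attractor can therefore never be metastatic — Rho
  cannot oscillate at a fixed point.
- **apoptotic** — caspase ON in every state. Apoptosis is reported as an
  orthogonal flag, not folded into the class taxonomy: the three
  class-defining criteria (normal regulation, proliferative, metastatic)
  do not mention caspase, and keeping the flag orthogonal avoids an
  arbitrary precedence rule.

The three criteria define 8 classes; since normal regulation implies
proliferative, two of the eight combinations are unreachable but kept so
the taxonomy is a total map. Headline classes: *normal proliferation*
(regulated cycling without metastasis), *cancer progression* (abnormal
cycling with metastasis), *quiescent* (neither proliferative nor
metastatic). Classification is rotation-invariant (tested).

## Dose–response protocol

Input intensity p ∈ [0, 1] is the input's average ON fraction over the
run. By default the input is redrawn each step as an independent
Bernoulli(p) (the input "flickers" with mean p); a deterministic duty-cycle
mode (Bresenham spreading of ON steps) is available when run-to-run
variance must be zero. Readout is steady-state activity: the mean of the
output node over the last 100 steps of a 1,000-step run (defaults),
averaged over random initial conditions. Other inputs are held at a fixed
baseline, all-OFF unless configured otherwise. The window length is
uninfluential on the fixtures tested (30/50/150 vs 100 correlate > 0.95),
which is why the default window is not treated as a tuning parameter.

## Reverse control by genetic algorithm

The control search asks for a minimal pin-set under which all initial
states converge to a desired phenotype group (quiescent or normal
proliferation). Chromosomes carry one ternary gene per node — unselected /
pin-0 / pin-1 — so pin directions are learned, not prescribed. The fitness
is B³·(n−ΣXᵢ)², doubled exactly when B = 1; B is the desired-group basin
fraction estimated from 1,000 sampled trajectories (default). The B = 1
doubling is decided on counted samples — every sample converged — never on
a float tolerance, and the final reported set is re-estimated with a fresh
seed at 10× the samples, since a sampled B = 1 is optimistic.

GA mechanics (all in `GAConfig`, all logged): population 100, tournament
selection (size 3), uniform crossover (rate 0.9), per-gene mutation 1/n,
elitism 1, 200 generations with early stop after 30 stagnant generations.
These are standard choices where no principled value exists. Determinism:
every chromosome's basin sample is seeded by (search seed, CRC32 of the
gene vector), so fitness is a pure function of the chromosome and the whole
search is reproducible; the empty chromosome is always seeded into the
initial population so an already-satisfied landscape resolves to the empty
control set. Ties in final fitness break toward fewer selected nodes, then
lexicographic node order.

Mutation-pinned nodes and input-condition nodes are ineligible as controls:
the former because a therapy cannot un-mutate a driver gene, the latter
because the input condition is part of the experimental setup, not a drug
target.

`essentiality` of a single control node is the desired-group basin fraction
achieved by pinning that node alone on top of the stage's mutations —
always in [0, 1], directly comparable to the full set's achieved B.

`exhaustive_control_search` enumerates every pin-set up to a size cap with
exact (enumerated) basins; on the toy fixture it certifies the GA's answer.

## Drug-target enrichment

A one-sided two-sample chi-squared test compares the target frequency in a
control set against pooled uniform random draws of the same size (1,000
draws by default; the draw count is a logged parameter, as is the seed).
Continuity correction is off by default; for very small tables a
Monte-Carlo one-sided p (fraction of random sets with at least as many
targets) can be reported alongside. One-sided p = two-sided/2 when the
control frequency exceeds the random frequency, else 1 − two-sided/2. The
target list is a user-supplied TSV; no database retrieval is performed.

## Synthetic data

`random_network` draws weakly connected random Boolean networks (each
regulated node anchors at least one parent in the node prefix; rules are
random AND/OR/NOT compositions with configurable negation and operator
bias). These exist to drive property tests — round-trips, sampled-vs-exact
basin agreement — where biological structure is irrelevant.

The **toy colorectal-like fixture** (20 nodes, 16 free after the input
condition, so 65,536 states enumerate in milliseconds) is authored by hand
so its landscape is stable and interpretable. Its design:

- beta-catenin, Snail, MMP and P115RhoGEF are *latches* (`X, X | trigger`)
  whose triggers are gated by the tumor-suppressor analogs — APC gates
  beta-catenin, PTEN gates Snail, TP53 gates MMP, and the RasGAP-inhibited
  KRAS gates P115RhoGEF. Each driver mutation (APC:0, KRAS:1, PTEN:0,
  TP53:0) permanently opens one latch, so the metastatic basin (which
  requires all four latches) grows strictly at every stage: exact fractions
  30.1 % → 35.5 % → 40.6 % → 62.5 % → 100 %.
- the cyclin cascade (D → E → A → B, with CyclinB resetting CyclinD) is
  driven by beta-catenin, so proliferation and all metastasis triggers
  share one hub. Pinning beta-catenin OFF is therefore the unique
  single-node control restoring 100 % quiescence at every stage — verified
  by exhaustive pin-set search and recovered by the GA.
- unmutated suppressors are constant-1 rules; their *initial* states are
  free, which gives the baseline (stage-0) landscape its partial basins:
  transient windows at t = 0 can fire latch triggers before the
  suppressors settle. This stands in for the cell-to-cell variability that
  makes basins non-degenerate in large models.

What the fixture does **not** emulate: the scale (hundreds of nodes), long
transients, dozens of external inputs, redundant parallel pathways, or any
quantitative basin value of a real curated signaling model. Passing the
fixture tests shows the machinery is correct (classification, enumeration,
sampling, search), not that any particular biological model is; real
models are consumed as `.bnet` + YAML inputs
(`scripts/convert_model_tables.py` is the documented adapter stub for
publisher-specific logic-table layouts).

## Numerical and degenerate-input choices

- States pack to arbitrary-precision ints (bit per node), so node count is
  unbounded by machine words; enumeration is capped at 20 free nodes.
- Attractor-search cap (`max_attractor_steps`, default 10,000) exists only
  to surface misconfiguration; a deterministic finite system always
  repeats.
- Sampled basin fractions are binomial; oracle agreement is asserted at 3
  standard errors with a violation budget at the nominal 0.27 % exceedance
  rate (and a hard 6-SE cap), since ~10³ simultaneous 3σ checks are
  expected to produce a few nominal exceedances even for a perfect
  implementation.
- "No significant change" between landscape stages, where needed
  qualitatively, means < 5 percentage points per class.
- Empty landscapes, zero samples, windows longer than trajectories,
  conflicting simultaneous pins, and unknown nodes all raise with specific
  messages rather than propagating NaNs.

## Known limitations

- Synchronous update only; attractors of the same model under asynchronous
  update can differ qualitatively.
- The GA offers no optimality certificate on large networks; the
  exhaustive certificate exists only where enumeration is feasible.
- The Bernoulli input convention makes dose–response curves stochastic;
  the duty-cycle mode trades that for weak dependence on cycle phase.
- Basin estimation assumes uniform initial states, which weights all
  molecular configurations equally — a modeling convention, not a
  biological claim.
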