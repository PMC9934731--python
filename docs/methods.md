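# Methods

## The stochastic update process

`cartsim` simulates probabilistic Boolean networks in the
activation/degradation-propensity formalism. A model is a set of nodes,
each with a Boolean update rule over node names and two probabilities:
`p_a`, the chance that a node whose rule is satisfied but which is OFF
switches ON during an iteration, and `p_d`, the chance that a node whose
rule is unsatisfied but which is ON switches OFF. When rule value and node
state agree nothing happens; in particular a node with a constant-TRUE rule
can never degrade. The propensities model the fact that not every
molecular process fires in every time window: high `p_a` with low `p_d`
yields the all-or-none activation with slow decay seen in T-cell signaling
kinetics.

One *iteration* visits every node exactly once, in a uniformly random
permutation drawn fresh each iteration (Fisher–Yates over the node list; no
node priorities). Updates are truly asynchronous: a node visited later in
the permutation sees the values already written by earlier visits of the
same iteration. This is the standard resolution of random-order updating
in asynchronous Boolean-network practice; the alternative (all updates
against the frozen previous state) is available as the explicitly flagged
`update_mode="synchronous"` variant and is not the default semantics.

One uniform draw is consumed per node per iteration whether or not a
switching event is possible, which keeps the replicate's random stream
aligned regardless of trajectory.

## Initial conditions and input semantics

Simulations start all-OFF except: LCK starts ON (basal pools of active LCK
are maintained in resting T cells); each *active* input ligand starts as an
independent fair coin; perturbation-forced values take precedence over
both. Active inputs are rewired to constant-TRUE rules — they re-engage
through `p_a` and never satisfy the degradation condition — realizing
continuous ligand exposure in a closed effector–target loop. Inactive
inputs are constant-FALSE and stay 0. The propensity reading of `p_a`/`p_d`
(gate on the OFF→ON and ON→OFF transitions respectively, rather than on
rule evaluation itself) follows the stochastic discrete dynamical systems
formalism this engine implements.

## Ensembles, readouts, and errors

An ensemble runs `R` independent replicates for `T` iterations; the
reported activity of node `i` at iteration `t` is the fraction of
replicates with the node ON. The steady fraction is the mean activity over
the last `W` iterations; for the packaged network's readouts these are
reported as `p_cfunc`, `p_cinhib`, `p_tapop`. Standard errors are computed
from the replicate-level variance of per-replicate window means (each
replicate contributes one number in [0, 1], so the SE correctly accounts
for within-window autocorrelation).

Defaults: `R = 10,000`, `T = 100`, `W = 20`, `p_a = 0.5`, `p_d = 0.05`,
all configurable per scenario. `T = 100` is comfortably past the observed
relaxation of the packaged network (readout trajectories plateau by
`t ≈ 50–60`); `W = 20` averages over the plateau without touching the
transient. Test and acceptance runs use `R` between 5,000 and 10,000,
which puts binomial standard errors at 0.005–0.007 — small enough to
resolve every ordering the experiments assert.

Reproducibility: replicate `r` runs on its own random stream seeded from
entry `r` of `SeedSequence(base_seed).generate_state(R)`, so a fixed
(model, scenario, seed) gives byte-identical results and any single
replicate can be replayed in isolation. The heavy loop is numba-compiled;
rules are flattened to a postfix bytecode interpreted per update.

## Exact oracle

For models with at most 6 nodes the package constructs the exact
one-iteration Markov kernel on the 2^n joint states: the average over all
n! permutations of the ordered product of per-node single-site kernels,
each encoding the propensity-gated update of one node. The engine is
validated against this kernel (joint distribution within total-variation
0.02 at R = 10,000 on random 4-node models, marginals within 3 binomial
standard errors) and against closed forms: a constant-TRUE node obeys
P(t+1) = P(t) + (1 − P(t))·p_a exactly in expectation, and a
self-inhibiting node (`A = !A`) is a two-state birth–death chain with
stationary ON-fraction p_a/(p_a + p_d) = 10/11 at the defaults. The size
cutoff (6) keeps the oracle's 2^n × n! cost trivial; it is a validation
tool, never the production path.

## Structural zeros

A node outside the *activatable closure* — the least fixed point of "a
node can be ON if it starts ON or its rule can evaluate true using only
activatable nodes (all others pinned 0)" — has exactly zero activity for
all time, not merely small activity. Knockouts (forced initial 0 with
`p_a = 0`) are pinned 0 inside every rule when computing the closure. The
test suite asserts the engine never violates a structural zero; notable
consequences in the packaged network: with no active ligands `TAPOP ≡ 0`;
with only tumor antigen, `PD1 ≡ 0` and `BATF ≡ 0`; a ZAP70 knockout forces
`p_cfunc = 0` because NFAT requires calcineurin or P38, both strictly
downstream of ZAP70. Note the closure starts from negation-satisfiable
rules too: the immune synapse `IS = !CASP3CASP7` is activatable from the
all-zero state.

## The packaged CAR T-cell network

59 nodes, one per species of the curated interaction network (CD3ζ + CD28
CAR design), all at the default propensities. Roles: four ligand inputs,
three readouts, the rest internal. Compartments tag each node as
`cart` (the T-cell's own machinery), `tumor` (TA, FAS, CASP3CASP7, TAPOP)
or `interface` (ligand presentation and the immune synapse); the default
perturbation-scan target set is the 45 internal `cart` nodes.

Four printed defects in the source rule table are corrected in the
packaged file and recorded in its `@meta` entries: the LCK rule's two
unclosed parentheses (minimally balanced, preserving the printed token
sequence), the PERGRZM/PERGRZB naming inconsistency (canonical PERGRZB,
alias accepted), CINHI → CINHIB, and the CFUNC rule's reference to a
symbol (CDSYF) defined nowhere (dropped; CFUNC = AP1 & NFAT & MTORC1). The
parser itself is strict — no auto-repair of user files; the corrections
live only in the curated asset. A user can re-add a CDSYF node explicitly
if they have a definition for it. The rule table is otherwise implemented
exactly as printed, including choices a modeler might question: PI3K is
activated by CD28 | CTLA4 with no SHP2 inhibition, SLP76 = ZAP70 | LAT
makes LAT partially redundant, and PD1ex is a sink that does not gate PD1.

### Ligation scenarios

Named active-input sets: A = {TAex}; B = A + IL2ex; C = B + PDL1L2ex +
CD8086ex; D = C minus PDL1L2ex; E = C minus CD8086ex. All ligands engage
simultaneously at t = 0 (no staggered onset). Reproduced orderings at
R = 5,000: p_cfunc(B) > p_cfunc(A) > p_cfunc(C); p_cfunc(D) > p_cfunc(C);
p_cfunc(E) ≈ p_cfunc(C); p_tapop(C) > 0. Under scenario C the collapse of
function and cytotoxicity is nearly complete (steady fractions of order
10⁻³) because continuous inhibitory ligation holds SHP2 ON almost
permanently; apoptotic signaling remains positive but rare. Blocking
PDL1L2 (D) restores function almost to B; blocking CD8086 (E) does not,
since PD1 alone keeps SHP2 engaged.

### Perturbation scan

Knockout = initial 0 with `p_a = 0`; overexpression = initial 1 with
`p_a = 1`, leaving `p_d` at its default so an overexpressed node still
transiently degrades when unsupported (a strict clamp with `p_d = 0` is
available, not default). Percent change of each readout's steady fraction
is reported against a control run (scenario C by default) under the same
R/T/W/seed policy, unclipped, with NaN (never 0) where the control
fraction is zero; raw fractions and replicate-level standard errors are
retained alongside. Control and perturbed ensembles use independent
streams, so percent changes carry Monte-Carlo error of the order of the
reported SEs — consumers should compare differences to 3 combined SEs, as
the tests do.

## Design choices where the design was open

- **Readout nodes are ordinary nodes** (default propensities), not
  instantaneous functions of their regulators; their steady fractions
  therefore lag their inputs slightly but share the same plateau.
- **Half-maximum ordering** along a signaling cascade is only asserted for
  strict dependency chains (each node's activation requires the previous
  node). Nodes with parallel inputs — ERK via GRB2SOS, for example — can
  legitimately cross half-maximum before an upstream arm of a different
  path.
- **Random models** for engine validation use depth-≤3 rules over 4 nodes
  with `p_a ∈ [0.2, 1]`, `p_d ∈ [0, 0.3]`: small enough for the exact
  oracle, varied enough to exercise NOT/AND/OR nesting and asymmetric
  propensities.

## What the synthetic experiments do and do not show

The generator-driven validation (random small models vs. the exact kernel,
closed-form chains) establishes that the simulator implements the intended
Markov process. The packaged-network experiments show the *logic* of the
curated rule set under sustained ligand exposure. They do not calibrate to
real time (iterations are arbitrary units ordered like biological event
sequences), do not model CART differentiation states, CD4/CD8 subsets,
terminal exhaustion commitment, 4-1BB costimulatory designs, receptor
affinity, or tumor-cell population dynamics, and activity fractions are
population proportions, not concentrations. Inhibition here is transient
by construction — there is no absorbing exhausted state — so scenario C
reflects continuous competition between activating and inhibitory signals,
not a committed fate.

## Numerical notes

- Activities are exact ratios `count/R`; trajectory CSV and summary JSON
  are byte-stable across runs and platforms for a fixed seed.
- The model text format stores propensities with `repr` round-tripping, so
  save → load is structurally identical.
- Percent changes are computed as `100·p/p_ctrl − 100`, which returns
  exactly −100 for structurally-zero perturbed fractions.
- Degenerate inputs: empty models, duplicate names, unresolved rule
  references, out-of-range propensities and non-constant input rules are
  all rejected at load time with a full list of problems; the oracle
  refuses models with more than 6 nodes, stating the limit.
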