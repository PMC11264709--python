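# Methods

## Scope and model class

`pathway-evolver` simulates the evolution of a *fixed-topology* metabolic
pathway represented as a deterministic kinetic model: species
concentrations obey `dC/dt = N v(C, θ)` where `N` is the stoichiometric
matrix and each entry of `v` is an explicit enzyme-kinetic rate law
(Michaelis–Menten-style expressions over the operator set
`{+, −, ×, ÷, power, exp}`). Boundary species (network inputs/outputs such
as extracellular glucose) are clamped at constant concentration and are
excluded from both integration and mutation. The evolutionary regime is a
mutation–selection (origin–fixation) model: the population is a single
parameter state; each proposed mutation either fixes population-wide or is
lost before the next arises. There is no standing variation,
heterozygosity, or soft-sweep dynamics, no stochastic (Gillespie)
kinetics, no gene duplication, and no temporal regulation of the network.

## Steady state

A steady state is a concentration vector where every non-boundary
derivative vanishes, `max_i |dC_i/dt| ≤ tol` with `tol = 1e-9`
(absolute, concentration units per time; configurable). The solver is a
deterministic hybrid: damped Newton iteration on the free coordinates with
a forward-difference Jacobian (step `1e-7·max(|C_j|, 1)`), interleaved
with stiff forward integration (LSODA) over escalating time chunks
(1, 10, 100, … up to a `1e6` time-unit cap) whenever Newton stalls.
Because every post-mutation solve starts from the previous steady state,
the Newton phase almost always converges in a handful of iterations and
the integrator is touched only after large perturbations. Negative
concentrations are clipped to zero between phases. Failure — no finite
root (unbounded accumulation), oscillation, divergence — is an in-band
result (`converged=False`), which the evolutionary layer interprets as
lethality (fitness 0): a cell cannot survive with no flux. Ties and
degenerate cases: an already-steady input is returned (Newton may polish
it further within tolerance); a zero-size free coordinate set (all
species boundary) is trivially steady.

## Mutation model

Per generation and per mutable *functional* parameter (anything that is
not an enzyme concentration), the number of proposals is
Poisson(λ = 0.003). Effects are multiplicative deviations
`θ → θ(1+δ)`, `δ ~ Normal(μ, σ)` with `μ = −1%` (slight functional
degradation) except binding constants at `+1%` (poorer binding ⇒ larger
Km). The paper-level description fixes the means but not the spread; we
default `σ = 1%` — the same scale as |μ|, keeping most effects within a
few percent, configurable via `MutationModel.sigma`. Draws are redrawn
until `1+δ > 0` so kinetic parameters stay positive. Enzyme-concentration
parameters are proposed at rate `λ·k` per reaction, where `k` is the
number of that reaction's mutable functional parameters; this encodes the
assumption that a typical enzyme has about as many expression-affecting
sites as coding sites, and yields a 1:1 aggregate ratio of expression to
functional proposals.

All proposals arising in one generation are applied jointly, the steady
state is re-solved once, and one accept/reject draw decides the whole
set's fate; on rejection the parameter map reverts bit-identically. (A
sequential per-proposal evaluation would multiply solver work for no
behavioral difference at λ = 0.003, where same-generation collisions are
rare.)

## Thermodynamic (Haldane) constraint

For a reversible reaction with equal substrate and product counts, the
equilibrium constant, maximal velocities (or catalytic constants) and
Michaelis constants are not independent:
`K_eq = (V_f/V_r)·ΠKm_P/ΠKm_S`. Groups are collected per reaction from
informatively named parameters; binding constants are paired to
substrates/products by declaration order, and an equilibrium constant (or
derived reverse velocity) that does not appear in the rate law itself is
attached through the shared trailing `_<tag>` of the reaction's parameter
names. Within a group the reverse velocity is *derived*: it is excluded
from direct mutation and recomputed (`V_r ← V_f·ΠKm_P/(K_eq·ΠKm_S)`)
after any mutation to a Km or to the forward velocity, so the identity
holds to ≤ 1e-9 relative error after every fixed mutation. The
equilibrium constant itself is a thermodynamic property of the reaction,
not an enzyme-encoded quantity, and is immutable. Reactions that cannot
be paired (unequal reactant counts, missing members, or an identity
violated at load time) form no group and their binding constants mutate
unconstrained; this is logged.

## Fitness and fixation

Selected fluxes are proportionalized by their reference value recorded at
simulation start (before any mutation): `x = J/(J_start·m)` with
user multiplier `m` (default 1). The raw logistic
`L(x) = 1/(1+e^{10(0.5−x)})` is rescaled to
`score = (L(x) − L(0)) / (L(1/m) − L(0))`, floored at 0, so zero flux
scores 0, the starting flux scores exactly 1, and the ceiling
`(1 − L(0))/(L(1/m) − L(0))` (≈ 1.006783 for m = 1) models diminishing
returns; `m > 1` moves the start away from the ceiling and creates
directional selection. Negative reference fluxes are allowed (the
proportionalization is signed); a zero reference flux on a selected
reaction is a configuration error. Population fitness is the weighted
geometric mean of the scores (zero is absorbing). Fixation follows
Kimura's diffusion result
`P_fix = (1 − e^{−2cN_e sp})/(1 − e^{−2cN_e s})` with
`s = F_new/F_old − 1` and initial frequency `p = 0.5` rather than
`1/(cN_e)`, which gives neutral mutations a 50% fixation chance and
accelerates the neutral walk. Numerics: `|2cN_e s| < 1e-12` returns `p`
exactly (continuous limit); large negative arguments use the asymptotic
`e^{2cN_e s(1−p)}`, which underflows to 0 instead of overflowing.

## Burn-in and equilibrium detection

The root population evolves until mutation–selection equilibrium before
any branching. At every fixation the fitness and all reaction fluxes are
recorded; over non-overlapping windows of 100 fixations the
ordinary-least-squares slope (normalized by the window mean, per
fixation) and the coefficient of variation (sd/|mean|) measure flatness.
Equilibrium is declared when fitness *and* at least 80% of flux series
have `|slope| ≤ slope_tol` and `cv ≤ cv_tol` for five consecutive
windows; the burn-in then continues for as many generations as had
elapsed, doubling the total. The thresholds are not fixed by the
method's description; defaults are `slope_tol = 1e-5` and
`cv_tol = 0.01`, deliberately strict for production runs, and both are
prominent in the configuration (tests and examples use looser values so
toy models equilibrate at desk scale). A window whose mean is zero is
unstable by definition. A `generation_cap` (default 1,000,000) bounds the
burn-in; hitting it returns a cap-reached flag rather than an error.
Root snapshots serialize every float at full precision together with the
RNG state, the fixation series, and the proposal counters, so an
exported-then-resumed run is bit-identical to an uninterrupted one, and
one equilibrated root can seed branching over any tree with the same
starting population parameters.

## Branch-length calibration and tree traversal

The proposal counters record, per category (enzyme concentration vs
functional) and per reaction, when each proposal arrived. The generation
`G` at which the across-reaction average count reaches 7 in *both*
categories defines one calendar unit: under the two-percent rule
(diverging lineages accumulate ~1% sequence difference per Myr each), 1
Myr of branch length maps to `G` generations, and substitutions/site are
converted to percentages with a factor of 100. Where the two categories
cross at different generations the slower governs (the wording "to both
… parameters" is ambiguous between *both* and *their average*; requiring
both is the conservative reading and is what we implement). Models with
no enzyme-concentration parameters calibrate on the functional category
alone. Generation counts per branch are rounded half-up; a zero-length
branch is simulated for zero generations and inherits its parent state
unchanged.

Trees must be rooted (a bifurcating root; anything else is rejected as an
unrootedness signal). Multifurcations below the root are accepted behind
an explicit `allow_polytomy` flag. Traversal is depth-first; each child
branch starts from its parent's exact end state, uses its branch's
population size (constant within the branch, no re-equilibration after a
size change — matching real post-divergence disequilibrium), and draws
from an RNG stream spawned from `(seed, path-to-branch)`, making sibling
branches statistically independent while the entire run replays from one
seed. Lineages concatenate the branch traces from the root to each
external node and are numbered by their terminal node.

## Reporting

For every lineage and branch, the percent change
`100·(end − start)/start` between the end-of-burn-in value and the
end-of-branch value is tabulated over all model values (fitness, each
reaction flux, each non-boundary steady-state concentration, each
parameter). Cells with a zero start are undefined and serialize as `NA`,
excluded from normalization. The normalized twin divides each column by
its maximum absolute value, mapping cells into [−1, 1] with the extreme
cell at ±1. Replicates are averaged cell-wise on the *raw* percent scale
and then normalized (normalizing before averaging would let a single
extreme replicate rescale the others; averaging first keeps the cells on
a common physical scale — the alternative order is not distinguishable
from the method's description and this choice is fixed here). All tables
are TSV with 17 significant digits; a manifest lists files with SHA-256
checksums. Heatmap plots are optional presentation (`plots=True`) and
carry no information the TSVs lack.

## Fixture models and what they do (and do not) show

The test fixtures are built for analytic transparency, not biological
realism. The irreversible chain (constant source `v0`, MM steps) has the
closed form `S_i* = Km_i·v0/(Vmax_i − v0)` with all fluxes `v0`, which
makes it the solver's oracle — and, because its flux is source-limited,
every mutation is exactly flux-neutral, isolating the neutral fixation
class (P_fix = 0.5). The reversible chain enters from a constant-
concentration boundary species through enzymatic steps, so its drain flux
depends on every parameter: it exhibits the deleterious-biased fixation
spectrum, fitness equilibration, and Haldane-coupled dynamics. Its
optional decoy subnetwork is detached from the main pathway and
contributes an exactly neutral mutation class alongside selection. The
branched fixture (one input, two competing outputs) exercises
multi-target selection and the geometric-mean fitness. None of these
reproduce any published model's kinetics; passing tests demonstrate the
machinery's correctness on networks small enough to verify, not the
behavior of genome-scale reconstructions. Problem sizes in the test and
acceptance runs (chains of 1–5 steps, burn-ins capped at a few thousand
generations, 10^5-draw stochastic checks) are chosen so the full suite
verifies in seconds while leaving every estimate's standard error far
inside its tolerance.

## Numerical and design notes

- Rate laws are parsed with sympy into expression trees and compiled once
  per model into vectorized evaluators; the supported operator set is a
  superset of the usual Michaelis–Menten-family laws.
- SBML Level 2/3 is supported for models with explicit kinetic laws;
  events, rules, constraints, initial assignments and delays raise
  explicit unsupported-feature errors; compartments are collapsed to
  volume 1; function definitions are inlined on read.
- Parameter roles come from case-insensitive name prefixes
  (`Km*/Ki*` → binding, `Vmax*/Vf*` → forward velocity, `kcat*` →
  catalytic, `Keq*` → equilibrium, `E_*/conc_*` or a modifier-only
  species name → enzyme concentration), with explicit per-parameter
  overrides taking precedence — informative naming is assumed, as is
  conventional for curated kinetic models, and anything unmatched falls
  into an `other` role that still mutates at the default −1% bias unless
  excluded.
- Determinism is end-to-end: a fixed seed reproduces every output file
  byte for byte; all stochasticity flows through numpy Generators seeded
  from one SeedSequence.

## Known limitations

- The solver's steady states are those reachable from the supplied
  initial concentrations; multistable networks are followed through
  whichever basin the trajectory selects, with no bifurcation analysis.
- The Haldane machinery requires equal substrate/product counts and
  informative naming; reactions outside that envelope evolve their
  binding constants unconstrained.
- Branch-length calibration inherits the two-percent rule's
  vertebrate-centric assumptions; for taxa with very different molecular
  clocks the generations-per-Myr anchor is a convention, not an estimate.
- Runtime scales with fixation count × steady-state solve cost; large
  SBML models with slow solves remain expensive even though toy models
  run in seconds.
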