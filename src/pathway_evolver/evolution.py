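"""Mutation-selection engine.

Each discrete generation, every mutable parameter receives a Poisson-
distributed number of mutation proposals (rate 0.003 per functional
parameter; enzyme-concentration parameters are driven at rate 0.003 x k,
where k is the number of that reaction's mutable functional parameters, so
that expression-level and coding-level proposals arrive in a 1:1 aggregate
ratio).  Proposed effects are multiplicative deviations drawn from a normal
distribution centered at -1% (binding constants: +1%, since poorer binding
means a larger Km), truncated so values stay positive.  Mutations to a
Haldane-group member trigger recomputation of the group's reverse velocity
so that the thermodynamic identity is preserved.

Fitness of a candidate parameter set is the weighted geometric mean of
per-target scores derived from the logistic

    F(x) = 1 / (1 + exp(10 (0.5 - x)))

of the proportionalized flux x = flux / (start_flux * multiplier), rescaled
so that zero flux scores 0 and the starting flux scores 1.  The candidate
fixes with Kimura's diffusion probability

    P_fix = (1 - exp(-2 c Ne s p)) / (1 - exp(-2 c Ne s))

with selection coefficient s = F_new / F_old - 1, ploidy c, effective
population size Ne, and initial frequency p (0.5 by default, which gives
neutral proposals a 50% chance of fixing).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .model import (
    ROLE_ENZYME_CONC,
    ROLE_BINDING,
    HaldaneGroup,
    KineticModel,
)
from .steady_state import (
    DEFAULT_STEADY_TOL,
    DEFAULT_TIME_CAP,
    solve_steady_state,
)

NEUTRAL_GUARD = 1e-12
DEFAULT_INITIAL_FREQUENCY = 0.5


class ConfigurationError(ValueError):
    """Invalid run setup (zero start flux, no steady state, bad weights)."""


# ---------------------------------------------------------------------------
# Configuration & state types


@dataclass(frozen=True)
class MutationModel:
    """Tunable knobs of the proposal process."""

    rate: float = 0.003               # Poisson lambda per functional parameter
    mean_shift: float = -0.01         # mean multiplicative effect
    binding_mean_shift: float = 0.01  # binding constants drift up (poorer binding)
    sigma: float = 0.01               # sd of the effect distribution
    joint: bool = True                # evaluate same-generation proposals jointly


@dataclass(frozen=True)
class SolverOptions:
    steady_tolerance: float = DEFAULT_STEADY_TOL
    time_cap: float = DEFAULT_TIME_CAP


@dataclass
class SelectionTarget:
    reaction_id: str
    weight: float = 1.0
    multiplier: float = 1.0

    def __post_init__(self):
        if self.weight <= 0:
            raise ConfigurationError(
                f"selection weight for {self.reaction_id!r} must be > 0")
        if self.multiplier <= 0:
            raise ConfigurationError(
                f"multiplier for {self.reaction_id!r} must be > 0")


def normalize_weights(targets: Sequence[SelectionTarget]) -> list[SelectionTarget]:
    total = sum(t.weight for t in targets)
    return [replace(t, weight=t.weight / total) for t in targets]


@dataclass
class MutationProposal:
    parameter_id: str
    old_value: float
    effect: float                           # multiplicative deviation delta
    new_value: float = None                 # old * (1 + delta)
    haldane_update: tuple[str, float, float] | None = None

    def __post_init__(self):
        if self.new_value is None:
            self.new_value = self.old_value * (1.0 + self.effect)


@dataclass
class FixationEvent:
    generation: int
    proposals: list[MutationProposal]
    fitness_before: float
    fitness_after: float
    s: float
    fixation_probability: float
    fixed: bool


@dataclass
class PopulationState:
    """One population under the mutation-selection regime."""

    parameter_values: dict[str, float]
    start_fluxes: dict[str, float]          # per-target reference fluxes
    targets: list[SelectionTarget]
    fitness: float
    fluxes: dict[str, float]                # all reaction fluxes, current
    concentrations: np.ndarray              # current steady state (warm start)
    ne: int
    ploidy: int = 2
    p0: float = DEFAULT_INITIAL_FREQUENCY
    rng: np.random.Generator | None = None

    def clone(self) -> "PopulationState":
        return PopulationState(
            parameter_values=dict(self.parameter_values),
            start_fluxes=dict(self.start_fluxes),
            targets=list(self.targets),
            fitness=self.fitness,
            fluxes=dict(self.fluxes),
            concentrations=self.concentrations.copy(),
            ne=self.ne, ploidy=self.ploidy, p0=self.p0, rng=self.rng,
        )


# ---------------------------------------------------------------------------
# Fitness


def raw_logistic(x: float) -> float:
    """The logistic fitness kernel 1 / (1 + exp(10 (0.5 - x)))."""
    z = 10.0 * (0.5 - x)
    if z > 700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(z))


def flux_fitness(flux: float, target: SelectionTarget,
                 start_flux: float) -> float:
    """Normalized per-target score: 0 at zero flux, 1 at the starting flux.

    The raw logistic of the proportionalized flux is shifted/scaled so the
    zero-flux anchor maps to 0 and the start-flux anchor (x = 1/multiplier)
    maps to 1; the upper asymptote is then the diminishing-returns ceiling.
    """
    if start_flux == 0:
        raise ConfigurationError(
            f"selected reaction {target.reaction_id!r} has zero start flux")
    x = flux / (start_flux * target.multiplier)
    x0 = 1.0 / target.multiplier
    lo = raw_logistic(0.0)
    denom = raw_logistic(x0) - lo
    score = (raw_logistic(x) - lo) / denom
    return max(score, 0.0)


def population_fitness(scores: Sequence[float],
                       weights: Sequence[float]) -> float:
    """Weighted geometric mean of per-target scores (0 is absorbing)."""
    acc = 0.0
    for s, w in zip(scores, weights):
        if s < 0:
            raise ValueError("fitness scores must be >= 0")
        if s == 0.0:
            if w > 0:
                return 0.0
            continue
        acc += w * math.log(s)
    return math.exp(acc)


def _state_fitness(state: PopulationState, fluxes: Mapping[str, float]) -> float:
    scores = [flux_fitness(fluxes[t.reaction_id], t,
                           state.start_fluxes[t.reaction_id])
              for t in state.targets]
    return population_fitness(scores, [t.weight for t in state.targets])


# ---------------------------------------------------------------------------
# Fixation probability (Kimura diffusion approximation)


def fixation_probability(s: float, ne: float, c: int = 2,
                         p: float = DEFAULT_INITIAL_FREQUENCY) -> float:
    """P_fix = (1 - e^{-2 c Ne s p}) / (1 - e^{-2 c Ne s}), overflow-safe.

    |2 c Ne s| below 1e-12 is treated as neutral and returns p exactly (the
    continuous limit).  Strongly deleterious arguments underflow to ~0
    without overflowing.
    """
    if ne < 1:
        raise ValueError("Ne must be >= 1")
    if c not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    if not 0.0 < p < 1.0:
        raise ValueError("initial frequency must lie in (0, 1)")
    a = 2.0 * c * ne * s
    if abs(a) < NEUTRAL_GUARD:
        return p
    if -a > 700.0:  # deleterious enough that expm1 would overflow
        # P = exp(-a p) / exp(-a) up to O(1) factors -> exp(a (1 - p)),
        # which underflows toward 0 instead of overflowing
        return math.exp(a * (1.0 - p))
    num = math.expm1(-a * p)
    den = math.expm1(-a)
    out = num / den
    return min(max(out, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Proposal engine


def sample_effect(role: str, rng: np.random.Generator,
                  mutation: MutationModel = MutationModel()) -> float:
    """Draw a multiplicative deviation for a parameter of the given role.

    Redraws until 1 + delta > 0 so kinetic parameters stay positive.
    """
    mu = (mutation.binding_mean_shift if role == ROLE_BINDING
          else mutation.mean_shift)
    while True:
        delta = float(rng.normal(mu, mutation.sigma))
        if 1.0 + delta > 0.0:
            return delta


class ProposalEngine:
    """Precomputed per-parameter Poisson rates for one model."""

    def __init__(self, model: KineticModel,
                 mutation: MutationModel = MutationModel()):
        self.model = model
        self.mutation = mutation
        self.groups_by_member: dict[str, HaldaneGroup] = {}
        for g in model.haldane_groups:
            for pid in (g.vf, g.keq, *g.substrate_kms, *g.product_kms):
                self.groups_by_member[pid] = g
        params = {p.id: p for p in model.all_parameters()}
        functional = [p for p in params.values()
                      if p.mutable and p.role != ROLE_ENZYME_CONC]
        # Enzyme-concentration rates: lambda x (mutable functional parameters
        # of the owning reaction), aggregated over reactions referencing it.
        enzyme_rates: dict[str, float] = {}
        for r in model.reactions:
            pids = model.reaction_parameter_ids(r)
            k = sum(1 for pid in pids
                    if params[pid].mutable
                    and params[pid].role != ROLE_ENZYME_CONC)
            for pid in pids:
                if params[pid].role == ROLE_ENZYME_CONC and params[pid].mutable:
                    enzyme_rates[pid] = enzyme_rates.get(pid, 0.0) \
                        + mutation.rate * k
        self.entries: list[tuple[str, str, float]] = (
            [(p.id, p.role, mutation.rate) for p in functional]
            + [(pid, ROLE_ENZYME_CONC, lam)
               for pid, lam in enzyme_rates.items()])
        self.lam = np.array([lam for _, _, lam in self.entries])
        # reaction membership for calibration counters
        self.param_reactions: dict[str, list[str]] = {}
        for r in model.reactions:
            for pid in model.reaction_parameter_ids(r):
                self.param_reactions.setdefault(pid, []).append(r.id)

    def propose(self, values: Mapping[str, float],
                rng: np.random.Generator) -> list[MutationProposal]:
        counts = rng.poisson(self.lam)
        if not counts.any():
            return []
        proposals: list[MutationProposal] = []
        current = dict(values)
        for (pid, role, _), k in zip(self.entries, counts):
            for _ in range(int(k)):
                delta = sample_effect(role, rng, self.mutation)
                old = current[pid]
                prop = MutationProposal(pid, old, delta)
                current[pid] = prop.new_value
                group = self.groups_by_member.get(pid)
                if group is not None:
                    old_vr = current[group.vr]
                    new_vr = apply_haldane_update(group, pid, current)
                    current[group.vr] = new_vr
                    prop.haldane_update = (group.vr, old_vr, new_vr)
                proposals.append(prop)
        return proposals


def propose_mutations(state: PopulationState, model: KineticModel,
                      rng: np.random.Generator | None = None,
                      mutation: MutationModel = MutationModel()
                      ) -> list[MutationProposal]:
    """One generation's worth of mutation proposals (possibly empty)."""
    engine = _engine_of(model, mutation)
    return engine.propose(state.parameter_values, rng or state.rng)


def _engine_of(model: KineticModel, mutation: MutationModel) -> ProposalEngine:
    cached = getattr(model, "_proposal_engine", None)
    if cached is None or cached.mutation != mutation or cached.model is not model:
        cached = ProposalEngine(model, mutation)
        model._proposal_engine = cached
    return cached


def apply_haldane_update(group: HaldaneGroup, mutated_id: str,
                         values: Mapping[str, float]) -> float:
    """Reverse velocity restoring Keq = (Vf/Vr) prod(KmP)/prod(KmS).

    Vf and Keq are held at their current values; the returned number is the
    new value for the group's reverse velocity (or reverse kcat).
    """
    if mutated_id not in group.members():
        raise ValueError(f"{mutated_id!r} is not a member of the Haldane "
                         f"group of reaction {group.reaction_id!r}")
    vf, keq = values[group.vf], values[group.keq]
    if vf <= 0 or keq <= 0:
        raise ValueError(
            f"reaction {group.reaction_id!r}: Vf and Keq must be positive")
    num = vf
    for k in group.product_kms:
        num *= values[k]
    den = keq
    for k in group.substrate_kms:
        den *= values[k]
    return num / den


# ---------------------------------------------------------------------------
# Generation loop


def generation_step(state: PopulationState, model: KineticModel,
                    rng: np.random.Generator | None = None,
                    mutation: MutationModel = MutationModel(),
                    solver: SolverOptions = SolverOptions(),
                    generation: int = 0,
                    counters=None,
                    ) -> tuple[PopulationState, FixationEvent | None]:
    """Advance one generation; returns the (possibly unchanged) state.

    All proposals arising in the generation are applied jointly, the steady
    state is re-solved once, and a single accept/reject draw decides the
    fate of the whole set.  Solver failure after a mutation is lethal
    (fitness 0).  On rejection the parameter map reverts bit-identically.
    """
    rng = rng or state.rng
    engine = _engine_of(model, mutation)
    proposals = engine.propose(state.parameter_values, rng)
    if counters is not None:
        counters.record(engine, proposals, generation)
    if not proposals:
        return state, None

    new_values = dict(state.parameter_values)
    for prop in proposals:
        new_values[prop.parameter_id] = prop.new_value
        if prop.haldane_update is not None:
            pid, _old, new = prop.haldane_update
            new_values[pid] = new
    result = solve_steady_state(model, new_values,
                                initial_concentrations=state.concentrations,
                                steady_tolerance=solver.steady_tolerance,
                                time_cap=solver.time_cap)
    fitness_before = state.fitness
    if result.converged:
        flux_map = result.flux_map(model)
        fitness_after = _state_fitness(state, flux_map)
    else:
        flux_map = None
        fitness_after = 0.0
    s = (fitness_after / fitness_before - 1.0) if fitness_before > 0 else 0.0
    pfix = fixation_probability(s, state.ne, state.ploidy, state.p0)
    fixed = bool(rng.random() < pfix)
    event = FixationEvent(generation, proposals, fitness_before,
                          fitness_after, s, pfix, fixed)
    if fixed:
        new_state = state.clone()
        new_state.parameter_values = new_values
        new_state.fitness = fitness_after
        if flux_map is not None:
            new_state.fluxes = flux_map
            new_state.concentrations = result.concentrations.copy()
        return new_state, event
    return state, event


def simulate_generations(state: PopulationState, model: KineticModel,
                         n_generations: int,
                         rng: np.random.Generator | None = None,
                         mutation: MutationModel = MutationModel(),
                         solver: SolverOptions = SolverOptions(),
                         start_generation: int = 0,
                         counters=None,
                         trace_hook=None,
                         ) -> tuple[PopulationState, list[FixationEvent],
                                    list[dict]]:
    """Run the mutation-selection loop for *n_generations*.

    The trace records generation, fitness and all reaction fluxes at every
    fixation.  ``trace_hook(entry)`` (if given) sees each trace entry as it
    is appended — the equilibration detector uses this.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = rng or state.rng
    events: list[FixationEvent] = []
    trace: list[dict] = []
    for g in range(start_generation + 1, start_generation + n_generations + 1):
        state, event = generation_step(state, model, rng, mutation, solver,
                                       generation=g, counters=counters)
        if event is not None:
            events.append(event)
            if event.fixed:
                entry = {"generation": g, "fitness": state.fitness,
                         **{f"flux:{rid}": v
                            for rid, v in state.fluxes.items()}}
                trace.append(entry)
                if trace_hook is not None:
                    trace_hook(entry)
    return state, events, trace


# ---------------------------------------------------------------------------
# Population initialization


def initialize_population(model: KineticModel,
                          targets: Sequence[SelectionTarget],
                          ne: int, ploidy: int = 2,
                          rng: np.random.Generator | None = None,
                          p0: float = DEFAULT_INITIAL_FREQUENCY,
                          solver: SolverOptions = SolverOptions(),
                          ) -> PopulationState:
    """Solve the pristine model and anchor the reference (start) fluxes.

    The model must reach steady state with its original parameters; anything
    else is a fatal configuration error.  The starting fitness is exactly 1
    by construction.
    """
    targets = normalize_weights([SelectionTarget(t.reaction_id, t.weight,
                                                 t.multiplier)
                                 for t in targets])
    values = model.parameter_values()
    result = solve_steady_state(model, values,
                                steady_tolerance=solver.steady_tolerance,
                                time_cap=solver.time_cap)
    if not result.converged:
        raise ConfigurationError(
            "model does not reach steady state with its original parameters "
            f"(residual {result.residual_norm:.3g})")
    flux_map = result.flux_map(model)
    known = {r.id for r in model.reactions}
    start_fluxes = {}
    for t in targets:
        if t.reaction_id not in known:
            raise ConfigurationError(
                f"selection target {t.reaction_id!r} is not a model reaction")
        if flux_map[t.reaction_id] == 0.0:
            raise ConfigurationError(
                f"selected reaction {t.reaction_id!r} carries zero flux at "
                "the starting steady state")
        start_fluxes[t.reaction_id] = flux_map[t.reaction_id]
    state = PopulationState(
        parameter_values=values,
        start_fluxes=start_fluxes,
        targets=list(targets),
        fitness=1.0,
        fluxes=flux_map,
        concentrations=result.concentrations.copy(),
        ne=ne, ploidy=ploidy, p0=p0, rng=rng,
    )
    state.fitness = _state_fitness(state, flux_map)
    return state
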