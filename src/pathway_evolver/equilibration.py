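"""Root burn-in to mutation-selection equilibrium, and root snapshots.

Before the phylogeny is traversed, the root population evolves until its
fitness and most (by default 80%) of its reaction fluxes are statistically
flat: over non-overlapping 100-fixation windows, the normalized least-
squares slope and the coefficient of variation of each series must stay
within thresholds of zero for five consecutive windows.  Once the criterion
is met at generation g, the burn-in continues for another g generations
(total 2g) before the root state is frozen.  Equilibrated roots serialize
to a plain-text snapshot (including the RNG state and the proposal
counters needed for branch-length calibration) and can be imported to skip
or extend the burn-in.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .evolution import (
    FixationEvent,
    MutationModel,
    PopulationState,
    SolverOptions,
    generation_step,
)
from .model import ROLE_ENZYME_CONC, KineticModel

CATEGORY_ENZYME = "enzyme_concentration"
CATEGORY_FUNCTIONAL = "functional"


class SnapshotError(ValueError):
    """Malformed or model-incompatible root snapshot."""


# ---------------------------------------------------------------------------
# Windowed flatness statistics


@dataclass
class WindowStats:
    series_id: str
    slope: float    # OLS slope per fixation, normalized by the window mean
    cv: float       # sd / |mean| within the window
    stable_mean: bool = True  # False when the window mean is zero

    def is_flat(self, slope_tol: float, cv_tol: float) -> bool:
        return (self.stable_mean and abs(self.slope) <= slope_tol
                and self.cv <= cv_tol)


@dataclass
class EquilibrationConfig:
    window_size: int = 100          # fixations per window
    consecutive_windows: int = 5
    flux_fraction: float = 0.8      # fraction of flux series that must be flat
    slope_tol: float = 1e-5
    cv_tol: float = 0.01
    generation_cap: int = 1_000_000

    def __post_init__(self):
        if self.window_size <= 0 or self.consecutive_windows <= 0:
            raise ValueError("window_size and consecutive_windows must be > 0")
        if not 0.0 < self.flux_fraction <= 1.0:
            raise ValueError("flux_fraction must lie in (0, 1]")
        if self.slope_tol <= 0 or self.cv_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.generation_cap < 0:
            raise ValueError("generation_cap must be >= 0")


def window_statistics(series, window_size: int,
                      series_id: str = "") -> list[WindowStats]:
    """Slope/CV over consecutive non-overlapping windows of the series."""
    values = np.asarray(series, dtype=float)
    out: list[WindowStats] = []
    n_windows = len(values) // window_size
    x = np.arange(window_size, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc) if window_size > 1 else 1.0
    for w in range(n_windows):
        y = values[w * window_size:(w + 1) * window_size]
        mean = float(y.mean())
        slope = float(xc @ (y - y.mean())) / denom if window_size > 1 else 0.0
        if mean == 0.0:
            out.append(WindowStats(series_id, np.nan, np.nan,
                                   stable_mean=False))
            continue
        sd = float(y.std(ddof=0))
        out.append(WindowStats(series_id, slope / mean, sd / abs(mean)))
    return out


def equilibrium_reached(stats: dict[str, list[WindowStats]],
                        config: EquilibrationConfig) -> bool:
    """Fitness AND >= flux_fraction of flux series flat in the latest windows."""
    def flat(series_stats: list[WindowStats]) -> bool:
        if len(series_stats) < config.consecutive_windows:
            return False
        recent = series_stats[-config.consecutive_windows:]
        return all(w.is_flat(config.slope_tol, config.cv_tol) for w in recent)

    if "fitness" not in stats or not flat(stats["fitness"]):
        return False
    flux_ids = [k for k in stats if k != "fitness"]
    if not flux_ids:
        return True
    n_flat = sum(flat(stats[k]) for k in flux_ids)
    return n_flat >= config.flux_fraction * len(flux_ids)


# ---------------------------------------------------------------------------
# Proposal counters (feed the branch-length calibration)


@dataclass
class ProposalCounters:
    """Per-category generation stamps of every proposal, plus reaction sets."""

    stamps: dict[str, list[int]] = field(default_factory=lambda: {
        CATEGORY_ENZYME: [], CATEGORY_FUNCTIONAL: []})
    reaction_totals: dict[str, dict[str, int]] = field(default_factory=lambda: {
        CATEGORY_ENZYME: {}, CATEGORY_FUNCTIONAL: {}})
    n_reactions: dict[str, int] = field(default_factory=lambda: {
        CATEGORY_ENZYME: 0, CATEGORY_FUNCTIONAL: 0})

    def bind_model(self, model: KineticModel) -> None:
        """Record how many reactions own mutable parameters per category."""
        params = {p.id: p for p in model.all_parameters()}
        n_e = n_f = 0
        for r in model.reactions:
            pids = model.reaction_parameter_ids(r)
            roles = [params[p].role for p in pids if params[p].mutable]
            if any(role == ROLE_ENZYME_CONC for role in roles):
                n_e += 1
            if any(role != ROLE_ENZYME_CONC for role in roles):
                n_f += 1
        self.n_reactions = {CATEGORY_ENZYME: n_e, CATEGORY_FUNCTIONAL: n_f}

    def record(self, engine, proposals, generation: int) -> None:
        if not proposals:
            return
        params = {p.id: p for p in engine.model.all_parameters()}
        for prop in proposals:
            role = params[prop.parameter_id].role
            cat = (CATEGORY_ENZYME if role == ROLE_ENZYME_CONC
                   else CATEGORY_FUNCTIONAL)
            self.stamps[cat].append(generation)
            rxns = engine.param_reactions.get(prop.parameter_id)
            rid = rxns[0] if rxns else "_global"
            totals = self.reaction_totals[cat]
            totals[rid] = totals.get(rid, 0) + 1

    def average_count(self, category: str, generation: int) -> float:
        """Across-reaction mean cumulative proposal count at *generation*."""
        n = self.n_reactions.get(category, 0)
        if n == 0:
            return 0.0
        stamps = self.stamps[category]
        total = int(np.searchsorted(stamps, generation, side="right"))
        return total / n


# ---------------------------------------------------------------------------
# Equilibration driver


@dataclass
class EquilibratedRoot:
    parameter_values: dict[str, float]
    start_fluxes: dict[str, float]
    fitness: float
    fluxes: dict[str, float]                # all reaction fluxes at the root
    concentrations: list[float]
    generations_elapsed: int
    criterion_met: bool
    cap_reached: bool
    counters: ProposalCounters
    rng_state: dict
    series: dict[str, list[float]]          # fixation-indexed history
    events: list[FixationEvent] = field(default_factory=list)


def equilibrate_root(state: PopulationState, model: KineticModel,
                     config: EquilibrationConfig = EquilibrationConfig(),
                     rng: np.random.Generator | None = None,
                     mutation: MutationModel = MutationModel(),
                     solver: SolverOptions = SolverOptions(),
                     resume: EquilibratedRoot | None = None,
                     ) -> EquilibratedRoot:
    """Burn the root population in until the windowed criterion fires.

    If the criterion fires at generation g the run continues for g further
    generations; hitting ``generation_cap`` first returns with
    ``cap_reached=True``.  Passing *resume* continues a previous burn-in
    (generation numbering, counters and fixation series carry over, so the
    combined run is indistinguishable from an uninterrupted one).
    """
    rng = rng or state.rng
    if resume is not None:
        counters = resume.counters
        series: dict[str, list[float]] = {k: list(v)
                                          for k, v in resume.series.items()}
        offset = resume.generations_elapsed
        all_events = list(resume.events)
    else:
        counters = ProposalCounters()
        counters.bind_model(model)
        series = {"fitness": []}
        for rid in state.fluxes:
            series[f"flux:{rid}"] = []
        offset = 0
        all_events = []

    def record_fixation() -> None:
        series["fitness"].append(state.fitness)
        for rid, val in state.fluxes.items():
            series.setdefault(f"flux:{rid}", []).append(val)

    def criterion_fires() -> bool:
        n_fix = len(series["fitness"])
        if (n_fix % config.window_size != 0
                or n_fix // config.window_size < config.consecutive_windows):
            return False
        stats = {k: window_statistics(v, config.window_size, k)
                 for k, v in series.items()}
        return equilibrium_reached(stats, config)

    gen = offset
    criterion_met = False
    detection_gen: int | None = None
    target = config.generation_cap
    while gen < target:
        gen += 1
        state, event = generation_step(state, model, rng, mutation, solver,
                                       generation=gen, counters=counters)
        if event is not None:
            all_events.append(event)
            if event.fixed:
                record_fixation()
                if detection_gen is None and criterion_fires():
                    detection_gen = gen
                    criterion_met = True
                    # the paper's rule: burn in for as long again
                    target = min(2 * gen, config.generation_cap)
    cap_reached = gen >= config.generation_cap

    return EquilibratedRoot(
        parameter_values=dict(state.parameter_values),
        start_fluxes=dict(state.start_fluxes),
        fitness=state.fitness,
        fluxes=dict(state.fluxes),
        concentrations=[float(c) for c in state.concentrations],
        generations_elapsed=gen,
        criterion_met=criterion_met,
        cap_reached=cap_reached,
        counters=counters,
        rng_state=rng.bit_generator.state,
        series=series,
        events=all_events,
    )


# ---------------------------------------------------------------------------
# Snapshot serialization

_SNAPSHOT_FORMAT = "pathway-evolver-root/1"


def export_root(root: EquilibratedRoot) -> str:
    """Serialize an equilibrated root as a plain-text key-value document."""
    lines = [f"format = {_SNAPSHOT_FORMAT}",
             f"generations_elapsed = {root.generations_elapsed}",
             f"criterion_met = {json.dumps(root.criterion_met)}",
             f"cap_reached = {json.dumps(root.cap_reached)}",
             f"fitness = {root.fitness!r}",
             f"concentrations = {json.dumps(root.concentrations)}",
             f"rng_state = {json.dumps(root.rng_state)}"]
    for pid, val in root.parameter_values.items():
        lines.append(f"param {pid} = {val!r}")
    for rid, val in root.start_fluxes.items():
        lines.append(f"start_flux {rid} = {val!r}")
    for rid, val in root.fluxes.items():
        lines.append(f"flux {rid} = {val!r}")
    for cat, stamps in root.counters.stamps.items():
        lines.append(f"counter_stamps {cat} = {json.dumps(stamps)}")
    for cat, totals in root.counters.reaction_totals.items():
        lines.append(f"counter_reactions {cat} = {json.dumps(totals)}")
    lines.append(f"counter_n_reactions = "
                 f"{json.dumps(root.counters.n_reactions)}")
    for sid, vals in root.series.items():
        lines.append(f"series {sid} = {json.dumps(vals)}")
    return "\n".join(lines) + "\n"


def import_root(document: str,
                model: KineticModel | None = None) -> EquilibratedRoot:
    """Parse a root snapshot; optionally validate it against *model*."""
    simple: dict[str, str] = {}
    params: dict[str, float] = {}
    start_fluxes: dict[str, float] = {}
    fluxes: dict[str, float] = {}
    counters = ProposalCounters()
    series: dict[str, list[float]] = {}
    for raw in document.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(" = ")
        if not _:
            raise SnapshotError(f"malformed snapshot line: {line!r}")
        kind, _, rest = key.partition(" ")
        if kind == "param":
            params[rest] = float(value)
        elif kind == "start_flux":
            start_fluxes[rest] = float(value)
        elif kind == "flux":
            fluxes[rest] = float(value)
        elif kind == "counter_stamps":
            counters.stamps[rest] = [int(x) for x in json.loads(value)]
        elif kind == "counter_reactions":
            counters.reaction_totals[rest] = {
                k: int(v) for k, v in json.loads(value).items()}
        elif kind == "series":
            series[rest] = [float(x) for x in json.loads(value)]
        else:
            simple[key] = value
    if simple.get("format") != _SNAPSHOT_FORMAT:
        raise SnapshotError(
            f"unsupported snapshot format {simple.get('format')!r}")
    if "counter_n_reactions" in simple:
        counters.n_reactions = {
            k: int(v)
            for k, v in json.loads(simple["counter_n_reactions"]).items()}
    if model is not None:
        model_ids = {p.id for p in model.all_parameters()}
        missing = model_ids - set(params)
        extra = set(params) - model_ids
        if missing or extra:
            bad = sorted(missing | extra)
            raise SnapshotError(
                f"snapshot does not match the model; mismatched parameter "
                f"id(s): {bad}")
    return EquilibratedRoot(
        parameter_values=params,
        start_fluxes=start_fluxes,
        fitness=float(simple["fitness"]),
        fluxes=fluxes,
        concentrations=[float(x)
                        for x in json.loads(simple["concentrations"])],
        generations_elapsed=int(simple["generations_elapsed"]),
        criterion_met=json.loads(simple["criterion_met"]),
        cap_reached=json.loads(simple["cap_reached"]),
        counters=counters,
        rng_state=json.loads(simple["rng_state"]),
        series=series,
    )


def restore_rng(rng_state: dict) -> np.random.Generator:
    """Rebuild the generator stream recorded in a snapshot."""
    bg_name = rng_state.get("bit_generator", "PCG64")
    bg = getattr(np.random, bg_name)()
    bg.state = rng_state
    return np.random.Generator(bg)


def root_to_state(root: EquilibratedRoot, model: KineticModel, targets,
                  ne: int, ploidy: int = 2, p0: float = 0.5,
                  rng: np.random.Generator | None = None) -> PopulationState:
    """Rehydrate a PopulationState from a snapshot.

    Concentrations and fluxes come verbatim from the snapshot (they were
    recorded at full precision), so a resumed run is bit-identical to an
    uninterrupted one.
    """
    from .evolution import normalize_weights  # noqa: PLC0415

    model_ids = {p.id for p in model.all_parameters()}
    if model_ids != set(root.parameter_values):
        bad = sorted(model_ids ^ set(root.parameter_values))
        raise SnapshotError(
            f"snapshot does not match the model; mismatched parameter "
            f"id(s): {bad}")
    targets = normalize_weights(list(targets))
    return PopulationState(
        parameter_values=dict(root.parameter_values),
        start_fluxes=dict(root.start_fluxes),
        targets=targets,
        fitness=root.fitness,
        fluxes=dict(root.fluxes),
        concentrations=np.array(root.concentrations, dtype=float),
        ne=ne, ploidy=ploidy, p0=p0,
        rng=rng if rng is not None else restore_rng(root.rng_state),
    )
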