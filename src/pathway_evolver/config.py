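"""Commands-file parsing and whole-run orchestration.

The commands file is line-oriented ``key = value`` text.  Repeatable keys:
``select = reaction:weight[:multiplier]`` and ``popsize = label:value`` (or
a single ``popsize = N`` for a uniform size).  Role overrides use
``role = parameter:role_name``; ``exclude`` freezes parameters.  A run
equilibrates the root (or imports a snapshot), calibrates the generation
scale from the burn-in's proposal counters, simulates every replicate over
the tree from the shared root, and writes the report tables plus manifest.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fixtures as _fixtures
from .equilibration import (
    EquilibrationConfig,
    EquilibratedRoot,
    equilibrate_root,
    export_root,
    import_root,
    restore_rng,
)
from .evolution import (
    ConfigurationError,
    MutationModel,
    SelectionTarget,
    SolverOptions,
    initialize_population,
)
from .model import (
    KineticModel,
    ROLES,
    finalize_model,
    parse_native_model,
    parse_sbml,
)
from .phylogeny import (
    UNITS_MYR,
    UNITS_SUBS,
    PhyloNode,
    calibrate_generation_scale,
    parse_newick,
    simulate_tree,
)
from .reporting import RunOutputs, write_outputs

log = logging.getLogger(__name__)

_UNIT_ALIASES = {"myr": UNITS_MYR, "subs": UNITS_SUBS,
                 "substitutions_per_site": UNITS_SUBS}


@dataclass
class RunConfig:
    model_path: str
    model_format: str                    # "native" | "sbml"
    targets: list[SelectionTarget]
    tree: str                            # Newick text
    units: str = UNITS_MYR
    ploidy: int = 2
    popsize: int | dict[str, int] = 1000
    exclude: list[str] = field(default_factory=list)
    role_overrides: dict[str, str] = field(default_factory=dict)
    n_simulations: int = 1
    seed: int = 0
    equilibration: EquilibrationConfig = field(
        default_factory=EquilibrationConfig)
    mutation: MutationModel = field(default_factory=MutationModel)
    solver: SolverOptions = field(default_factory=SolverOptions)
    output_dir: str = "out"
    import_root_path: str | None = None
    allow_polytomy: bool = False
    p0: float = 0.5

    def __post_init__(self):
        if self.ploidy not in (1, 2):
            raise ConfigurationError("ploidy must be 1 or 2")
        if self.n_simulations < 1:
            raise ConfigurationError("n_simulations must be >= 1")
        if not self.targets:
            raise ConfigurationError("at least one selection target required")


def _read_tree_value(value: str, base: Path) -> str:
    if value.rstrip().endswith(";") and ("(" in value):
        return value
    path = (base / value).resolve() if not Path(value).is_absolute() \
        else Path(value)
    return path.read_text()


def parse_commands_file(text: str, base_dir: str | Path = ".") -> RunConfig:
    """Parse a commands document into a validated :class:`RunConfig`."""
    base = Path(base_dir)
    kv: dict[str, str] = {}
    selects: list[SelectionTarget] = []
    popsizes: dict[str, int] = {}
    uniform_pop: int | None = None
    overrides: dict[str, str] = {}
    eq_kwargs: dict[str, float | int] = {}
    mut_kwargs: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise ConfigurationError(f"line {lineno}: expected 'key = value'")
        key, value = key.strip().lower(), value.strip()
        if key == "select":
            parts = value.split(":")
            if len(parts) not in (2, 3):
                raise ConfigurationError(
                    f"line {lineno}: select needs reaction:weight[:multiplier]")
            mult = float(parts[2]) if len(parts) == 3 else 1.0
            selects.append(SelectionTarget(parts[0].strip(),
                                           float(parts[1]), mult))
        elif key == "popsize":
            if ":" in value:
                label, _, num = value.partition(":")
                popsizes[label.strip()] = int(num)
            else:
                uniform_pop = int(value)
        elif key == "role":
            pid, _, role = value.partition(":")
            role = role.strip()
            if role not in ROLES:
                raise ConfigurationError(
                    f"line {lineno}: unknown role {role!r}")
            overrides[pid.strip()] = role
        elif key in ("window_size", "consecutive_windows", "generation_cap"):
            eq_kwargs[key] = int(value)
        elif key in ("flux_fraction", "slope_tol", "cv_tol"):
            eq_kwargs[key] = float(value)
        elif key in ("mutation_rate", "sigma"):
            mut_kwargs["rate" if key == "mutation_rate" else "sigma"] = \
                float(value)
        else:
            kv[key] = value

    missing = [k for k in ("model", "tree") if k not in kv]
    if missing:
        raise ConfigurationError(f"missing mandatory key(s): {missing}")
    if not selects:
        raise ConfigurationError("at least one 'select = reaction:weight' "
                                 "line is required")
    if uniform_pop is None and not popsizes:
        raise ConfigurationError("missing mandatory key(s): ['popsize']")

    model_path = str((base / kv["model"]))
    fmt = kv.get("format")
    if fmt is None:
        fmt = "sbml" if model_path.endswith((".xml", ".sbml")) else "native"
    units = _UNIT_ALIASES.get(kv.get("units", "myr").lower())
    if units is None:
        raise ConfigurationError(f"unknown units {kv.get('units')!r}")

    return RunConfig(
        model_path=model_path,
        model_format=fmt,
        targets=selects,
        tree=_read_tree_value(kv["tree"], base),
        units=units,
        ploidy=int(kv.get("ploidy", 2)),
        popsize=popsizes if popsizes else uniform_pop,
        exclude=[e.strip() for e in kv.get("exclude", "").split(",")
                 if e.strip()],
        role_overrides=overrides,
        n_simulations=int(kv.get("nsims", 1)),
        seed=int(kv.get("seed", 0)),
        equilibration=EquilibrationConfig(**eq_kwargs),
        mutation=MutationModel(**mut_kwargs),
        output_dir=str(base / kv.get("outdir", "out")),
        import_root_path=(str(base / kv["import_root"])
                          if "import_root" in kv else None),
        allow_polytomy=kv.get("allow_polytomy", "").lower()
        in ("1", "true", "yes"),
        p0=float(kv.get("p0", 0.5)),
    )


def load_model(config: RunConfig) -> KineticModel:
    text = Path(config.model_path).read_text()
    model = (parse_sbml(text) if config.model_format == "sbml"
             else parse_native_model(text))
    return finalize_model(model, overrides=config.role_overrides,
                          exclude=config.exclude)


@dataclass
class RunSummary:
    root: EquilibratedRoot
    g_unit: int
    outputs: RunOutputs
    completed: bool


def run(config: RunConfig, dry_run: bool = False,
        save_root: bool = True) -> RunSummary:
    """Equilibrate -> calibrate -> branch every replicate -> report."""
    model = load_model(config)
    tree = parse_newick(config.tree, allow_polytomy=config.allow_polytomy)
    known = {r.id for r in model.reactions}
    for t in config.targets:
        if t.reaction_id not in known:
            raise ConfigurationError(
                f"selection target {t.reaction_id!r} is not a reaction of "
                "the model")
    if isinstance(config.popsize, dict):
        for node in tree.preorder():
            if node is not tree and node.label not in config.popsize:
                raise ConfigurationError(
                    f"no population size for branch/node {node.label!r}")
    root_ne = (config.popsize if isinstance(config.popsize, int)
               else config.popsize.get(tree.label,
                                       next(iter(config.popsize.values()))))

    seed_seq = np.random.SeedSequence(config.seed)
    eq_rng = np.random.default_rng(seed_seq.spawn(1)[0])

    if config.import_root_path is not None:
        root = import_root(Path(config.import_root_path).read_text(), model)
        log.info("imported equilibrated root (%d generations of burn-in)",
                 root.generations_elapsed)
    else:
        state = initialize_population(model, config.targets, ne=root_ne,
                                      ploidy=config.ploidy, rng=eq_rng,
                                      p0=config.p0, solver=config.solver)
        log.info("equilibrating root population (cap %d generations)",
                 config.equilibration.generation_cap)
        root = equilibrate_root(state, model, config.equilibration, eq_rng,
                                config.mutation, config.solver)
        log.info("burn-in done: %d generations, criterion_met=%s",
                 root.generations_elapsed, root.criterion_met)

    scale = calibrate_generation_scale(root.counters)
    log.info("generation scale: %d generations per Myr (1%% divergence)",
             scale.g_unit)

    sim_results = []
    for i in range(config.n_simulations):
        res = simulate_tree(
            root, tree, model, config.targets, scale,
            units=config.units, popsize=config.popsize,
            ploidy=config.ploidy,
            seed=int(seed_seq.generate_state(1)[0] >> 1) + i,
            p0=config.p0, mutation=config.mutation, solver=config.solver)
        sim_results.append(res)
        log.info("replicate %d/%d finished", i + 1, config.n_simulations)

    outputs = write_outputs(model, root, sim_results, config.output_dir,
                            dry_run=dry_run)
    if save_root and not dry_run:
        Path(config.output_dir, "equilibrated_root.txt").write_text(
            export_root(root))
    return RunSummary(root=root, g_unit=scale.g_unit, outputs=outputs,
                      completed=True)


def make_fixture(name: str):
    """Fixture factory used by the CLI (`fixtures <name>`)."""
    if name == "linear_chain":
        model, _ = _fixtures.make_linear_chain()
        return model
    if name == "reversible_chain":
        return _fixtures.make_reversible_chain()
    if name == "branched":
        return _fixtures.make_branched_fixture()
    raise ValueError(f"unknown fixture {name!r}; choose linear_chain, "
                     "reversible_chain or branched")
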