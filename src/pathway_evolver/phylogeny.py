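"""Rooted Newick phylogeny, branch-length calibration, recursive simulation.

Branch lengths are mapped to generation counts through a calibration
derived from the burn-in: the generation count at which an average of 7
mutation proposals per reaction has accumulated in both the enzyme-
concentration and the functional-parameter category defines one calendar
unit (1 Myr under the two-percent rule, equivalently 1% divergence).
Lengths in substitutions per site are converted to percentages with a
factor of 100.  Every branch is simulated with its own deterministically
derived RNG stream, so sibling branches are statistically independent while
the whole tree run replays from a single seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .equilibration import (
    CATEGORY_ENZYME,
    CATEGORY_FUNCTIONAL,
    EquilibratedRoot,
    ProposalCounters,
    root_to_state,
)
from .evolution import (
    FixationEvent,
    MutationModel,
    SolverOptions,
    simulate_generations,
)
from .model import KineticModel

UNITS_MYR = "myr"
UNITS_SUBS = "substitutions_per_site"
SUBS_TO_PERCENT = 100.0     # substitutions/site -> % divergence
CALIBRATION_PROPOSALS = 7.0


class TreeError(ValueError):
    """Malformed or unsupported phylogeny."""


class CalibrationError(ValueError):
    """Equilibration too short to anchor the generation scale."""


# ---------------------------------------------------------------------------
# Tree types and parsing


@dataclass
class PhyloNode:
    label: str = ""
    branch_length: float | None = None      # None only at the root
    children: list["PhyloNode"] = field(default_factory=list)
    ne_override: int | None = None
    number: int = -1                        # preorder index, assigned on parse

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self):
        return [n for n in self.preorder() if n.is_leaf]

    def edges(self):
        """(parent, child) pairs in preorder."""
        for node in self.preorder():
            for child in node.children:
                yield node, child


def parse_newick(text: str, allow_polytomy: bool = False) -> PhyloNode:
    """Parse a rooted Newick string with mandatory branch lengths.

    The root must bifurcate (anything else signals an unrooted tree);
    multifurcations below the root are rejected unless *allow_polytomy*.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick string: {exc}") from exc

    def convert(node: dendropy.Node) -> PhyloNode:
        if node.taxon is not None:
            label = node.taxon.label
        else:
            label = node.label or ""
        return PhyloNode(label=label, branch_length=node.edge.length,
                         children=[convert(c) for c in node.child_nodes()])

    root = convert(tree.seed_node)
    if len(root.children) != 2:
        raise TreeError(
            f"tree must be rooted: the root has {len(root.children)} "
            "children (expected a bifurcation)")
    for node in root.preorder():
        if node is root:
            continue
        if node.branch_length is None:
            raise TreeError(
                f"branch leading to {node.label or 'an internal node'!s} "
                "has no length; branch lengths are required")
        if node.branch_length < 0:
            raise TreeError("negative branch length")
        if len(node.children) > 2 and not allow_polytomy:
            raise TreeError(
                "multifurcation below the root; rerun with "
                "allow_polytomy=True to accept it")
    _number_nodes(root)
    return root


def _number_nodes(root: PhyloNode) -> None:
    """Preorder numbering; unlabeled internal nodes get 'node<k>' labels."""
    for i, node in enumerate(root.preorder()):
        node.number = i
        if not node.label and node.children:
            node.label = f"node{i}"


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class GenerationScale:
    """Generations per calendar unit (1 Myr == 1% divergence)."""

    g_unit: int
    per_category: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.g_unit < 1:
            raise CalibrationError("generation scale must be >= 1")


def calibrate_generation_scale(counters: ProposalCounters) -> GenerationScale:
    """Generation at which both proposal categories average >= 7 per reaction.

    The slower category governs; a model with no enzyme-concentration
    parameters is calibrated on the functional category alone.
    """
    crossings: dict[str, int] = {}
    for cat in (CATEGORY_ENZYME, CATEGORY_FUNCTIONAL):
        n_rxn = counters.n_reactions.get(cat, 0)
        if n_rxn == 0:
            continue
        stamps = counters.stamps[cat]
        needed = math.ceil(CALIBRATION_PROPOSALS * n_rxn)
        if len(stamps) < needed:
            raise CalibrationError(
                f"equilibration too short: category {cat!r} accumulated "
                f"{len(stamps)} proposals but {needed} are needed for the "
                f"{CALIBRATION_PROPOSALS:g}-proposal calibration; "
                "equilibrate longer")
        crossings[cat] = int(stamps[needed - 1])
    if not crossings:
        raise CalibrationError("no mutable parameters: nothing to calibrate")
    return GenerationScale(g_unit=max(crossings.values()),
                           per_category=crossings)


def branch_generations(length: float, units: str, scale: GenerationScale,
                       rounded: bool = True) -> int | float:
    """Generations to simulate for a branch of the given length.

    Myr lengths multiply the scale directly; substitutions/site first become
    percentages (x100).  Rounding is half-up; a 0-generation branch is legal
    (the child inherits the parent state unchanged).
    """
    if length < 0:
        raise TreeError("negative branch length")
    if units == UNITS_MYR:
        exact = length * scale.g_unit
    elif units == UNITS_SUBS:
        exact = length * SUBS_TO_PERCENT * scale.g_unit
    else:
        raise ValueError(f"unknown branch-length units {units!r}; expected "
                         f"{UNITS_MYR!r} or {UNITS_SUBS!r}")
    if not rounded:
        return exact
    return int(math.floor(exact + 0.5))


# ---------------------------------------------------------------------------
# Tree simulation


@dataclass
class BranchTrace:
    branch_id: int                      # number of the child (terminal) node
    label: str
    parent_id: int
    inherited_values: dict[str, float]
    generations: int
    events: list[FixationEvent]
    trace: list[dict]
    end_values: dict[str, float]
    end_fitness: float
    end_fluxes: dict[str, float]
    end_concentrations: list[float]
    ne: int


@dataclass
class LineageTrace:
    leaf_label: str
    terminal_branch_id: int
    branch_ids: list[int]
    events: list[FixationEvent]         # absolute generation indices
    trace: list[dict]
    total_generations: int
    end_values: dict[str, float]
    end_fitness: float
    end_fluxes: dict[str, float]


@dataclass
class TreeSimulationResult:
    tree: PhyloNode
    branches: dict[int, BranchTrace]
    lineages: dict[str, LineageTrace]


def _resolve_ne(node: PhyloNode, popsize) -> int:
    if isinstance(popsize, dict):
        if node.label in popsize:
            return int(popsize[node.label])
        raise TreeError(
            f"per-branch population sizes given, but node {node.label!r} "
            "has no entry")
    return int(popsize)


def simulate_tree(root: EquilibratedRoot, tree: PhyloNode,
                  model: KineticModel, targets, scale: GenerationScale,
                  units: str, popsize, ploidy: int = 2, seed: int = 0,
                  p0: float = 0.5,
                  mutation: MutationModel = MutationModel(),
                  solver: SolverOptions = SolverOptions(),
                  ) -> TreeSimulationResult:
    """Depth-first recursive simulation of every branch of the tree.

    Each child branch starts from its parent's exact end state; sibling
    branches draw from independent RNG streams spawned from (seed, path), so
    a run replays identically from one seed. Population size is constant
    within a branch and no re-equilibration is attempted after it changes.
    """
    base = np.random.SeedSequence(seed)
    if isinstance(popsize, dict):
        # the root itself only seeds the recursion; tolerate a missing label
        root_ne = int(popsize.get(tree.label, next(iter(popsize.values()))))
    else:
        root_ne = int(popsize)
    root_state = root_to_state(root, model, targets, ne=root_ne,
                               ploidy=ploidy, p0=p0,
                               rng=np.random.default_rng(base))
    branches: dict[int, BranchTrace] = {}

    def simulate_branch(parent_state, parent_node: PhyloNode,
                        node: PhyloNode, path: tuple[int, ...]) -> None:
        gens = branch_generations(node.branch_length, units, scale)
        ne = _resolve_ne(node, popsize)
        state = parent_state.clone()
        state.ne = ne
        state.ploidy = ploidy
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=path))
        state.rng = rng
        state, events, trace = simulate_generations(
            state, model, gens, rng, mutation, solver)
        branches[node.number] = BranchTrace(
            branch_id=node.number,
            label=node.label,
            parent_id=parent_node.number,
            inherited_values=dict(parent_state.parameter_values),
            generations=gens,
            events=events,
            trace=trace,
            end_values=dict(state.parameter_values),
            end_fitness=state.fitness,
            end_fluxes=dict(state.fluxes),
            end_concentrations=[float(c) for c in state.concentrations],
            ne=ne,
        )
        for i, child in enumerate(node.children):
            simulate_branch(state, node, child, path + (i,))

    for i, child in enumerate(tree.children):
        simulate_branch(root_state, tree, child, (i,))

    lineages = assemble_lineages(tree, branches)
    return TreeSimulationResult(tree=tree, branches=branches,
                                lineages=lineages)


def assemble_lineages(tree: PhyloNode,
                      branches: dict[int, BranchTrace]
                      ) -> dict[str, LineageTrace]:
    """Concatenate root-to-leaf branch traces into per-leaf lineages.

    Generation indices are offset so they increase strictly along each
    lineage; a shared ancestral branch contributes identical events to every
    descendant lineage.
    """
    paths: dict[str, list[PhyloNode]] = {}

    def walk(node: PhyloNode, path: list[PhyloNode]) -> None:
        if node.is_leaf:
            paths[node.label] = path
            return
        for child in node.children:
            walk(child, path + [child])

    for child in tree.children:
        walk(child, [child])

    lineages: dict[str, LineageTrace] = {}
    for leaf_label, path in paths.items():
        offset = 0
        events: list[FixationEvent] = []
        trace: list[dict] = []
        for node in path:
            bt = branches[node.number]
            for ev in bt.events:
                shifted = FixationEvent(
                    generation=ev.generation + offset,
                    proposals=ev.proposals,
                    fitness_before=ev.fitness_before,
                    fitness_after=ev.fitness_after,
                    s=ev.s,
                    fixation_probability=ev.fixation_probability,
                    fixed=ev.fixed,
                )
                events.append(shifted)
            for entry in bt.trace:
                shifted_entry = dict(entry)
                shifted_entry["generation"] = entry["generation"] + offset
                trace.append(shifted_entry)
            offset += bt.generations
        terminal = branches[path[-1].number]
        lineages[leaf_label] = LineageTrace(
            leaf_label=leaf_label,
            terminal_branch_id=terminal.branch_id,
            branch_ids=[n.number for n in path],
            events=events,
            trace=trace,
            total_generations=offset,
            end_values=terminal.end_values,
            end_fitness=terminal.end_fitness,
            end_fluxes=terminal.end_fluxes,
        )
    return lineages
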