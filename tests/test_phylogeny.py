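"""Newick parsing, generation-scale calibration, recursive branch simulation."""
import numpy as np
import pytest

from pathway_evolver.equilibration import (
    CATEGORY_ENZYME,
    CATEGORY_FUNCTIONAL,
    ProposalCounters,
)
from pathway_evolver.phylogeny import (
    UNITS_MYR,
    UNITS_SUBS,
    CalibrationError,
    GenerationScale,
    TreeError,
    assemble_lineages,
    branch_generations,
    calibrate_generation_scale,
    parse_newick,
    simulate_tree,
)


class TestNewickParsing:
    def test_two_leaf_tree(self):
        root = parse_newick("(A:1.0,B:2.0):0.0;")
        assert len(root.children) == 2
        assert sorted(leaf.label for leaf in root.leaves()) == ["A", "B"]

    def test_unrooted_trifurcation_rejected(self):
        with pytest.raises(TreeError, match="rooted"):
            parse_newick("(A:1,B:1,C:1);")

    def test_three_leaf_caterpillar_counts(self):
        root = parse_newick("((A:1,B:1):0.5,C:1.5);")
        assert len(root.leaves()) == 3
        assert len(list(root.edges())) == 4

    def test_missing_branch_length_rejected(self):
        with pytest.raises(TreeError, match="length"):
            parse_newick("((A:1,B):0.5,C:1.5);")

    def test_polytomy_below_root_needs_flag(self):
        text = "((A:1,B:1,C:1):0.5,D:1.5);"
        with pytest.raises(TreeError, match="polytomy"):
            parse_newick(text)
        root = parse_newick(text, allow_polytomy=True)
        assert len(root.leaves()) == 4

    def test_malformed_string(self):
        with pytest.raises(TreeError):
            parse_newick("((A:1,B:2;")

    def test_preorder_numbering_and_autolabels(self):
        root = parse_newick("((A:1,B:1):0.5,C:1.5);")
        assert root.number == 0
        internal = root.children[0]
        assert internal.label.startswith("node")


def _counters(rate_e, rate_f, n_rxn=1, horizon=10_000):
    """Synthetic counters with deterministic proposal arrival rates."""
    c = ProposalCounters()
    c.n_reactions = {CATEGORY_ENZYME: n_rxn, CATEGORY_FUNCTIONAL: n_rxn}
    for cat, rate in ((CATEGORY_ENZYME, rate_e), (CATEGORY_FUNCTIONAL, rate_f)):
        stamps, acc, g = [], 0.0, 0
        while g < horizon:
            g += 1
            acc += rate * n_rxn
            while acc >= 1.0:
                stamps.append(g)
                acc -= 1.0
        c.stamps[cat] = stamps
    return c


class TestCalibration:
    def test_equal_rates_cross_near_seven_over_rate(self):
        scale = calibrate_generation_scale(_counters(0.007, 0.007))
        assert scale.g_unit == pytest.approx(1000, abs=2)

    def test_slower_category_governs(self):
        scale = calibrate_generation_scale(_counters(0.007, 0.0035))
        assert scale.g_unit == pytest.approx(2000, abs=2)
        assert scale.per_category[CATEGORY_FUNCTIONAL] > \
            scale.per_category[CATEGORY_ENZYME]

    def test_empty_counters_error(self):
        c = ProposalCounters()
        c.n_reactions = {CATEGORY_ENZYME: 1, CATEGORY_FUNCTIONAL: 1}
        with pytest.raises(CalibrationError):
            calibrate_generation_scale(c)

    def test_too_short_equilibration_error(self):
        with pytest.raises(CalibrationError, match="longer"):
            calibrate_generation_scale(_counters(0.007, 0.007, horizon=500))


class TestBranchGenerations:
    SCALE = GenerationScale(g_unit=1000)

    def test_myr_multiplication(self):
        assert branch_generations(2.5, UNITS_MYR, self.SCALE) == 2500

    def test_substitutions_convert_via_factor_100(self):
        assert branch_generations(0.025, UNITS_SUBS, self.SCALE) == 2500

    def test_zero_length_zero_generations(self):
        assert branch_generations(0.0, UNITS_MYR, self.SCALE) == 0

    def test_unrounded_ratio_between_conventions(self):
        subs = branch_generations(0.03, UNITS_SUBS, self.SCALE, rounded=False)
        myr = branch_generations(0.03, UNITS_MYR, self.SCALE, rounded=False)
        assert subs / myr == 100.0

    def test_negative_length_rejected(self):
        with pytest.raises(TreeError):
            branch_generations(-1.0, UNITS_MYR, self.SCALE)


class TestTreeSimulation:
    def _run(self, equilibrated_reversible, newick, seed=11, g_unit=300,
             popsize=1000):
        model, targets, root = equilibrated_reversible
        tree = parse_newick(newick)
        scale = GenerationScale(g_unit=g_unit)
        res = simulate_tree(root, tree, model, targets, scale,
                            units=UNITS_MYR, popsize=popsize, ploidy=2,
                            seed=seed)
        return model, root, tree, res

    def test_zero_length_branches_inherit_root_state(
            self, equilibrated_reversible):
        _, root, _, res = self._run(equilibrated_reversible,
                                    "(A:0.0,B:0.0);")
        for bt in res.branches.values():
            assert bt.generations == 0
            assert bt.end_values == root.parameter_values

    def test_one_trace_per_edge(self, equilibrated_reversible):
        _, _, tree, res = self._run(equilibrated_reversible,
                                    "((A:0.2,B:0.2):0.1,(C:0.1,D:0.2):0.3);")
        assert len(res.branches) == len(list(tree.edges())) == 6
        assert sorted(res.lineages) == ["A", "B", "C", "D"]

    def test_children_inherit_parent_end_state_exactly(
            self, equilibrated_reversible):
        _, _, tree, res = self._run(equilibrated_reversible,
                                    "((A:0.3,B:0.3):0.3,C:0.6);")
        internal = tree.children[0]
        parent_trace = res.branches[internal.number]
        for child in internal.children:
            child_trace = res.branches[child.number]
            assert child_trace.inherited_values == parent_trace.end_values

    def test_reproducible_from_one_seed(self, equilibrated_reversible):
        _, _, _, res1 = self._run(equilibrated_reversible,
                                  "(A:0.5,B:0.5);", seed=3)
        _, _, _, res2 = self._run(equilibrated_reversible,
                                  "(A:0.5,B:0.5);", seed=3)
        for bid in res1.branches:
            assert res1.branches[bid].end_values \
                == res2.branches[bid].end_values
        assert [e.generation for lt in res1.lineages.values()
                for e in lt.events] \
            == [e.generation for lt in res2.lineages.values()
                for e in lt.events]

    def test_siblings_draw_from_independent_streams(
            self, equilibrated_reversible):
        _, _, _, res = self._run(equilibrated_reversible, "(A:0.5,B:0.5);")
        a, b = res.branches[1], res.branches[2]
        assert a.generations == b.generations
        # same inherited state, different streams -> different event lists
        assert [e.generation for e in a.events] \
            != [e.generation for e in b.events]

    def test_per_branch_popsize_by_label(self, equilibrated_reversible):
        model, targets, root = equilibrated_reversible
        tree = parse_newick("(A:0.1,B:0.1);")
        scale = GenerationScale(g_unit=100)
        res = simulate_tree(root, tree, model, targets, scale,
                            units=UNITS_MYR,
                            popsize={"A": 500, "B": 2000, "node0": 1000},
                            ploidy=2, seed=5)
        assert res.branches[1].ne == 500
        assert res.branches[2].ne == 2000
        with pytest.raises(TreeError, match="B"):
            simulate_tree(root, tree, model, targets, scale,
                          units=UNITS_MYR, popsize={"A": 500}, ploidy=2,
                          seed=5)


class TestLineages:
    def test_two_leaf_lineages_are_single_branches(
            self, equilibrated_reversible):
        model, targets, root = equilibrated_reversible
        tree = parse_newick("(A:0.2,B:0.2);")
        res = simulate_tree(root, tree, model, targets,
                            GenerationScale(g_unit=200), units=UNITS_MYR,
                            popsize=1000, ploidy=2, seed=9)
        for label, lt in res.lineages.items():
            assert len(lt.branch_ids) == 1
            assert lt.total_generations == 40

    def test_caterpillar_concatenates_and_shares_prefix(
            self, equilibrated_reversible):
        model, targets, root = equilibrated_reversible
        tree = parse_newick("((A:0.3,B:0.3):0.3,C:0.6);")
        res = simulate_tree(root, tree, model, targets,
                            GenerationScale(g_unit=300), units=UNITS_MYR,
                            popsize=1000, ploidy=2, seed=9)
        la, lb = res.lineages["A"], res.lineages["B"]
        assert len(la.branch_ids) == 2
        assert la.branch_ids[0] == lb.branch_ids[0]  # shared ancestral branch
        shared = res.branches[la.branch_ids[0]]
        n_shared = len(shared.events)
        assert [e.generation for e in la.events[:n_shared]] \
            == [e.generation for e in lb.events[:n_shared]]
        # strictly increasing generation indices along each lineage
        for lt in res.lineages.values():
            gens = [e.generation for e in lt.events]
            assert gens == sorted(gens)
            assert len(set(gens)) == len(gens)
        assert la.total_generations == 90 + 90
        assert res.lineages["C"].total_generations == 180

    def test_assemble_lineages_counts(self, equilibrated_reversible):
        model, targets, root = equilibrated_reversible
        tree = parse_newick("((A:0.2,B:0.2):0.2,(C:0.2,D:0.2):0.2);")
        res = simulate_tree(root, tree, model, targets,
                            GenerationScale(g_unit=100), units=UNITS_MYR,
                            popsize=1000, ploidy=2, seed=13)
        lineages = assemble_lineages(tree, res.branches)
        assert len(lineages) == 4
        total = sum(bt.generations for bt in res.branches.values())
        assert total == 6 * 20
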