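"""End-to-end run: equilibrate, simulate a 3-leaf phylogeny, report changes.

Every branch inherits its parent's exact parameter state, evolves for a
generation count set by its length, and the run ends in percent-change
matrices over all model values (fitness, fluxes, concentrations,
parameters) per lineage.
"""
import tempfile
from pathlib import Path

import numpy as np

from pathway_evolver import SelectionTarget, initialize_population
from pathway_evolver.equilibration import EquilibrationConfig, equilibrate_root
from pathway_evolver.fixtures import make_reversible_chain
from pathway_evolver.phylogeny import (
    UNITS_MYR,
    calibrate_generation_scale,
    parse_newick,
    simulate_tree,
)
from pathway_evolver.reporting import read_change_matrix, write_outputs

model = make_reversible_chain(n=2)
targets = [SelectionTarget("Rdrain", 1.0)]
rng = np.random.default_rng(42)
state = initialize_population(model, targets, ne=1000, ploidy=2, rng=rng)
config = EquilibrationConfig(window_size=20, consecutive_windows=3,
                             slope_tol=5e-3, cv_tol=0.05,
                             generation_cap=50_000)
root = equilibrate_root(state, model, config, rng)
scale = calibrate_generation_scale(root.counters)

tree = parse_newick("((A:1.0,B:1.0):0.5,C:1.5);")
result = simulate_tree(root, tree, model, targets, scale, units=UNITS_MYR,
                       popsize=1000, ploidy=2, seed=42)

print(f"burn-in {root.generations_elapsed} generations; "
      f"scale {scale.g_unit} generations/Myr")
for label, lt in sorted(result.lineages.items()):
    fixed = sum(e.fixed for e in lt.events)
    print(f"lineage {label}: {lt.total_generations} generations, "
          f"{len(lt.events)} proposals, {fixed} fixed, "
          f"end fitness {lt.end_fitness:.6f}")

with tempfile.TemporaryDirectory() as tmp:
    write_outputs(model, root, [result], tmp)
    m = read_change_matrix(Path(tmp) / "sim1_lineage_change.tsv")
    cols = ["fitness", "flux:Rdrain", "param:KmS_1", "param:kcatf_1"]
    print("\npercent change (end of burn-in -> lineage tip):")
    print(m[cols].to_string(float_format=lambda v: f"{v:+.3f}"))
print("\nBinding constants drift upward while fitness and the selected "
      "flux stay near their equilibrated values: rapid enzyme-level "
      "change under stabilizing selection on pathway flux.")
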