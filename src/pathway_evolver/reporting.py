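"""Tabular outputs: mutation logs, trajectories, percent-change heatmaps.

The central artifact is the change matrix: rows are lineages (external
nodes) or branches, columns are all model values (fitness, every reaction
flux, every non-boundary steady-state concentration, every parameter), and
cells hold the percent change between the end of equilibration and the end
of branching.  A normalized twin divides each column by its maximum
absolute value so cells lie in [-1, 1].  Replicate simulations are averaged
on the raw percent scale before normalization.  All tables are TSV at full
double precision; plots are optional presentation, never computation.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FLOAT_FMT = "%.17g"


class ReportError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Percent change and normalization


def percent_change(start: float, end: float) -> float:
    """100 * (end - start) / start; NaN ("NA" on disk) when start is 0."""
    if start == 0:
        return float("nan")
    return 100.0 * (end - start) / start


def normalize_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each column by its max |value|; all-zero columns stay zero.

    NaN cells (undefined percent changes) are excluded from the column
    maximum and remain NaN.
    """
    out = matrix.copy()
    for col in out.columns:
        col_max = out[col].abs().max(skipna=True)
        if pd.isna(col_max) or col_max == 0:
            out[col] = out[col].where(out[col].isna(), 0.0)
        else:
            out[col] = out[col] / col_max
    return out


def average_replicates(matrices: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Cell-wise mean of raw percent-change matrices with matching labels."""
    if not matrices:
        raise ReportError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise ReportError("replicate matrices have mismatched labels")
    return sum(matrices[1:], first.copy()) / len(matrices)


# ---------------------------------------------------------------------------
# Building matrices from simulation results


def state_columns(model, fitness: float, fluxes: Mapping[str, float],
                  concentrations, values: Mapping[str, float]) -> dict[str, float]:
    """Flatten one population state into the change-matrix column space."""
    cols = {"fitness": fitness}
    for rid, v in fluxes.items():
        cols[f"flux:{rid}"] = v
    for sp, c in zip(model.species, concentrations):
        if not sp.is_boundary:
            cols[f"conc:{sp.id}"] = float(c)
    for pid, v in values.items():
        cols[f"param:{pid}"] = v
    return cols


def build_change_matrix(start: Mapping[str, float],
                        ends: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Percent change start -> end for each row (lineage or branch)."""
    rows = {}
    for row_label, end in ends.items():
        rows[row_label] = {col: percent_change(start[col], end[col])
                           for col in start}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(start)).sort_index()


# ---------------------------------------------------------------------------
# File output


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT,
                 index_label=index_label, na_rep="NA")


def read_change_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def mutation_table(events, sim: int, branch) -> pd.DataFrame:
    """Event log rows: one per proposal, annotated with the joint event fate."""
    rows = []
    for ev in events:
        for prop in ev.proposals:
            rows.append({
                "sim": sim,
                "branch": branch,
                "generation": ev.generation,
                "parameter": prop.parameter_id,
                "old_value": prop.old_value,
                "new_value": prop.new_value,
                "effect": prop.effect,
                "haldane_partner": (prop.haldane_update[0]
                                    if prop.haldane_update else "NA"),
                "s": ev.s,
                "pfix": ev.fixation_probability,
                "fixed": int(ev.fixed),
                "fitness_before": ev.fitness_before,
                "fitness_after": ev.fitness_after,
            })
    cols = ["sim", "branch", "generation", "parameter", "old_value",
            "new_value", "effect", "haldane_partner", "s", "pfix", "fixed",
            "fitness_before", "fitness_after"]
    return pd.DataFrame(rows, columns=cols)


def trajectory_table(trace: Sequence[Mapping[str, float]]) -> pd.DataFrame:
    return pd.DataFrame(list(trace))


@dataclass
class RunOutputs:
    files: list[Path]
    summary: dict


def write_outputs(model, root, sim_results: Sequence, outdir,
                  plots: bool = False, dry_run: bool = False) -> RunOutputs:
    """Write all tables for a multi-replicate run and a checksum manifest.

    *sim_results* is a sequence of TreeSimulationResult, one per replicate.
    With ``dry_run=True`` nothing is written and only the summary returns.
    """
    outdir = Path(outdir)
    start = state_columns(model, root.fitness,
                          _root_fluxes(model, root),
                          root.concentrations, root.parameter_values)
    lineage_matrices, branch_matrices = [], []
    planned: list[tuple[str, pd.DataFrame, str]] = []
    total_fixed = 0

    for i, res in enumerate(sim_results, start=1):
        tables = []
        for bid, bt in sorted(res.branches.items()):
            tables.append(mutation_table(bt.events, sim=i, branch=bid))
            total_fixed += sum(ev.fixed for ev in bt.events)
        mut = (pd.concat(tables, ignore_index=True) if tables
               else mutation_table([], i, 0))
        planned.append((f"sim{i}_mutations.tsv", mut, "row"))
        for label, lt in sorted(res.lineages.items()):
            planned.append((f"sim{i}_lineage_{label}_trajectory.tsv",
                            trajectory_table(lt.trace), "row"))
        for bid, bt in sorted(res.branches.items()):
            planned.append((f"sim{i}_branch_{bid}_{bt.label}_trajectory.tsv",
                            trajectory_table(bt.trace), "row"))
        lin_ends = {label: state_columns(model, lt.end_fitness, lt.end_fluxes,
                                         res.branches[lt.terminal_branch_id]
                                         .end_concentrations,
                                         lt.end_values)
                    for label, lt in res.lineages.items()}
        br_ends = {f"{bid}:{bt.label}": state_columns(
                       model, bt.end_fitness, bt.end_fluxes,
                       bt.end_concentrations, bt.end_values)
                   for bid, bt in res.branches.items()}
        lin_m = build_change_matrix(start, lin_ends)
        br_m = build_change_matrix(start, br_ends)
        lineage_matrices.append(lin_m)
        branch_matrices.append(br_m)
        planned.append((f"sim{i}_lineage_change.tsv", lin_m, "lineage"))
        planned.append((f"sim{i}_lineage_change_normalized.tsv",
                        normalize_columns(lin_m), "lineage"))
        planned.append((f"sim{i}_branch_change.tsv", br_m, "branch"))
        planned.append((f"sim{i}_branch_change_normalized.tsv",
                        normalize_columns(br_m), "branch"))

    if len(sim_results) > 1:
        avg_lin = average_replicates(lineage_matrices)
        avg_br = average_replicates(branch_matrices)
        planned.append(("average_lineage_change.tsv", avg_lin, "lineage"))
        planned.append(("average_lineage_change_normalized.tsv",
                        normalize_columns(avg_lin), "lineage"))
        planned.append(("average_branch_change.tsv", avg_br, "branch"))
        planned.append(("average_branch_change_normalized.tsv",
                        normalize_columns(avg_br), "branch"))

    summary = {
        "n_simulations": len(sim_results),
        "files_planned": [name for name, _, _ in planned],
        "total_fixed_events": int(total_fixed),
    }
    if dry_run:
        return RunOutputs(files=[], summary=summary)

    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, frame, index_label in planned:
        path = outdir / name
        try:
            _write_tsv(frame, path, index_label)
        except OSError as exc:
            raise ReportError(f"cannot write {path}: {exc}") from exc
        written.append(path)
    if plots:
        for i, m in enumerate(lineage_matrices, start=1):
            p = outdir / f"sim{i}_lineage_change_heatmap.png"
            plot_heatmap(normalize_columns(m), p)
            written.append(p)
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("file\tsha256\n")
        for path in written:
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            fh.write(f"{path.name}\t{digest}\n")
    written.append(manifest)
    return RunOutputs(files=written, summary=summary)


def _root_fluxes(model, root) -> dict[str, float]:
    """All reaction fluxes at the root steady state (recorded at burn-in)."""
    return dict(root.fluxes)


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    """Optional matplotlib heatmap of a normalized change matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(6, 0.25 * len(matrix.columns)),
                 max(3, 0.5 * len(matrix.index))))
    data = matrix.to_numpy(dtype=float)
    im = ax.imshow(np.nan_to_num(data), cmap="RdBu_r", vmin=-1, vmax=1,
                   aspect="auto")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns,
                  rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="normalized % change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
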