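"""Simulated signaling features for classification.

For each (cell line, ligand) pair the model is simulated at the screen dose
and the area under the curve (AUC) of every signaling dimer's phospho-level
plus pAKT, pERK and pS6 is integrated over the stimulation window — the
12-dimensional feature set.  Fold-change (peak over baseline) and
quasi-steady-state (value at the horizon end) variants are available as
optional extras.  AUCs integrate the raw phospho-level; a baseline-subtracted
variant sits behind a flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import CompiledModel, Trajectory
from .network import SCREEN_DOSES, CellLineContext, StimulusCondition

log = logging.getLogger(__name__)


def feature_species(model: CompiledModel) -> tuple[str, ...]:
    """The simulated feature set: phospho-AUC of each signaling dimer plus
    pAKT, pERK and pS6 (12 features for the default ten-dimer network)."""
    dimers = tuple(
        f"p{a}-{b}" for (a, b) in model.spec.dimers if model.spec.signaling_mask[(a, b)]
    )
    return dimers + ("pAKT", "pERK", "pS6")


def auc(trajectory: Trajectory, species: str, t0: float = 0.0, t1: float | None = None) -> float:
    """Trapezoidal integral of an observable over [t0, t1] (min)."""
    times = trajectory.times
    t1 = float(times[-1]) if t1 is None else t1
    if t0 < times[0] or t1 > times[-1] or t1 <= t0:
        raise ValueError(f"[{t0}, {t1}] outside the trajectory span "
                         f"[{times[0]}, {times[-1]}]")
    values = trajectory.observable(species)
    grid = np.unique(np.clip(np.concatenate([[t0, t1], times]), t0, t1))
    return float(np.trapezoid(np.interp(grid, times, values), grid))


def feature_table(
    model: CompiledModel,
    contexts,
    ligands: tuple[str, ...] = ("EGF", "HRG", "HGF", "IGF1"),
    doses: dict[str, float] | None = None,
    extras: bool = False,
    baseline_subtract: bool = False,
    horizon: float = 240.0,
) -> pd.DataFrame:
    """One feature row per (context, ligand): the 12 AUC features plus the
    mutation flags copied from the context.  Rows whose simulation fails are
    excluded with a logged reason."""
    doses = dict(SCREEN_DOSES) if doses is None else doses
    species = feature_species(model)
    rows = []
    for ctx in contexts:
        try:
            basal = model.steady_state(ctx)
        except Exception as exc:
            log.warning("excluding all rows for %s: steady state failed (%s)", ctx.name, exc)
            continue
        for lig in ligands:
            stim = StimulusCondition({lig: doses[lig]}, horizon=horizon)
            try:
                traj = model.simulate(ctx, stim)
            except Exception as exc:
                log.warning("excluding (%s, %s): simulation failed (%s)", ctx.name, lig, exc)
                continue
            row: dict = {"cell_line": ctx.name, "ligand": lig}
            for sp in species:
                value = auc(traj, sp)
                if baseline_subtract:
                    x0 = float(model.observable_matrix(sp) @ basal.x0)
                    value -= x0 * (traj.times[-1] - traj.times[0])
                row[f"auc_{sp}"] = value
                if extras:
                    v = traj.observable(sp)
                    x0 = float(model.observable_matrix(sp) @ basal.x0)
                    row[f"fc_{sp}"] = float(v.max() / max(x0, 1e-12))
                    row[f"qss_{sp}"] = float(v[-1])
            row["kras_mutant"] = ctx.kras_mutant
            row["pik3ca_mutant"] = ctx.pik3ca_mutant
            rows.append(row)
    return pd.DataFrame(rows)


def receptor_feature_table(contexts, ligands: tuple[str, ...] = ("EGF", "HRG", "HGF", "IGF1")) -> pd.DataFrame:
    """Receptor-expression-only feature set (the head-to-head comparison
    mode): five surface levels + mutation flags, one row per (line, ligand)."""
    rows = []
    for ctx in contexts:
        for lig in ligands:
            row = {"cell_line": ctx.name, "ligand": lig}
            for r, v in ctx.receptor_expression.items():
                row[f"expr_{r}"] = v
            row["kras_mutant"] = ctx.kras_mutant
            row["pik3ca_mutant"] = ctx.pik3ca_mutant
            rows.append(row)
    return pd.DataFrame(rows)
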