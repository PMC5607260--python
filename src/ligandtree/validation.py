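"""Model validation procedures: nested-model likelihood-ratio experiments
and receptor-randomization checks.

The LRT harness uses a scaled-down two-receptor network (EGFR + HER2, one
heterodimer) so that the full/reduced fit pair is cheap enough to replicate
for type-I-error calibration.  Removing a dimer constrains its association
rate to the ka -> 0 boundary, so the harness evaluates the boundary-mixture
p-value (see :func:`ligandtree.calibration.lrt_reduced`).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .calibration import (
    FreeParameters,
    MeasurementSet,
    chi_square,
    fit,
    lrt_reduced,
)
from .model import build_model
from .network import CellLineContext, ModelSpec, StimulusCondition
from .params import KineticParameterSet
from .synth import GroundTruth, make_timecourses

LRT_TIME_GRID = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0)
LRT_DOSES = (0.625, 10.0)


def _lrt_setup(hetero_in_truth: bool):
    full_spec = ModelSpec.custom(("EGFR", "HER2"), heterodimers=(("EGFR", "HER2"),))
    red_spec = ModelSpec.custom(("EGFR", "HER2"), heterodimers=())
    truth_spec = full_spec if hetero_in_truth else red_spec
    truth = GroundTruth.default(seed=0, spec=truth_spec, observables=("pEGFR", "pHER2"))
    context = CellLineContext("LRT-LINE", {"EGFR": 2e5, "HER2": 1e5})
    stimuli = [StimulusCondition({"EGF": d}, time_grid=LRT_TIME_GRID) for d in LRT_DOSES]
    model_full = build_model(full_spec, KineticParameterSet.defaults(full_spec))
    model_red = build_model(red_spec, KineticParameterSet.defaults(red_spec))
    free_red = FreeParameters(global_paths=("dimer/EGFR-EGFR/ka", "dimer/HER2-HER2/ka"))
    free_full = FreeParameters(global_paths=("dimer/EGFR-EGFR/ka", "dimer/HER2-HER2/ka",
                                             "dimer/EGFR-HER2/ka"))
    return truth, context, stimuli, model_full, model_red, free_full, free_red


def lrt_replicate(data: MeasurementSet, truth, context, model_full, model_red,
                  free_full, free_red, seed: int, starts: int = 3,
                  rtol: float = 1e-6, atol: float = 1e-8):
    """One full-vs-reduced fit pair on a dataset; the full fit is seeded
    with the reduced optimum (heterodimer rate at the lower bound) so the
    pair is numerically nested by construction."""
    fit_red = fit(model_red, [context], data, free_red, starts=starts, seed=seed,
                  obs_map=truth.obs_map, rtol=rtol, atol=atol)
    nested_start = np.array([
        fit_red.theta["dimer/EGFR-EGFR/ka"],
        fit_red.theta["dimer/HER2-HER2/ka"],
        model_full.params.dimer["EGFR-HER2"]["ka"] * 1e-6,
    ])
    fit_full = fit(model_full, [context], data, free_full, starts=starts, seed=seed,
                   obs_map=truth.obs_map, extra_starts=[nested_start],
                   rtol=rtol, atol=atol)
    return fit_full, fit_red


def lrt_experiment(n_reps: int = 100, seed: int = 0, alpha: float = 0.05,
                   hetero_in_truth: bool = False, sigma: float = 0.1,
                   starts: int = 3) -> dict:
    """Replicated likelihood-ratio experiment on the scaled-down network.

    With ``hetero_in_truth=False`` the data carry no heterodimer signal and
    the boundary-corrected p-values should be uniform-ish (type-I error
    ~ alpha); with ``True`` the test should reject essentially always.
    """
    truth, context, stimuli, model_full, model_red, free_full, free_red = \
        _lrt_setup(hetero_in_truth)
    rng = np.random.default_rng(seed)
    p_values, statistics = [], []
    for rep in range(n_reps):
        data = make_timecourses(truth, [context], stimuli=stimuli,
                                seed=int(rng.integers(2**31 - 1)), sigma=sigma)
        fit_full, fit_red = lrt_replicate(data, truth, context, model_full,
                                          model_red, free_full, free_red,
                                          seed=rep, starts=starts)
        stat, df, p = lrt_reduced(fit_full, fit_red, boundary=True)
        p_values.append(p)
        statistics.append(stat)
    p_values = np.array(p_values)
    return {
        "p_values": p_values,
        "statistics": np.array(statistics),
        "rejection_rate": float(np.mean(p_values < alpha)),
        "alpha": alpha,
        "n_reps": n_reps,
        "df": df,
    }


# ---------------------------------------------------------------------------

def receptor_randomization(model, contexts, obs_map, data: MeasurementSet,
                           n_swaps: int = 20, seed: int = 0,
                           rtol: float = 1e-6, atol: float = 1e-8) -> dict:
    """Goodness of fit with matched vs randomly swapped receptor levels.

    For each swap, every line's receptor expression is replaced by a
    non-matching line's values and chi2/n is recomputed; a genuine
    receptor-expression dependence shows as a systematic decline (higher
    chi2) relative to the matched assignment.
    """
    if len(contexts) < 2:
        raise ValueError("need at least two contexts to swap")
    n = len(data)
    matched = chi_square(model, contexts, obs_map, data, rtol=rtol, atol=atol) / n
    rng = np.random.default_rng(seed)
    swapped = []
    for _ in range(n_swaps):
        # a derangement of expression vectors across lines
        while True:
            perm = rng.permutation(len(contexts))
            if not np.any(perm == np.arange(len(contexts))):
                break
        swapped_contexts = [
            replace(c, receptor_expression=dict(contexts[j].receptor_expression))
            for c, j in zip(contexts, perm)
        ]
        swapped.append(chi_square(model, swapped_contexts, obs_map, data,
                                  rtol=rtol, atol=atol) / n)
    swapped = np.array(swapped)
    return {
        "matched_chi2_per_point": matched,
        "swapped_chi2_per_point": swapped,
        "mean_decline": float(np.mean(swapped) / matched - 1.0),
        "fraction_worse": float(np.mean(swapped > matched)),
    }
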