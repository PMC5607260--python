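"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here, so all stages are
testable without downloads: cell-line panels (receptor levels log-uniform
over the span of the packaged reference table, mutation frequencies matched
to it), time-resolved phospho-measurements (log-normal noise around true
model trajectories over the experimental dose/time design), quadruplicate
3-day viability readouts with a planted response rule, and cohort
expression tables with responder-enriched ligand expression.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as ltio
from .calibration import MeasurementSet, Observable, ObservationMap
from .features import feature_table
from .model import CompiledModel, build_model
from .network import (
    RECEPTORS,
    SCREEN_DOSES,
    CellLineContext,
    ModelSpec,
    StimulusCondition,
)
from .params import KineticParameterSet
from .phenotype import ViabilityRecord

#: receptor surface-count span of the reference panel (3.0k - 5501.4k per cell)
EXPRESSION_RANGE = (3e3, 5.5e6)

#: the experimental dose design: four doses per single ligand plus pairwise
#: co-stimulations at 2.5 nM
TIMECOURSE_DOSES = (0.156, 0.625, 2.5, 10.0)
TIMECOURSE_LIGANDS = ("EGF", "HRG", "IGF1")

DEFAULT_OBSERVABLES = ("pEGFR", "pHER2", "pErbB3", "pMet", "pIGF1R",
                       "pMEK", "pERK", "pAKT", "pS6K1", "pS6")

#: default measurement noise, log10 units (~26% CV)
DEFAULT_SIGMA = 0.1


@dataclass
class PlantedRule:
    """A depth-<=3 decision rule on the true simulated features.

    The default is the single-feature rule "responder iff the pS6 AUC of
    the (line, ligand) pair exceeds the pooled median"; an optional second
    clause ORs in a (feature > quantile AND mutation) branch, still
    representable by a depth-3 tree.
    """

    feature: str = "auc_pS6"
    quantile: float = 0.5
    or_feature: str | None = None
    or_quantile: float = 0.7
    or_mutation: str | None = None
    #: absolute thresholds, frozen at the first application so that every
    #: dataset generated from one ground truth uses the same rule
    threshold_: float | None = None
    or_threshold_: float | None = None

    def apply(self, features: pd.DataFrame) -> np.ndarray:
        if self.threshold_ is None:
            self.threshold_ = float(features[self.feature].quantile(self.quantile))
        labels = features[self.feature].to_numpy() > self.threshold_
        if self.or_feature is not None:
            if self.or_threshold_ is None:
                self.or_threshold_ = float(features[self.or_feature].quantile(self.or_quantile))
            clause = features[self.or_feature].to_numpy() > self.or_threshold_
            if self.or_mutation is not None:
                clause &= features[self.or_mutation].to_numpy(bool)
            labels = labels | clause
        return labels


@dataclass
class GroundTruth:
    """Everything needed to generate and verify synthetic data."""

    spec: ModelSpec
    params: KineticParameterSet
    obs_map: ObservationMap
    rule: PlantedRule
    seed: int
    sigma: float = DEFAULT_SIGMA
    _model: CompiledModel | None = field(default=None, repr=False)

    @property
    def model(self) -> CompiledModel:
        if self._model is None:
            self._model = build_model(self.spec, self.params)
        return self._model

    @classmethod
    def default(cls, seed: int = 0, sigma: float = DEFAULT_SIGMA,
                spec: ModelSpec | None = None,
                observables: tuple[str, ...] = DEFAULT_OBSERVABLES) -> "GroundTruth":
        spec = spec if spec is not None else ModelSpec.full()
        params = KineticParameterSet.defaults(spec)
        obs_map = ObservationMap.uniform(observables, sigma=sigma, log=True)
        return cls(spec=spec, params=params, obs_map=obs_map,
                   rule=PlantedRule(), seed=seed, sigma=sigma)


# ---------------------------------------------------------------------------

def make_cell_lines(n: int, seed: int = 0, fixture: bool = False) -> list[CellLineContext]:
    """Synthetic cell-line contexts.

    Receptor counts are drawn log-uniform over the span of the reference
    panel; KRAS/PIK3CA mutants appear with the panel's frequencies
    (computed from the packaged table at run time).  ``fixture=True``
    returns the packaged 58-line panel itself (``n`` is then ignored).
    """
    if fixture:
        return ltio.fixture_contexts()
    if n < 2:
        raise ValueError("n must be >= 2")
    p_kras, p_pik3ca = ltio.mutation_frequencies()
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(EXPRESSION_RANGE[0]), np.log10(EXPRESSION_RANGE[1])
    contexts = []
    for i in range(n):
        expr = {r: float(10 ** rng.uniform(lo, hi)) for r in RECEPTORS}
        contexts.append(CellLineContext(
            name=f"SYN-{i:03d}",
            receptor_expression=expr,
            kras_mutant=bool(rng.random() < p_kras),
            pik3ca_mutant=bool(rng.random() < p_pik3ca),
        ))
    return contexts


def default_stimuli(design: str = "paper") -> list[StimulusCondition]:
    """The time-course stimulation design.

    ``"paper"``: four doses of EGF, HRG and IGF-1 plus the three pairwise
    co-stimulations at 2.5 nM each.  ``"minimal"``: one saturating dose per
    ligand (including HGF), for fast fitting harnesses.
    """
    if design == "paper":
        stimuli = [StimulusCondition({lig: d})
                   for lig in TIMECOURSE_LIGANDS for d in TIMECOURSE_DOSES]
        pairs = [("EGF", "HRG"), ("EGF", "IGF1"), ("HRG", "IGF1")]
        stimuli += [StimulusCondition({a: 2.5, b: 2.5}) for a, b in pairs]
        return stimuli
    if design == "minimal":
        return [StimulusCondition({lig: 10.0}) for lig in ("EGF", "HRG", "HGF", "IGF1")]
    raise ValueError(f"unknown design {design!r}")


def make_timecourses(truth: GroundTruth, contexts, stimuli=None, seed: int = 0,
                     sigma: float | None = None,
                     time_grid: tuple[float, ...] | None = None) -> MeasurementSet:
    """Noisy time courses from the true model.

    Observation scale/offset from the truth's observation map are applied,
    then multiplicative log-normal noise (sigma in log10 units).
    """
    sigma = truth.sigma if sigma is None else sigma
    stimuli = default_stimuli() if stimuli is None else stimuli
    if time_grid is not None:
        stimuli = [StimulusCondition(s.doses, horizon=time_grid[-1], time_grid=time_grid)
                   for s in stimuli]
    rng = np.random.default_rng(seed)
    model = truth.model
    rows = []
    for ctx in contexts:
        for stim in stimuli:
            traj = model.simulate(ctx, stim)
            for obs_name, om in truth.obs_map.items():
                x = traj.observable(obs_name)
                g = om.scale * x + om.offset
                noise = 10.0 ** (sigma * rng.standard_normal(len(g))) if sigma > 0 else 1.0
                y = g * noise
                for t, v in zip(traj.times, y):
                    rows.append((ctx.name, obs_name, stim.label(), float(t), 0,
                                 float(v), max(sigma, 1e-12)))
    frame = pd.DataFrame(rows, columns=MeasurementSet.REQUIRED)
    return MeasurementSet(frame)


def make_viability(truth: GroundTruth, contexts, ligands=None, seed: int = 0,
                   effect: float = 0.35, label_noise: float = 0.10,
                   cv: float = 0.05, control_day3: float = 1000.0,
                   day0: float = 400.0, n_replicates: int = 4):
    """Quadruplicate viability readouts with the planted response rule.

    Day-3 treated mean = control * (1 + effect) for planted responders and
    = control otherwise; a ``label_noise`` fraction of (line, ligand) pairs
    has its effect flipped.  Returns ``(records, truth_labels)`` where
    ``records`` maps (cell_line, treatment) -> :class:`ViabilityRecord` and
    ``truth_labels`` is a frame with the noisy planted labels.
    """
    ligands = tuple(SCREEN_DOSES) if ligands is None else tuple(ligands)
    feats = feature_table(truth.model, contexts, ligands=ligands)
    planted = truth.rule.apply(feats)
    rng = np.random.default_rng(seed)
    flip = rng.random(len(planted)) < label_noise
    labels = planted ^ flip

    records: dict[tuple[str, str], ViabilityRecord] = {}
    rows = []
    for ctx in contexts:
        records[(ctx.name, "control")] = ViabilityRecord(
            ctx.name, "control",
            day0 * (1 + cv * rng.standard_normal(n_replicates)),
            control_day3 * (1 + cv * rng.standard_normal(n_replicates)),
        )
    for (_, frow), label in zip(feats.iterrows(), labels):
        line, lig = frow["cell_line"], frow["ligand"]
        mean3 = control_day3 * (1 + (effect if label else 0.0))
        records[(line, lig)] = ViabilityRecord(
            line, lig,
            day0 * (1 + cv * rng.standard_normal(n_replicates)),
            mean3 * (1 + cv * rng.standard_normal(n_replicates)),
        )
        rows.append((line, lig, bool(label), bool(planted[len(rows)])))
    truth_labels = pd.DataFrame(rows, columns=["cell_line", "ligand", "responder",
                                               "planted_before_noise"])
    return records, truth_labels


def viability_frame(records) -> pd.DataFrame:
    """Tidy long-format view of viability records (cell_line, treatment,
    day, replicate, value)."""
    rows = []
    for (line, treatment), rec in records.items():
        for day, values in ((0, rec.day0), (3, rec.day3)):
            for i, v in enumerate(values):
                rows.append((line, treatment, day, i, float(v)))
    return pd.DataFrame(rows, columns=["cell_line", "treatment", "day", "replicate", "value"])


def make_cohort(truth: GroundTruth, n_samples: int = 400,
                responder_fraction: float = 0.5, ligand_shift: float = 1.0,
                seed: int = 0, ligand: str = "HRG",
                tpm_per_1k_receptors: float = 10.0, tpm_noise: float = 0.05,
                ligand_base_log2: float = 4.0, ligand_sd_log2: float = 0.8):
    """Synthetic patient cohort with planted ligand dependence.

    Receptor TPM values are log-normal around (surface count / gain);
    samples are accepted or rejected until the requested responder fraction
    (under the planted rule on true simulated features) is met, and ligand
    genes are shifted ``+ligand_shift`` log2 units in responders.  Returns
    ``(expression table, true labels)``.
    """
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError("responder_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_resp = int(round(responder_fraction * n_samples))
    chosen: list[tuple[CellLineContext, bool]] = []
    need = {True: n_resp, False: n_samples - n_resp}
    batch = 0
    while sum(need.values()) > 0:
        batch += 1
        if batch > 50:
            raise RuntimeError("could not realize the requested responder fraction")
        m = max(16, 2 * sum(need.values()))
        cand = make_cell_lines(m, seed=int(rng.integers(2**31 - 1)))
        feats = feature_table(truth.model, cand, ligands=(ligand,))
        labels = truth.rule.apply(feats)
        for ctx, lab in zip(cand, labels):
            if need[bool(lab)] > 0:
                chosen.append((ctx, bool(lab)))
                need[bool(lab)] -= 1
    rng2 = np.random.default_rng(seed + 1)
    gene_of = {"EGFR": "EGFR", "HER2": "ERBB2", "ErbB3": "ERBB3",
               "Met": "MET", "IGF1R": "IGF1R"}
    lig_genes = {"EGF": "EGF", "HRG": "NRG1", "HGF": "HGF", "IGF1": "IGF1"}
    rows = []
    for i, (ctx, lab) in enumerate(chosen):
        row = {"sample": f"PT-{i:04d}"}
        for receptor, gene in gene_of.items():
            base = ctx.receptor_expression[receptor] / 1e3 * tpm_per_1k_receptors
            row[gene] = base * 10 ** (tpm_noise * rng2.standard_normal())
        for lig, gene in lig_genes.items():
            mu = ligand_base_log2 + (ligand_shift if (lab and lig == ligand) else 0.0)
            row[gene] = 2.0 ** (mu + ligand_sd_log2 * rng2.standard_normal())
        rows.append(row)
    order = rng2.permutation(len(rows))
    expr = pd.DataFrame([rows[i] for i in order]).set_index("sample")
    labels = pd.Series([chosen[i][1] for i in order],
                       index=expr.index, name="responder")
    return expr, labels
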