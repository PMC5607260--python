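"""Receptor mRNA <-> surface-count mapping and cohort-scale prediction.

Receptor surface counts (qFACS-style, molecules/cell) relate to mRNA
abundance (TPM) through a per-receptor power law, fitted as a linear model
on the log10-log10 scale.  For cohort application, expression tables on an
arbitrary scale are normalized per gene to the cohort mean and re-anchored
to reference surface counts before simulation; predicted responders are
then tested for elevated ligand expression (two-sample t-test on the log2
scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bdt import BaggedTreeModel, LabeledFeatureSet
from .features import feature_table
from .model import CompiledModel
from .network import CellLineContext

#: gene symbol -> model receptor name
RECEPTOR_GENES = {"EGFR": "EGFR", "ERBB2": "HER2", "ERBB3": "ErbB3",
                  "MET": "Met", "IGF1R": "IGF1R"}
#: ligand -> gene symbol measured in cohorts
LIGAND_GENES = {"EGF": "EGF", "HRG": "NRG1", "HGF": "HGF", "IGF1": "IGF1"}


class MissingGeneError(KeyError):
    """A required gene column is absent from the expression table."""


class UndefinedTestError(ValueError):
    """An association test needs both predicted classes to be non-empty."""


def validate_expression(expr: pd.DataFrame, need_ligands: bool = False) -> None:
    required = list(RECEPTOR_GENES) + (list(LIGAND_GENES.values()) if need_ligands else [])
    for gene in required:
        if gene not in expr.columns:
            raise MissingGeneError(gene)
    if (expr[required] < 0).any().any():
        raise ValueError("expression values must be >= 0")


@dataclass
class LinearMap:
    """Per-receptor log10-log10 linear map from mRNA to surface count."""

    slope: dict[str, float]
    intercept: dict[str, float]
    r_squared: dict[str, float]
    n_pairs: dict[str, int]

    def surface_from_mrna(self, receptor: str, mrna: float) -> float:
        return 10.0 ** (self.intercept[receptor] + self.slope[receptor] * np.log10(mrna))


def fit_linear_map(pairs: pd.DataFrame) -> LinearMap:
    """Least squares on log10 scale from paired (mRNA, surface count)
    observations; ``pairs`` columns: receptor, mrna_tpm, surface_count.
    Non-positive values are dropped (logged transform); each receptor needs
    at least three usable pairs."""
    slope, intercept, r2, npairs = {}, {}, {}, {}
    for receptor, grp in pairs.groupby("receptor"):
        ok = (grp["mrna_tpm"] > 0) & (grp["surface_count"] > 0)
        grp = grp[ok]
        if len(grp) < 3:
            raise ValueError(f"receptor {receptor!r} has {len(grp)} usable pairs; need >= 3")
        res = stats.linregress(np.log10(grp["mrna_tpm"]), np.log10(grp["surface_count"]))
        slope[receptor] = float(res.slope)
        intercept[receptor] = float(res.intercept)
        r2[receptor] = float(res.rvalue ** 2)
        npairs[receptor] = int(len(grp))
    return LinearMap(slope, intercept, r2, npairs)


def reference_surface_means(contexts) -> dict[str, float]:
    """Mean surface count per receptor over a reference cell-line panel."""
    receptors = contexts[0].receptor_expression.keys()
    return {
        r: float(np.mean([c.receptor_expression[r] for c in contexts]))
        for r in receptors
    }


def cohort_contexts(expr: pd.DataFrame, reference_means: dict[str, float]) -> list[CellLineContext]:
    """Mean-normalize receptor genes and re-anchor to reference surface
    counts: count = (TPM / cohort mean TPM) * reference mean count."""
    validate_expression(expr)
    contexts = []
    gene_means = {g: float(expr[g].mean()) for g in RECEPTOR_GENES}
    for sample, row in expr.iterrows():
        expression = {}
        for gene, receptor in RECEPTOR_GENES.items():
            mean = gene_means[gene]
            norm = row[gene] / mean if mean > 0 else 0.0
            expression[receptor] = norm * reference_means[receptor]
        contexts.append(CellLineContext(name=str(sample), receptor_expression=expression))
    return contexts


def cohort_predict(expr: pd.DataFrame, model: CompiledModel, bdt: BaggedTreeModel,
                   ligand: str, reference_means: dict[str, float],
                   log10_features: bool = True) -> pd.DataFrame:
    """Per-sample responder predictions for one ligand.

    Simulates the signaling features of every sample from its normalized
    receptor expression and applies the trained bagged-tree vote.  Returns a
    frame indexed like ``expr`` with a boolean ``predicted_responder``.
    """
    if len(expr) == 0:
        return pd.DataFrame(columns=["predicted_responder"])
    contexts = cohort_contexts(expr, reference_means)
    feats = feature_table(model, contexts, ligands=(ligand,))
    X = _design_matrix(feats, bdt.feature_names, log10_features=log10_features)
    pred = bdt.predict(X)
    out = pd.DataFrame({"predicted_responder": pred}, index=feats["cell_line"])
    out.index.name = expr.index.name or "sample"
    return out


def _design_matrix(feats: pd.DataFrame, feature_names, log10_features: bool) -> np.ndarray:
    cols = []
    for name in feature_names:
        if name.startswith("ligand_"):
            lig = name[len("ligand_"):]
            cols.append((feats["ligand"] == lig).to_numpy(float))
        elif name in ("kras_mutant", "pik3ca_mutant"):
            if name in feats.columns:
                cols.append(feats[name].to_numpy(float))
            else:  # cohort samples without mutation calls: assume wild type
                cols.append(np.zeros(len(feats)))
        else:
            v = feats[name].to_numpy(float)
            cols.append(np.log10(np.maximum(v, 1e-12)) if log10_features else v)
    return np.column_stack(cols)


def responder_fractions(predictions: pd.DataFrame, indications: pd.Series | None = None) -> pd.Series:
    """Predicted responder fraction, overall or per indication."""
    if indications is None:
        return pd.Series({"all": float(predictions["predicted_responder"].mean())})
    joined = predictions.join(indications.rename("indication"))
    return joined.groupby("indication")["predicted_responder"].mean()


def ligand_association(expr: pd.DataFrame, predictions: pd.DataFrame,
                       ligand_gene: str) -> tuple[float, float, float]:
    """Two-sample t-test of log2 ligand expression, predicted responders vs
    non-responders; returns (mean log2 difference, t, p)."""
    if ligand_gene not in expr.columns:
        raise MissingGeneError(ligand_gene)
    mask = predictions["predicted_responder"].to_numpy(bool)
    values = np.log2(expr[ligand_gene].to_numpy(float) + 1.0)
    a, b = values[mask], values[~mask]
    if len(a) == 0 or len(b) == 0:
        raise UndefinedTestError("both predicted classes must be non-empty")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(a.mean() - b.mean()), float(t), float(p)
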