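"""End-to-end orchestration: generate/load inputs, simulate features, call
responders, train/evaluate the bagged trees, and report."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as ltio
from .bdt import (
    LabeledFeatureSet,
    compare_to_control,
    evaluate_splits,
    train_bagged,
)
from .config import RunConfig
from .features import feature_table
from .network import ModelSpec
from .phenotype import call_table
from .synth import GroundTruth, make_cell_lines, make_viability, viability_frame

log = logging.getLogger(__name__)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic pipeline described by ``config``.

    Stages: cell-line generation (or the packaged panel) -> feature
    simulation -> synthetic viability + responder calls -> bagged-tree
    training/evaluation against the random control -> report.  Every
    artifact written to the output directory carries the config hash; the
    run is idempotent given the config.  A stage failure is recorded in the
    report while upstream artifacts are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.hash
    config.to_yaml(outdir / "config.yaml")
    report: dict = {"config_hash": h, "stages": {}}

    def stage(name, fn):
        try:
            result = fn()
            report["stages"][name] = "ok"
            return result
        except Exception as exc:
            log.exception("stage %s failed", name)
            report["stages"][name] = f"failed: {exc}"
            return None

    truth = GroundTruth.default(seed=config.seed, spec=ModelSpec.from_variant(config.variant))
    contexts = stage("cell_lines", lambda: make_cell_lines(
        config.n_lines, seed=config.seed, fixture=config.fixture))
    if contexts is None:
        return _finish(report, outdir, h)

    feats = stage("features", lambda: feature_table(
        truth.model, contexts, doses=config.doses))
    if feats is None:
        return _finish(report, outdir, h)
    ltio.write_table(feats, outdir / "features.csv", h)

    def viability_stage():
        records, truth_labels = make_viability(
            truth, contexts, seed=config.seed + 1,
            effect=config.effect, label_noise=config.label_noise)
        ltio.write_table(viability_frame(records), outdir / "viability.csv", h)
        calls = call_table(records, treatments=set(feats["ligand"]),
                           threshold=config.responder_threshold, alpha=config.alpha)
        calls_df = pd.DataFrame([{
            "cell_line": c.cell_line, "treatment": c.treatment, "ligand": c.treatment,
            "ratio": c.ratio, "p_value": c.p_value, "responder": c.responder,
        } for c in calls])
        ltio.write_table(calls_df, outdir / "calls.csv", h)
        return calls_df

    calls_df = stage("responder_calls", viability_stage)
    if calls_df is None:
        return _finish(report, outdir, h)

    def evaluate_stage():
        data = LabeledFeatureSet.from_tables(feats, calls_df)
        kw = dict(n_reps=config.n_reps, train_fraction=config.train_fraction,
                  exclude_ligands=config.exclude_ligands, seed=config.seed + 2,
                  n_trees=config.n_trees, depth_limit=config.depth_limit,
                  min_leaf=config.min_leaf)
        evaluation = evaluate_splits(data, **kw)
        control = evaluate_splits(data, control=True, **kw)
        p = compare_to_control(evaluation, control)
        frame = pd.concat([
            evaluation.to_frame().assign(mode="bdt"),
            control.to_frame().assign(mode="control"),
        ])
        ltio.write_table(frame, outdir / "evaluation.csv", h)
        full_model = train_bagged(data, n_trees=max(config.n_trees, 50),
                                  seed=config.seed + 3, depth_limit=config.depth_limit,
                                  min_leaf=config.min_leaf)
        full_model.to_text(outdir / "bdt_model.yaml")
        return {
            "bdt_mean_accuracy": evaluation.mean_accuracy,
            "bdt_sd_accuracy": evaluation.sd_accuracy,
            "control_mean_accuracy": control.mean_accuracy,
            "p_vs_control": p,
            "importance": full_model.importance(),
        }

    metrics = stage("evaluation", evaluate_stage)
    if metrics is not None:
        report.update(metrics)
        report["n_rows"] = int(len(feats))
        report["responder_fraction"] = float(calls_df["responder"].mean())
    return _finish(report, outdir, h)


def _finish(report: dict, outdir: Path, h: str) -> dict:
    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump({"config": h, **_plain(report)}, fh, sort_keys=False)
    return report


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
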