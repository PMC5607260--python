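"""Responder calling from 3-day viability readouts.

A cell line responds to a ligand when its day-3 signal exceeds the matched
control by more than 20% AND the difference is significant at alpha = 0.05
in a two-sided Wilcoxon rank-sum test (exact enumeration for the
quadruplicate design).  For inhibition (antibody) calls the mirrored rule
applies: >= 20% below the reference with the same significance requirement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


class PairingError(ValueError):
    """Treated and reference records belong to different cell lines."""


def wilcoxon_rank_sum(a, b, exact: bool | None = None) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    For combined n <= 12 (the quadruplicate regime) the exact null is
    enumerated over all C(n, n_a) label assignments with mid-rank handling
    of ties; larger samples fall back to the normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each replicate vector needs length >= 2")
    n = len(a) + len(b)
    if exact is None:
        exact = n <= 12
    if not exact:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic").pvalue)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    if len(np.unique(pooled)) < n:
        log.info("ties present in exact rank-sum test; using mid-ranks")
    w_obs = ranks[: len(a)].sum()
    # enumerate the permutation null of the rank sum of group a
    sums = np.array([ranks[list(idx)].sum() for idx in combinations(range(n), len(a))])
    total = comb(n, len(a))
    eps = 1e-9
    p_le = np.sum(sums <= w_obs + eps) / total
    p_ge = np.sum(sums >= w_obs - eps) / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


@dataclass
class ViabilityRecord:
    """Quadruplicate day-0 and day-3 luminescence for one (line, treatment)."""

    cell_line: str
    treatment: str
    day0: np.ndarray
    day3: np.ndarray

    def __post_init__(self):
        self.day0 = np.asarray(self.day0, dtype=float)
        self.day3 = np.asarray(self.day3, dtype=float)
        if len(self.day0) < 2 or len(self.day3) < 2:
            raise ValueError("at least duplicate readouts are required")
        if np.any(self.day0 <= 0) or np.any(self.day3 <= 0):
            raise ValueError("luminescence values must be > 0")


@dataclass
class ResponseCall:
    cell_line: str
    treatment: str
    reference: str
    ratio: float
    p_value: float
    responder: bool
    log10_fold_day0: float
    direction: str = "up"


def call_responder(record: ViabilityRecord, reference: ViabilityRecord,
                   threshold: float = 1.20, alpha: float = 0.05,
                   direction: str = "up", statistic: str = "mean") -> ResponseCall:
    """Classify a treatment response against its reference.

    ``direction="up"`` is the proliferation rule (ratio > threshold);
    ``direction="down"`` the mirrored inhibition rule (ratio < 1/threshold).
    The effect ratio uses the mean of the day-3 replicates by default
    (``statistic="median"`` is available).
    """
    if record.cell_line != reference.cell_line:
        raise PairingError(
            f"treated record is {record.cell_line!r} but reference is {reference.cell_line!r}"
        )
    agg = np.median if statistic == "median" else np.mean
    ratio = float(agg(record.day3) / agg(reference.day3))
    p = wilcoxon_rank_sum(record.day3, reference.day3)
    if direction == "up":
        effect = ratio > threshold
    elif direction == "down":
        effect = ratio < 1.0 / threshold
    else:
        raise ValueError("direction must be 'up' or 'down'")
    return ResponseCall(
        cell_line=record.cell_line,
        treatment=record.treatment,
        reference=reference.treatment,
        ratio=ratio,
        p_value=p,
        responder=bool(effect and p < alpha),
        log10_fold_day0=float(np.log10(agg(record.day3) / agg(record.day0))),
        direction=direction,
    )


def call_table(records: dict[tuple[str, str], ViabilityRecord],
               treatments, reference_treatment: str = "control",
               threshold: float = 1.20, alpha: float = 0.05) -> "list[ResponseCall]":
    """Responder calls for every (line, treatment) against the line's
    reference treatment."""
    calls = []
    for (line, treatment), rec in records.items():
        if treatment == reference_treatment or treatment not in treatments:
            continue
        ref = records.get((line, reference_treatment))
        if ref is None:
            raise PairingError(f"no {reference_treatment!r} record for line {line!r}")
        calls.append(call_responder(rec, ref, threshold=threshold, alpha=alpha))
    return calls


def threshold_sweep(records, treatments, thresholds=(1.10, 1.15, 1.20, 1.25, 1.30),
                    reference_treatment: str = "control", alpha: float = 0.05):
    """Responder calls recomputed across effect thresholds (robustness of the
    20% criterion)."""
    return {
        thr: call_table(records, treatments, reference_treatment, threshold=thr, alpha=alpha)
        for thr in thresholds
    }
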