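"""ROC/PR evaluation, DeLong curve comparison, strata, carbon accounting.

Both curves are reported because they answer different questions: AUROC is
prevalence-free (the probability that a random positive outscores a random
negative, ties counted half), while precision-recall reflects the operating
reality of sparse interactomes — the same ranking that looks strong at 50%
prevalence can be useless at 1%.

Curve comparison between two models scored on the *same* pairs uses
DeLong's nonparametric test for correlated ROC curves, based on placement
values; metrics are additionally broken down by protein-overlap stratum and
network-topology stratum (hub-hub / hub-lone / lone-lone), which is where
FG-based and sequence-based models diverge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

from .core import PPIBenchError


class DegenerateComparisonError(PPIBenchError):
    """DeLong variance estimate is zero with a nonzero AUROC difference."""


@dataclass
class CurvePoints:
    """Ordered curve coordinates with per-point thresholds.

    ``kind`` is ``"ROC"`` (x=FPR, y=TPR) or ``"PR"`` (x=recall, y=precision).
    """

    kind: str
    thresholds: np.ndarray
    x: np.ndarray
    y: np.ndarray
    area: float

    def to_frame(self) -> pd.DataFrame:
        xname, yname = ("fpr", "tpr") if self.kind == "ROC" else ("recall", "precision")
        return pd.DataFrame(
            {"threshold": self.thresholds, xname: self.x, yname: self.y}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _validate_scores(labels, scores, need_both_classes=True, need_positive=True):
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    if need_positive and y.sum() == 0:
        raise ValueError("no positive labels; metric undefined")
    if need_both_classes and (y.sum() == 0 or y.sum() == y.size):
        raise ValueError("labels contain a single class; metric undefined")
    return y, s


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """AUROC via midranks (Mann-Whitney), ties counted half.

    Algebraically identical to the trapezoidal area under the empirical ROC
    curve, and exact: the underlying statistic is a half-integer.
    """
    y, s = _validate_scores(labels, scores)
    ranks = stats.rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    rank_sum = ranks[y == 1].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve(labels: Sequence[int], scores: Sequence[float]) -> tuple[CurvePoints, float]:
    """Empirical ROC curve (thresholded at distinct scores) and its AUROC."""
    y, s = _validate_scores(labels, scores)
    fpr, tpr, thr = skmetrics.roc_curve(y, s, drop_intermediate=False)
    area = auroc(y, s)
    return CurvePoints("ROC", thr, fpr, tpr, area), area


def average_precision(labels: Sequence[int], scores: Sequence[float]) -> float:
    """AUPRC as step-wise average precision (no linear interpolation).

    Sum over the ranked list of precision x recall-increment; tied scores are
    processed as a block.  Equals the prevalence for a random ranking and is
    bounded below by it for any informative one.
    """
    y, s = _validate_scores(labels, scores, need_both_classes=False)
    return float(skmetrics.average_precision_score(y, s))


def pr_curve(labels: Sequence[int], scores: Sequence[float]) -> tuple[CurvePoints, float]:
    """Precision-recall curve ordered by nondecreasing recall, plus AP."""
    y, s = _validate_scores(labels, scores, need_both_classes=False)
    precision, recall, thr = skmetrics.precision_recall_curve(y, s)
    # sklearn emits recall nonincreasing (thresholds ascending) with a final
    # synthetic (recall=0, precision=1) point; reverse for nondecreasing
    # recall and pad the threshold for that synthetic endpoint.
    thr = np.concatenate([thr, [np.inf]])
    order = slice(None, None, -1)
    curve = CurvePoints(
        "PR", thr[order], recall[order], precision[order], average_precision(y, s)
    )
    return curve, curve.area


def _placements(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values (V10 per positive, V01 per negative) and AUROC."""
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = pos.size, neg.size
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    ranks_pos = stats.rankdata(pos)
    ranks_neg = stats.rankdata(neg)
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    auc = v10.mean()
    return v10, v01, auc


def compare_roc(
    labels: Sequence[int],
    scores_a: Sequence[float],
    scores_b: Sequence[float],
) -> dict:
    """Two-sided DeLong test for two correlated ROC curves.

    Both score vectors must be computed on the same rows (same label
    vector).  Returns a dict with ``auc_a``, ``auc_b``, ``z`` and ``p``.
    When the variance estimate is zero: p = 1 if the AUROCs are equal,
    otherwise the comparison is flagged as non-applicable.
    """
    y, sa = _validate_scores(labels, scores_a)
    _, sb = _validate_scores(labels, scores_b)
    v10_a, v01_a, auc_a = _placements(y, sa)
    v10_b, v01_b, auc_b = _placements(y, sb)
    m, n = v10_a.size, v01_a.size

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    contrast = np.array([1.0, -1.0])
    var = contrast @ (s10 / m + s01 / n) @ contrast
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            return {"auc_a": auc_a, "auc_b": auc_b, "z": 0.0, "p": 1.0}
        raise DegenerateComparisonError(
            "zero variance estimate with unequal AUROCs; DeLong test not applicable"
        )
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": float(auc_a), "auc_b": float(auc_b), "z": float(z), "p": float(p)}


def stratified_eval(
    labels: Sequence[int],
    scores: Sequence[float],
    strata_labels: Sequence[str],
) -> dict[str, dict]:
    """Per-stratum metrics; single-class strata are flagged, never dropped.

    Returns ``{stratum: {n, n_positive, positive_fraction, evaluable,
    auroc, auprc, reason}}``.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    strata = np.asarray(strata_labels)
    if not (y.shape == s.shape == strata.shape):
        raise ValueError("labels, scores and strata must have equal length")
    out: dict[str, dict] = {}
    for stratum in sorted(set(strata.tolist())):
        mask = strata == stratum
        ys, ss = y[mask], s[mask]
        entry: dict = {
            "n": int(mask.sum()),
            "n_positive": int(ys.sum()),
            "positive_fraction": float(ys.mean()),
        }
        if ys.sum() in (0, ys.size):
            entry.update(
                evaluable=False,
                auroc=None,
                auprc=None,
                reason="single-class stratum (not-evaluable)",
            )
        else:
            entry.update(
                evaluable=True,
                auroc=float(auroc(ys, ss)),
                auprc=average_precision(ys, ss),
                reason=None,
            )
        out[stratum] = entry
    return out


# ---------------------------------------------------------------------------
# Resource / carbon accounting

#: Calculator-style defaults: data-centre power-usage effectiveness, global
#: average carbon intensity (gCO2e per kWh), full core usage, typical core
#: and memory power draws.  These are editable conventions, not measurements.
DEFAULT_PUE = 1.67
DEFAULT_CARBON_INTENSITY = 475.0
DEFAULT_POWER_PER_CORE_W = 12.0
DEFAULT_POWER_PER_GB_W = 0.3725
DEFAULT_USAGE_FACTOR = 1.0


def estimate_carbon(
    walltime_s: float,
    n_cores: int = 1,
    power_per_core_W: float = DEFAULT_POWER_PER_CORE_W,
    usage_factor: float = DEFAULT_USAGE_FACTOR,
    mem_GB: float = 0.0,
    power_per_GB_W: float = DEFAULT_POWER_PER_GB_W,
    PUE: float = DEFAULT_PUE,
    carbon_intensity_gCO2e_per_kWh: float = DEFAULT_CARBON_INTENSITY,
) -> tuple[float, float]:
    """(energy_kWh, carbon_gCO2e) for a compute job.

    energy = hours x (cores x W/core x usage + GB x W/GB) x PUE / 1000;
    carbon = energy x carbon intensity.
    """
    values = dict(
        walltime_s=walltime_s,
        n_cores=n_cores,
        power_per_core_W=power_per_core_W,
        usage_factor=usage_factor,
        mem_GB=mem_GB,
        power_per_GB_W=power_per_GB_W,
        PUE=PUE,
        carbon_intensity=carbon_intensity_gCO2e_per_kWh,
    )
    for name, value in values.items():
        if value < 0:
            raise ValueError(f"{name} must be nonnegative, got {value}")
    hours = walltime_s / 3600.0
    draw_watts = n_cores * power_per_core_W * usage_factor + mem_GB * power_per_GB_W
    energy_kwh = hours * draw_watts * PUE / 1000.0
    return energy_kwh, energy_kwh * carbon_intensity_gCO2e_per_kWh


# ---------------------------------------------------------------------------
# Full per-model report

@dataclass
class EvalReport:
    """Everything the reporting sheet needs for one model on one split."""

    auroc: float
    auprc: float
    n: int
    positive_fraction: float
    roc: CurvePoints
    pr: CurvePoints
    by_overlap: dict[str, dict] = field(default_factory=dict)
    by_topology: dict[str, dict] = field(default_factory=dict)
    comparisons: list[dict] = field(default_factory=list)
    resources: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "n": self.n,
            "positive_fraction": self.positive_fraction,
            "by_overlap": self.by_overlap,
            "by_topology": self.by_topology,
            "comparisons": self.comparisons,
            "resources": self.resources,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def evaluate_model(
    labels: Sequence[int],
    scores: Sequence[float],
    overlap_strata: Optional[Sequence[str]] = None,
    topology_strata: Optional[Sequence[str]] = None,
    resources: Optional[Mapping] = None,
) -> EvalReport:
    """Assemble the full report: curves, areas, stratified breakdowns."""
    y = np.asarray(labels).astype(int)
    roc, auc = roc_curve(y, scores)
    pr, ap = pr_curve(y, scores)
    report = EvalReport(
        auroc=auc,
        auprc=ap,
        n=int(y.size),
        positive_fraction=float(y.mean()),
        roc=roc,
        pr=pr,
        resources=dict(resources or {}),
    )
    if overlap_strata is not None:
        report.by_overlap = stratified_eval(y, scores, overlap_strata)
    if topology_strata is not None:
        report.by_topology = stratified_eval(y, scores, topology_strata)
    return report
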