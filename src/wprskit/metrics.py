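"""Nonparametric classifier evaluation: AUROC, DeLong CIs, threshold metrics.

The AUROC estimator is the tie-corrected Mann-Whitney statistic: the
probability that a randomly chosen case outscores a randomly chosen
control, with half credit for ties.  Confidence intervals use the DeLong
structural-components variance with a normal approximation, truncated to
[0, 1].  Ordinal (grouped) inputs — e.g. a tertile table of case and
control counts per risk level — are handled by the same pair-counting
rule applied to grouped data, which makes published count tables exactly
recomputable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import norm, rankdata


@dataclass(frozen=True)
class RocSummary:
    """Point estimate and 95% CI for an AUROC."""

    auroc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    method: str  # 'continuous' | 'ordinal'

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.auroc <= self.ci_high <= 1.0):
            raise ValueError(
                f"inconsistent ROC summary: {self.ci_low}, {self.auroc}, {self.ci_high}"
            )


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal round-half-up, the convention used for displayed metrics."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def _delong_components(
    case_scores: np.ndarray, control_scores: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC and per-observation placement values (DeLong V10, V01)."""
    m, n = case_scores.size, control_scores.size
    allranks = rankdata(np.concatenate([case_scores, control_scores]))
    case_ranks = rankdata(case_scores)
    control_ranks = rankdata(control_scores)
    v10 = (allranks[:m] - case_ranks) / n
    v01 = 1.0 - (allranks[m:] - control_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _normal_ci(
    auc: float, v10: np.ndarray, v01: np.ndarray, alpha: float
) -> tuple[float, float]:
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    if var <= 0.0:
        warnings.warn(
            "degenerate DeLong variance (perfect or constant classifier); "
            "interval collapses to the point estimate",
            stacklevel=3,
        )
        return auc, auc
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def auroc(labels: np.ndarray, scores: np.ndarray, alpha: float = 0.05) -> RocSummary:
    """Tie-corrected AUROC with a DeLong confidence interval.

    ``labels`` are 0 (control) / 1 (case); higher scores should indicate
    cases.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("labels and scores must have the same shape")
    auc, v10, v01 = _delong_components(scores[labels == 1], scores[labels == 0])
    lo, hi = _normal_ci(auc, v10, v01, alpha)
    return RocSummary(auc, lo, hi, int(labels.sum()), int((1 - labels).sum()), "continuous")


def delong_ci(
    labels: np.ndarray, scores: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """DeLong normal-approximation CI for the AUROC, truncated to [0, 1]."""
    summary = auroc(labels, scores, alpha=alpha)
    return summary.ci_low, summary.ci_high


def auroc_from_ordinal(
    case_counts: np.ndarray, control_counts: np.ndarray, alpha: float = 0.05
) -> RocSummary:
    """AUROC of an ordinal risk classifier from grouped counts.

    ``case_counts[k]`` and ``control_counts[k]`` are the numbers of cases
    and controls assigned to ordered risk level k (lowest first).  The
    estimator is the same tie-corrected pair counting as :func:`auroc`
    applied to the grouped data, so a published count table reproduces
    its AUROC exactly.
    """
    cases = np.asarray(case_counts, dtype=np.int64)
    controls = np.asarray(control_counts, dtype=np.int64)
    if cases.shape != controls.shape or cases.ndim != 1 or cases.size < 1:
        raise ValueError("case and control counts must be 1-D and equal length")
    if (cases < 0).any() or (controls < 0).any():
        raise ValueError("counts must be non-negative")
    m, n = int(cases.sum()), int(controls.sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must have positive totals")
    levels = np.repeat(np.arange(cases.size, dtype=float), cases)
    clevels = np.repeat(np.arange(controls.size, dtype=float), controls)
    auc, v10, v01 = _delong_components(levels, clevels)
    lo, hi = _normal_ci(auc, v10, v01, alpha)
    return RocSummary(auc, lo, hi, m, n, "ordinal")


def threshold_metrics(
    case_counts: np.ndarray, control_counts: np.ndarray, threshold_level: int
) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy of an ordinal threshold rule.

    Predict "case" iff the risk level is >= ``threshold_level`` (0-based
    index into the count arrays).  Sensitivity is the fraction of cases
    at or above the threshold; specificity the fraction of controls
    below it; accuracy the overall fraction correct.
    """
    cases = np.asarray(case_counts, dtype=np.int64)
    controls = np.asarray(control_counts, dtype=np.int64)
    if not 0 <= threshold_level < cases.size:
        raise ValueError(
            f"threshold_level {threshold_level} outside [0, {cases.size - 1}]"
        )
    m, n = int(cases.sum()), int(controls.sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must have positive totals")
    tp = int(cases[threshold_level:].sum())
    tn = int(controls[:threshold_level].sum())
    sens = tp / m
    spec = tn / n
    acc = (tp + tn) / (m + n)
    return sens, spec, acc


__all__ = [
    "RocSummary",
    "auroc",
    "auroc_from_ordinal",
    "threshold_metrics",
    "delong_ci",
    "round_half_up",
]
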