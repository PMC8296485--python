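"""Cut-point performance, ROC/AUC with DeLong inference, trend and rank tests.

The positivity convention throughout is ``r >= cutoff``: with an
achievable-score grid as the cutoff list, every grid value is its own
operating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CutpointRow",
    "ROCResult",
    "TrendTestResult",
    "RankSumResult",
    "DegenerateClassesError",
    "confusion_at_cutoff",
    "cutpoint_table",
    "optimal_cutoff",
    "roc_auc",
    "roc_curve_points",
    "compare_auc",
    "trend_chi2",
    "ranksum_ordinal",
]


class DegenerateClassesError(ValueError):
    """Raised when a metric needs at least one case and one control."""


@dataclass(frozen=True)
class CutpointRow:
    """One validation-table row; rates as proportions in [0, 1].

    ``ppv``/``npv`` are ``None`` when their denominator is zero (no
    predicted positives/negatives), never silently 0.
    """

    cutoff_r: float
    sensitivity: float
    specificity: float
    youden: float
    ppv: Optional[float]
    npv: Optional[float]
    tp: int
    fn: int
    fp: int
    tn: int


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    variance: float
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class TrendTestResult:
    chi2_trend: float
    p_value: float


@dataclass(frozen=True)
class RankSumResult:
    z: float
    p_value: float


def _split_cases(values: Sequence[float], outcomes: Sequence[int]):
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes)
    if v.shape[0] != y.shape[0]:
        raise ValueError("values and outcomes have different lengths")
    if not np.isin(y, (0, 1, True, False)).all():
        raise ValueError("outcomes must be binary 0/1")
    y = y.astype(bool)
    cases, controls = v[y], v[~y]
    if cases.size == 0 or controls.size == 0:
        raise DegenerateClassesError(
            f"need at least one case and one control, got {cases.size} cases "
            f"and {controls.size} controls"
        )
    return cases, controls


def confusion_at_cutoff(
    r_values: Sequence[float], outcomes: Sequence[int], cutoff: float
) -> CutpointRow:
    """Confusion metrics with positivity r >= cutoff."""
    cases, controls = _split_cases(r_values, outcomes)
    tp = int((cases >= cutoff).sum())
    fn = cases.size - tp
    fp = int((controls >= cutoff).sum())
    tn = controls.size - fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return CutpointRow(
        cutoff_r=float(cutoff),
        sensitivity=sens,
        specificity=spec,
        youden=sens + spec - 1.0,
        ppv=tp / (tp + fp) if (tp + fp) > 0 else None,
        npv=tn / (tn + fn) if (tn + fn) > 0 else None,
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
    )


def cutpoint_table(
    r_values: Sequence[float], outcomes: Sequence[int], cutoffs: Sequence[float]
) -> list[CutpointRow]:
    """One :class:`CutpointRow` per cutoff, in the order given."""
    return [confusion_at_cutoff(r_values, outcomes, c) for c in cutoffs]


def optimal_cutoff(table: list[CutpointRow]) -> CutpointRow:
    """Row maximizing the Youden index; ties go to the larger cutoff
    (higher specificity)."""
    if not table:
        raise ValueError("empty cut-point table")
    return max(table, key=lambda row: (row.youden, row.cutoff_r))


def _delong_components(cases: np.ndarray, controls: np.ndarray):
    """Per-observation placement values (structural components) and the AUC."""
    m, n = cases.size, controls.size
    all_v = np.concatenate([cases, controls])
    mid_all = stats.rankdata(all_v, method="average")
    mid_cases = stats.rankdata(cases, method="average")
    mid_controls = stats.rankdata(controls, method="average")
    # placement of each case among controls, and vice versa (ties count 1/2)
    v_cases = (mid_all[:m] - mid_cases) / n
    v_controls = 1.0 - (mid_all[m:] - mid_controls) / m
    auc = float(v_cases.mean())
    return auc, v_cases, v_controls


def roc_auc(r_values: Sequence[float], outcomes: Sequence[int]) -> ROCResult:
    """AUC via the Mann-Whitney statistic (ties 1/2) with a DeLong 95% CI.

    The CI is clipped to [0, 1]; the DeLong variance is 0 for perfectly
    separated data.
    """
    cases, controls = _split_cases(r_values, outcomes)
    auc, v_cases, v_controls = _delong_components(cases, controls)
    var = 0.0
    if cases.size > 1:
        var += float(np.var(v_cases, ddof=1)) / cases.size
    if controls.size > 1:
        var += float(np.var(v_controls, ddof=1)) / controls.size
    half = 1.959963984540054 * math.sqrt(var)
    return ROCResult(
        auc=auc,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        variance=var,
        n_cases=int(cases.size),
        n_controls=int(controls.size),
    )


def roc_curve_points(
    r_values: Sequence[float], outcomes: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC polygon (FPR, TPR), from (0,0) to (1,1), for the
    positivity convention r >= cutoff over all distinct values."""
    cases, controls = _split_cases(r_values, outcomes)
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        tpr.append(float((cases >= t).mean()))
        fpr.append(float((controls >= t).mean()))
    return np.asarray(fpr), np.asarray(tpr)


def compare_auc(
    values_a: Sequence[float],
    outcomes_a: Sequence[int],
    values_b: Sequence[float],
    outcomes_b: Sequence[int],
) -> tuple[float, float]:
    """Two-sided unpaired DeLong z-test comparing AUCs of independent groups.

    Returns ``(z, p_value)``.  Degenerate when both variances are 0 with
    equal AUCs; then z = 0, p = 1.
    """
    ra = roc_auc(values_a, outcomes_a)
    rb = roc_auc(values_b, outcomes_b)
    var = ra.variance + rb.variance
    diff = ra.auc - rb.auc
    if var == 0.0:
        z = 0.0 if diff == 0.0 else math.inf * math.copysign(1.0, diff)
    else:
        z = diff / math.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    return float(z), p


def trend_chi2(level_counts: Sequence[tuple[int, int]]) -> TrendTestResult:
    """Cochran-Armitage trend chi-square over ordered levels.

    ``level_counts`` is an ordered list of ``(n_enrolled, n_ill)``; levels
    with zero enrolment are dropped; scores are equally spaced integers
    0, 1, 2, ... over the remaining levels.
    """
    kept = [(n, r) for n, r in level_counts if n > 0]
    for n, r in kept:
        if r < 0 or r > n:
            raise ValueError(f"invalid level counts (n={n}, ill={r})")
    if len(kept) < 2:
        raise ValueError("need at least two levels with enrolment > 0")
    n_i = np.array([n for n, _ in kept], dtype=float)
    r_i = np.array([r for _, r in kept], dtype=float)
    s = np.arange(len(kept), dtype=float)
    N = n_i.sum()
    R = r_i.sum()
    if R == 0 or R == N:
        return TrendTestResult(chi2_trend=0.0, p_value=1.0)
    pbar = R / N
    t = float(np.sum(s * (r_i - n_i * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n_i * s**2) - np.sum(n_i * s) ** 2 / N)
    chi2 = t**2 / var
    return TrendTestResult(chi2_trend=float(chi2), p_value=float(stats.chi2.sf(chi2, df=1)))


def ranksum_ordinal(
    levels_a: Sequence[float], levels_b: Sequence[float]
) -> RankSumResult:
    """Wilcoxon rank-sum z with tie correction on ordinal level codes.

    The tie-corrected normal-approximation variance equals the exact
    permutation variance of the rank sum, so z matches the exact null
    moments even under heavy ties.  Two-sided p from the normal
    approximation; no continuity correction.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    N = n1 + n2
    ranks = stats.rankdata(np.concatenate([a, b]), method="average")
    w = float(ranks[:n1].sum())
    mean_w = n1 * (N + 1) / 2.0
    # exact permutation variance of W under ties
    var_w = n1 * n2 / (N * (N - 1.0)) * float(np.sum((ranks - (N + 1) / 2.0) ** 2))
    if var_w == 0.0:
        return RankSumResult(z=0.0, p_value=1.0)
    z = (w - mean_w) / math.sqrt(var_w)
    return RankSumResult(z=float(z), p_value=float(2.0 * stats.norm.sf(abs(z))))
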