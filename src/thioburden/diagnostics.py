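"""Dose-intensity endpoint and diagnostic accuracy machinery.

The clinical endpoint is the dose intensity percent (DIP), 100 x actual
last-cycle dose over protocol-planned dose; DIP at or below a threshold
(25% by convention) defines thiopurine intolerance. This module turns
predictor calls (star-allele phenotype groups or GVB bins) and DIP
outcomes into 2x2 tables, accuracy metrics, ROC curves with DeLong
confidence intervals, Youden-optimal cutpoints, nonparametric group
tests and paired McNemar / DeLong comparisons between predictors.

AUROC and its variance follow DeLong's structural-components estimator
(midranks handle ties), the standard approach for comparing correlated
ROC curves from paired predictors.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_DIP_THRESHOLDS = (5.0, 10.0, 15.0, 25.0, 35.0, 45.0, 60.0, 80.0, 100.0)

#: Ordinal risk coding for star phenotypes used as a ROC predictor.
PHENOTYPE_ORDINAL = {"PM": 2.0, "IM": 1.0, "NM": 0.0, "indeterminate": 0.0}


class DipGroup(str, enum.Enum):
    AT_OR_BELOW = "at_or_below"
    ABOVE = "above"


def compute_dip(actual_dose: float, planned_dose: float) -> float:
    """Dose intensity percent: 100 x actual / planned."""
    if planned_dose <= 0:
        raise ValueError(f"planned_dose must be > 0, got {planned_dose}")
    if actual_dose < 0:
        raise ValueError(f"actual_dose must be >= 0, got {actual_dose}")
    return 100.0 * actual_dose / planned_dose


def dichotomize(dip: float, threshold: float) -> DipGroup:
    """Event iff DIP <= threshold (inclusive, matching a "<=25" column)."""
    return DipGroup.AT_OR_BELOW if dip <= threshold else DipGroup.ABOVE


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows predicted high/low risk, columns event / no event."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_contingency(
    predictions: Sequence[bool], outcomes: Sequence[bool]
) -> ContingencyTable:
    """Cross-tabulate high-risk predictions against DIP events.

    ``predictions[i]`` True means predicted high risk; ``outcomes[i]``
    True means DIP at or below the threshold (the event).
    """
    if len(predictions) != len(outcomes):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(outcomes)} outcomes"
        )
    tp = fp = fn = tn = 0
    for p, o in zip(predictions, outcomes):
        if p and o:
            tp += 1
        elif p and not o:
            fp += 1
        elif not p and o:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percent accuracy metrics of a 2x2 table; None where undefined."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: float

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


def _ratio_pct(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den > 0 else None


def metrics(table: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy as percents.

    Metrics with a zero denominator are reported as None (missing), not 0.
    """
    if table.total == 0:
        raise ValueError("empty contingency table")
    return DiagnosticMetrics(
        sensitivity=_ratio_pct(table.tp, table.tp + table.fn),
        specificity=_ratio_pct(table.tn, table.tn + table.fp),
        ppv=_ratio_pct(table.tp, table.tp + table.fp),
        npv=_ratio_pct(table.tn, table.tn + table.fn),
        accuracy=100.0 * (table.tp + table.tn) / table.total,
    )


# ---------------------------------------------------------------------------
# DeLong AUROC estimator


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks of a 1-D array (average ranks for ties), 1-based."""
    return stats.rankdata(x, method="average")


def _delong_components(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Structural components V10 (per positive) and V01 (per negative).

    ``scores`` has shape (k, n) for k classifiers on the same n samples;
    ``labels`` is boolean with at least one of each class. Returns
    (aucs, v10, v01).
    """
    pos = scores[:, labels]
    neg = scores[:, ~labels]
    m = pos.shape[1]
    n = neg.shape[1]
    k = scores.shape[0]
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for r in range(k):
        all_r = np.concatenate([pos[r], neg[r]])
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(all_r)
        auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        aucs[r] = auc
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    return aucs, v10, v01


def _delong_cov(scores: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    aucs, v10, v01 = _delong_components(scores, labels)
    m = v10.shape[1]
    n = v01.shape[1]
    s10 = np.cov(v10) if m > 1 else np.zeros((scores.shape[0],) * 2)
    s01 = np.cov(v01) if n > 1 else np.zeros((scores.shape[0],) * 2)
    s10 = np.atleast_2d(s10)
    s01 = np.atleast_2d(s01)
    return aucs, s10 / m + s01 / n


def _validate_binary(outcomes: Sequence[bool]) -> np.ndarray:
    labels = np.asarray(outcomes, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both outcome classes must be present")
    return labels


def roc_auc(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    higher_score_means_event: bool = True,
    ci_level: float = 0.95,
) -> Tuple[float, Tuple[float, float]]:
    """AUROC (rank / Mann-Whitney estimator) with a DeLong normal CI.

    ``outcomes[i]`` True marks the event. When lower scores indicate the
    event (e.g. GVB), pass ``higher_score_means_event=False``; the scores
    are negated internally so the AUC is reported for the event.
    """
    labels = _validate_binary(outcomes)
    s = np.asarray(scores, dtype=float)
    if not higher_score_means_event:
        s = -s
    aucs, cov = _delong_cov(s[np.newaxis, :], labels)
    auc = float(aucs[0])
    se = math.sqrt(max(cov[0, 0], 0.0))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, (lo, hi)


def delong_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes: Sequence[bool],
    higher_score_means_event: bool = True,
) -> float:
    """Two-sided paired DeLong test comparing two correlated AUROCs.

    Returns the p-value. Identical classifiers (zero AUC difference and
    zero variance of the difference) give p = 1.
    """
    labels = _validate_binary(outcomes)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape[0] != labels.shape[0]:
        raise ValueError("scores_a, scores_b and outcomes must be the same length")
    s = np.vstack([sa, sb])
    if not higher_score_means_event:
        s = -s
    aucs, cov = _delong_cov(s, labels)
    diff = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 1e-15:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def youden_cutpoint(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    higher_score_means_event: bool = True,
) -> float:
    """Score threshold maximizing Youden's J = sensitivity + specificity - 1.

    Thresholds are scanned over the observed score values; the returned
    cutpoint is the inclusive boundary of the high-risk bin (prediction
    positive iff score >= cut, or score <= cut when lower scores mean
    the event). Ties in J are broken toward the more specific (smaller)
    high-risk bin. All-identical scores are degenerate: that value is
    returned with a warning.
    """
    labels = _validate_binary(outcomes)
    s = np.asarray(scores, dtype=float)
    sign = 1.0 if higher_score_means_event else -1.0
    oriented = sign * s
    uniq = np.unique(oriented)
    if uniq.size == 1:
        warnings.warn("all scores identical; Youden cutpoint is degenerate")
        return float(sign * uniq[0])
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best_j = -np.inf
    best_t = uniq[0]
    for t in uniq:
        pred = oriented >= t
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        j = sens + spec - 1.0
        # >= keeps the larger oriented threshold (more specific bin) on ties
        if j >= best_j:
            best_j = j
            best_t = t
    return float(sign * best_t)


# ---------------------------------------------------------------------------
# Group tests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float


def _exact_perm_pvalue(groups: List[np.ndarray], statistic) -> float:
    """Exact permutation p-value for a grouped statistic (small n only).

    Enumerates every reassignment of the pooled values to groups of the
    observed sizes and counts statistics at least as extreme as observed
    (statistic assumed to be "large = extreme").
    """
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    observed = statistic(groups)
    n = len(pooled)
    idx = list(range(n))
    count = 0
    total = 0
    # enumerate multiset partitions via combinations of indices
    def rec(remaining: List[int], remaining_sizes: List[int], chosen: List[np.ndarray]):
        nonlocal count, total
        if not remaining_sizes:
            total += 1
            if statistic(chosen) >= observed - 1e-12:
                count += 1
            return
        size = remaining_sizes[0]
        for comb in itertools.combinations(remaining, size):
            rest = [i for i in remaining if i not in comb]
            rec(rest, remaining_sizes[1:], chosen + [pooled[list(comb)]])

    rec(idx, sizes, [])
    return count / total


def _kw_statistic(groups: List[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def group_tests(
    values: Sequence[float],
    groups: Sequence,
    *,
    exact: bool = False,
) -> Dict[str, TestResult]:
    """Nonparametric association tests between values and ordinal groups.

    Returns Kruskal-Wallis, Spearman and Kendall results plus a pairwise
    Mann-Whitney U per group pair, keyed e.g. ``"mannwhitney_NM_vs_IM"``.
    Group labels are ordered by sort order for the rank correlations.
    Empty comparisons are skipped with a warning. With ``exact=True``
    (small n only) the Kruskal-Wallis and Mann-Whitney p-values come
    from exhaustive permutation enumeration.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape[0] != g.shape[0]:
        raise ValueError("values and groups must be the same length")
    labels = sorted(set(g.tolist()))
    by_group = {lab: v[g == lab] for lab in labels}
    results: Dict[str, TestResult] = {}

    nonempty = [lab for lab in labels if len(by_group[lab]) > 0]
    if len(nonempty) < 2:
        logger.warning("fewer than two non-empty groups; omnibus tests skipped")
        return results

    arrays = [by_group[lab] for lab in nonempty]
    if exact:
        h = _kw_statistic(arrays)
        p = _exact_perm_pvalue(arrays, _kw_statistic)
        results["kruskal_wallis"] = TestResult(statistic=float(h), pvalue=float(p))
    else:
        h, p = stats.kruskal(*arrays)
        results["kruskal_wallis"] = TestResult(statistic=float(h), pvalue=float(p))

    ordinal = {lab: i for i, lab in enumerate(labels)}
    x = np.array([ordinal[lab] for lab in g.tolist()], dtype=float)
    rho, p_rho = stats.spearmanr(x, v)
    results["spearman"] = TestResult(statistic=float(rho), pvalue=float(p_rho))
    tau, p_tau = stats.kendalltau(x, v)
    results["kendall"] = TestResult(statistic=float(tau), pvalue=float(p_tau))

    for a, b in itertools.combinations(labels, 2):
        va, vb = by_group[a], by_group[b]
        key = f"mannwhitney_{a}_vs_{b}"
        if len(va) == 0 or len(vb) == 0:
            logger.warning("empty group in %s; comparison skipped", key)
            continue
        method = "exact" if exact else "auto"
        u, p_u = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method)
        results[key] = TestResult(statistic=float(u), pvalue=float(p_u))
    return results


def mcnemar_test(correct_a: Sequence[bool], correct_b: Sequence[bool]) -> float:
    """Exact McNemar test on paired per-sample correctness indicators.

    Uses the exact binomial form on the discordant pairs (appropriate
    for small discordant counts). No discordant pairs gives p = 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("correctness vectors must be the same length")
    n01 = int((~a & b).sum())
    n10 = int((a & ~b).sum())
    if n01 + n10 == 0:
        return 1.0
    from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

    table = [[0, n01], [n10, 0]]
    res = _sm_mcnemar(table, exact=True)
    return float(min(res.pvalue, 1.0))
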