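"""Tertile stratification and the nonparametric association statistics used
throughout the analysis.

The stratification convention is "top tertile = high": the cutoff is the
empirical quantile at 1 - high_fraction (linear interpolation between order
statistics), and a sample is high only if its score is *strictly* above the
cutoff — ties at the cutoff fall low.  Stratification is always computed
within a cohort, never on pooled cohorts.

Group comparisons wrap the standard tests (Mann-Whitney U, Kruskal-Wallis,
Fisher exact, Spearman, log-rank) in a uniform result record.  p-values are
reported raw, with no multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .discovery import binary_auc

logger = logging.getLogger(__name__)

__all__ = [
    "StratifyParams",
    "GroupComparison",
    "tertile_split",
    "mann_whitney",
    "kruskal_wallis",
    "fisher_exact",
    "spearman",
    "km_logrank",
    "response_auc",
]


@dataclass(frozen=True)
class StratifyParams:
    """``high_fraction`` is the fraction of samples defining the high group
    (1/3 = top tertile); ties at the cutoff are assigned low."""

    high_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.high_fraction < 1.0):
            raise ValueError("high_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class GroupComparison:
    statistic_name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    direction: float = 0.0  # sign of the effect where meaningful

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def tertile_split(scores, params: StratifyParams | None = None) -> np.ndarray:
    """Binary high/low labels (1 = high) from per-sample scores.

    Cutoff = empirical quantile at 1 - high_fraction with linear
    interpolation; high means score strictly greater than the cutoff.
    """
    params = params or StratifyParams()
    s = np.asarray(scores, dtype=float)
    if s.size < 3:
        raise ValueError("stratification needs at least 3 samples")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if np.all(s == s[0]):
        raise ValueError("all scores identical; stratification is degenerate")
    cutoff = float(np.quantile(s, 1.0 - params.high_fraction))
    return (s > cutoff).astype(int)


def mann_whitney(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U (x as first group); U = AUC * n1 * n2.

    Exact null distribution for small untied samples, normal approximation
    with tie correction otherwise (scipy's 'auto' policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    direction = np.sign(float(res.statistic) / (x.size * y.size) - 0.5)
    return GroupComparison(
        "mann_whitney_U", float(res.statistic), float(res.pvalue),
        (x.size, y.size), direction,
    )


def kruskal_wallis(groups) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df).

    All-identical pooled values give H = 0, p = 1 by convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    sizes = tuple(a.size for a in arrays)
    if np.all(pooled == pooled[0]):
        return GroupComparison("kruskal_wallis_H", 0.0, 1.0, sizes)
    res = stats.kruskal(*arrays)
    return GroupComparison("kruskal_wallis_H", float(res.statistic), float(res.pvalue), sizes)


def fisher_exact(table) -> GroupComparison:
    """Two-sided Fisher exact test on a 2x2 count table, summing
    hypergeometric probabilities <= that of the observed table.

    A zero margin makes the table uninformative: p = 1 by convention (logged).
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must be 2x2 nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.warning("fisher_exact: zero margin; p = 1 by convention")
        return GroupComparison("fisher_odds_ratio", float("nan"), 1.0,
                               tuple(int(v) for v in t.sum(axis=1)))
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return GroupComparison(
        "fisher_odds_ratio", float(odds), float(min(p, 1.0)),
        tuple(int(v) for v in t.sum(axis=1)),
        direction=np.sign(float(odds) - 1.0) if np.isfinite(odds) else 1.0,
    )


def spearman(x, y) -> GroupComparison:
    """Spearman rank correlation (midranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in ranks; correlation undefined")
    r, p = stats.spearmanr(x, y)
    return GroupComparison("spearman_r", float(r), float(p), (x.size,),
                           direction=float(np.sign(r)))


def km_logrank(time, event, group):
    """Kaplan-Meier curves for two groups plus the log-rank test (1 df).

    Returns ``(curves, comparison)`` where ``curves`` maps group label to the
    fitted product-limit survival function (a DataFrame indexed by time).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if (time < 0).any():
        raise ValueError("survival times must be >= 0")
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError(f"log-rank compares exactly 2 groups, got {len(labels)}")
    curves = {}
    sizes = []
    for lab in labels:
        mask = group == lab
        if mask.sum() == 0:
            raise ValueError(f"group {lab!r} has no subjects")
        sizes.append(int(mask.sum()))
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(lab))
        curves[lab] = kmf.survival_function_
    m0, m1 = group == labels[0], group == labels[1]
    res = logrank_test(time[m0], time[m1], event_observed_A=event[m0],
                       event_observed_B=event[m1])
    comparison = GroupComparison(
        "logrank_chi2", float(res.test_statistic), float(res.p_value), tuple(sizes)
    )
    return curves, comparison


def response_auc(scores, response_labels):
    """ROC-AUC of a score for a binary outcome, with the ROC staircase.

    Returns ``(auc, roc)`` where ``roc`` is a DataFrame with columns
    threshold/fpr/tpr covering every unique score threshold; the trapezoidal
    area under these points equals the midrank AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(response_labels)
    auc = binary_auc(s, y)
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    tpr = [(s[pos] >= t).sum() / n1 for t in thresholds]
    fpr = [(s[~pos] >= t).sum() / n0 for t in thresholds]
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return auc, roc
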