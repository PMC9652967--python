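"""Independent brute-force reference implementations used only by tests.

Deliberately written as plain Python loops over lists — no shared code with
the package — so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations


def phi(t: float) -> float:
    return 0.5 * (1.0 + math.erf(t / math.sqrt(2.0)))


def oracle_kcdf(rows: list[list[float]], kcdf: str) -> list[list[float]]:
    """Per-gene CDF transform by direct summation (gaussian h = sd/4, ddof=1)."""
    out = []
    for row in rows:
        n = len(row)
        if kcdf == "ecdf":
            out.append([sum(1 for v in row if v <= x) / n for x in row])
        else:
            mean = sum(row) / n
            sd = math.sqrt(sum((v - mean) ** 2 for v in row) / (n - 1))
            h = sd / 4.0
            out.append([sum(phi((x - v) / h) for v in row) / n for x in row])
    return out


def oracle_walk(z_col: list[float], in_set: list[bool], tau: float, es_mode: str) -> float:
    """Rank, weight and walk one sample, all by explicit enumeration."""
    p = len(z_col)
    order = sorted(range(p), key=lambda i: (-z_col[i], i))
    weights = [abs(p / 2.0 - r) for r in range(1, p + 1)]
    m = sum(1 for i in order if in_set[i])
    denom = sum(weights[r] ** tau for r, i in enumerate(order) if in_set[i])
    nu, hits, misses = [], 0.0, 0
    for r, i in enumerate(order):
        if in_set[i]:
            hits += weights[r] ** tau
        else:
            misses += 1
        nu.append(hits / denom - misses / (p - m))
    if es_mode == "mx_diff":
        return max(max(nu), 0.0) + min(min(nu), 0.0)
    best = max(range(p), key=lambda l: (abs(nu[l]), -l))
    return nu[best]


def oracle_gsva(rows, gene_names, sample_names, set_genes, kcdf="gaussian",
                tau=1.0, es_mode="mx_diff"):
    """Full brute-force single-sample scores: {sample: score}."""
    z = oracle_kcdf([list(r) for r in rows], kcdf)
    in_set = [g in set(set_genes) for g in gene_names]
    scores = {}
    for j, s in enumerate(sample_names):
        col = [z[i][j] for i in range(len(gene_names))]
        scores[s] = oracle_walk(col, in_set, tau, es_mode)
    return scores


def oracle_auc(values: list[float], labels: list[int]) -> float:
    """AUC by exhaustive pair counting with half-credit for ties."""
    pos = [v for v, y in zip(values, labels) if y == 1]
    neg = [v for v, y in zip(values, labels) if y != 1]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric pmfs <= observed pmf."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x: int) -> float:
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    lo, hi = max(0, row1 - (n - col1)), min(row1, col1)
    p_obs = pmf(a)
    total = sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-12))
    return min(total, 1.0)


def oracle_logrank(time, event, group):
    """Two-group log-rank chi-square by tallying observed vs expected events
    at each distinct event time."""
    labels = sorted(set(group))
    assert len(labels) == 2
    event_times = sorted({t for t, e in zip(time, event) if e == 1})
    obs0 = exp0 = var = 0.0
    for t in event_times:
        at_risk = [(ti, ei, gi) for ti, ei, gi in zip(time, event, group) if ti >= t]
        n = len(at_risk)
        n0 = sum(1 for ti, ei, gi in at_risk if gi == labels[0])
        d = sum(1 for ti, ei, gi in at_risk if ti == t and ei == 1)
        d0 = sum(1 for ti, ei, gi in at_risk if ti == t and ei == 1 and gi == labels[0])
        obs0 += d0
        exp0 += d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return (obs0 - exp0) ** 2 / var


def oracle_trapezoid(fpr: list[float], tpr: list[float]) -> float:
    return sum(
        (fpr[i + 1] - fpr[i]) * (tpr[i + 1] + tpr[i]) / 2.0
        for i in range(len(fpr) - 1)
    )
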