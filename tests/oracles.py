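"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive and written without reference to
the package's vectorised implementations: plain loops, explicit
formulas, exhaustive enumeration.  The tests compare the package
against these.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- banding / typing --------------------------------------------------


def oracle_band(signal: float, lower: float, upper: float) -> str:
    if signal > upper:
        return "positive"
    if signal < lower:
        return "negative"
    return "unclassified"


def oracle_combine(a: str, b: str) -> str:
    if a == "positive" and b == "positive":
        return "O"
    if a == "negative" and b == "positive":
        return "A"
    if a == "positive" and b == "negative":
        return "B"
    if a == "negative" and b == "negative":
        return "AB"
    return "unclassified"


def oracle_agree(bands: list[str]) -> str:
    first = bands[0]
    if first != "unclassified" and all(b == first for b in bands):
        return first
    return "unclassified"


def oracle_flowchart(
    stage1_a: list[str],
    stage1_b: list[str],
    stage2_a: list[str],
    stage2_b: list[str],
) -> tuple[str, int]:
    """Two-stage flow-chart truth table -> (call, stage); stage 0 means
    never classified."""
    call1 = oracle_combine(oracle_agree(stage1_a), oracle_agree(stage1_b))
    if call1 != "unclassified":
        return call1, 1
    call2 = oracle_combine(oracle_agree(stage2_a), oracle_agree(stage2_b))
    if call2 != "unclassified":
        return call2, 2
    return "unclassified", 0


def oracle_two_component_search(samples, labels, candidates_a, candidates_b, grid,
                                min_rate):
    """Fully naive exhaustive two-component search.

    ``samples`` is a list of dicts (component, isotype) -> signal.
    Returns the ranked list of tuples
    (a_target, b_target, la, ua, lb, ub, n_classified, n_correct).
    """
    rows = []
    n = len(samples)
    for a_t, b_t in itertools.product(candidates_a, candidates_b):
        for ia, la in enumerate(grid):
            for ua in grid[ia:]:
                for ib, lb in enumerate(grid):
                    for ub in grid[ib:]:
                        n_cls = n_corr = 0
                        for sample, label in zip(samples, labels):
                            call = oracle_combine(
                                oracle_band(sample[a_t], la, ua),
                                oracle_band(sample[b_t], lb, ub),
                            )
                            if call != "unclassified":
                                n_cls += 1
                                if call == label:
                                    n_corr += 1
                        rate = n_cls / n
                        if rate + 1e-12 < min_rate:
                            continue
                        acc = n_corr / n_cls if n_cls else -1.0
                        rows.append(
                            (
                                -acc,
                                -rate,
                                (ua - la) + (ub - lb),
                                a_t[0], a_t[1], b_t[0], b_t[1],
                                la, ua, lb, ub,
                                n_cls, n_corr,
                            )
                        )
    rows.sort()
    return rows


# -- ANOVA -------------------------------------------------------------


def oracle_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Naive two-pass one-way ANOVA; returns (F, p)."""
    from scipy import stats

    all_values = np.concatenate(groups)
    grand = all_values.mean()
    n = len(all_values)
    g = len(groups)
    ssb = sum(len(grp) * (grp.mean() - grand) ** 2 for grp in groups)
    ssw = sum(((grp - grp.mean()) ** 2).sum() for grp in groups)
    if ssb + ssw < 1e-300:
        return 0.0, 1.0
    if ssw == 0:
        return math.inf, 1e-300
    f = (ssb / (g - 1)) / (ssw / (n - g))
    return f, max(float(stats.f.sf(f, g - 1, n - g)), 1e-300)


# -- survival ----------------------------------------------------------


def oracle_km(times, events):
    """Hand-unrolled product-limit table: list of (t, at_risk, deaths,
    survival)."""
    pairs = sorted(zip(times, events))
    event_times = sorted({t for t, e in pairs if e})
    s = 1.0
    rows = []
    for t in event_times:
        at_risk = sum(1 for ti, _ in pairs if ti >= t)
        deaths = sum(1 for ti, ei in pairs if ti == t and ei)
        s = s * (1 - deaths / at_risk)
        rows.append((t, at_risk, deaths, s))
    return rows


def oracle_logrank_chi2(t1, e1, t2, e2) -> float:
    """Naive two-group log-rank chi-square."""
    t1, e1 = list(t1), list(e1)
    t2, e2 = list(t2), list(e2)
    all_t = t1 + t2
    all_e = e1 + e2
    event_times = sorted({t for t, e in zip(all_t, all_e) if e})
    num = 0.0
    var = 0.0
    for t in event_times:
        n = sum(1 for ti in all_t if ti >= t)
        n1 = sum(1 for ti in t1 if ti >= t)
        d = sum(1 for ti, ei in zip(all_t, all_e) if ti == t and ei)
        d1 = sum(1 for ti, ei in zip(t1, e1) if ti == t and ei)
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return num * num / var if var > 0 else 0.0


def permutation_logrank_p(t1, e1, t2, e2, n_perm: int, seed: int) -> float:
    """Permutation-null p for the log-rank statistic (label shuffles)."""
    rng = np.random.default_rng(seed)
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    n1 = len(t1)
    observed = oracle_logrank_chi2(t1, e1, t2, e2)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(times))
        g1 = idx[:n1]
        g2 = idx[n1:]
        stat = oracle_logrank_chi2(
            times[g1], events[g1], times[g2], events[g2]
        )
        if stat >= observed - 1e-12:
            count += 1
    return count / n_perm


def oracle_odds_ratio(table):
    """Closed-form cross-product OR with Woolf CI and Wald p."""
    from scipy import stats

    (a, b), (c, d) = [list(map(float, row)) for row in table]
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orv = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    lo = math.exp(math.log(orv) - z * se)
    hi = math.exp(math.log(orv) + z * se)
    p = 2 * stats.norm.sf(abs(math.log(orv)) / se)
    return orv, lo, hi, p
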