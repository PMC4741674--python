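"""Cohort survival analysis: Kaplan-Meier, log-rank, odds ratios,
survival relative to prognosis, and blood-type/Forssman stratification.

The estimators are implemented directly from their defining formulas
(the product-limit estimator; the two-group log-rank statistic with
hypergeometric variance; the cross-product odds ratio with the Woolf
log-OR interval and Haldane-Anscombe correction), since they *are* the
analysis this package exists to reproduce; standard library
implementations serve as independent cross-checks in the test suite.

Group conventions: blood types pool into A/AB (blood-group A antigen is
self) versus B/O (A antigen is foreign); a Forssman responder shows a
>= 4-fold rise in total Ig to the Forssman disaccharide at the
2-3-month draw, i.e. a log2 increase >= 2 (boundary inclusive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

POOLED_GROUPS = ("A/AB", "B/O")
_POOL = {"A": "A/AB", "AB": "A/AB", "B": "B/O", "O": "B/O"}

#: log2 rise defining a Forssman responder (4-fold, boundary inclusive)
FORSSMAN_LOG2_RISE = 2.0


@dataclass
class KMCurve:
    """A Kaplan-Meier product-limit curve.

    ``times`` are the distinct event times (months, increasing);
    ``survival`` the step-function values S(t) just after each time;
    ``at_risk`` and ``n_events`` the risk-set size and death count at
    each time.  S(0) = 1 and S is non-increasing.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        """S(t): the step function evaluated at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (NaN if S never
        reaches 0.5)."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if len(below) else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


def km_estimate(
    times: Sequence[float], events: Optional[Sequence[bool]] = None
) -> KMCurve:
    """Product-limit survival estimate.

    At tied times deaths are processed before censorings (a subject
    censored at t is still at risk for deaths at t).  With no censoring
    the curve equals the empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0) or not np.isfinite(times).all():
        raise ValueError("times must be positive and finite")
    events = (
        np.ones_like(times, dtype=bool)
        if events is None
        else np.asarray(events, dtype=bool)
    )
    if events.shape != times.shape:
        raise ValueError("times and events must have equal length")

    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    uniq = np.unique(times[events]) if events.any() else np.unique(times)

    surv, at_risk, n_events = [], [], []
    s = 1.0
    for t in uniq:
        n_i = int((times >= t).sum())  # censored at t count as at risk
        d_i = int(((times == t) & events).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        n_events.append(d_i)
    return KMCurve(
        times=uniq,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_events),
        n_total=len(times),
    )


@dataclass
class GroupComparison:
    """Two-group survival comparison (log-rank test + KM medians)."""

    groups: dict[str, KMCurve]
    logrank_chi2: float
    logrank_p: float
    medians: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "medians": dict(self.medians),
            "n": {g: c.n_total for g, c in self.groups.items()},
        }


def logrank_statistic(
    times1: np.ndarray,
    events1: np.ndarray,
    times2: np.ndarray,
    events2: np.ndarray,
) -> float:
    """Two-group log-rank chi-square (1 df): (O1-E1)^2 / V with the
    hypergeometric variance accumulated over distinct event times."""
    all_times = np.concatenate([times1, times2])
    all_events = np.concatenate([events1, events2])
    group = np.concatenate([np.zeros(len(times1)), np.ones(len(times2))])
    event_times = np.unique(all_times[all_events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = all_times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((all_times == t) & all_events).sum()
        d1 = ((times1 == t) & events1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def logrank_test(
    group_data: Mapping[str, tuple[Sequence[float], Sequence[bool]]]
) -> GroupComparison:
    """Standard two-group log-rank test; p from the chi-square(1) upper
    tail.  Requires exactly two groups and at least one event."""
    if len(group_data) != 2:
        raise ValueError("log-rank comparison requires exactly two groups")
    names = sorted(group_data)
    arrays = {}
    for g in names:
        t, e = group_data[g]
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"group {g!r} is empty")
        arrays[g] = (t, e)
    total_events = sum(int(e.sum()) for _, e in arrays.values())
    if total_events == 0:
        raise ValueError("no events in either group")
    chi2 = logrank_statistic(*arrays[names[0]], *arrays[names[1]])
    p = float(max(stats.chi2.sf(chi2, df=1), np.finfo(float).tiny))
    curves = {g: km_estimate(t, e) for g, (t, e) in arrays.items()}
    return GroupComparison(
        groups=curves,
        logrank_chi2=chi2,
        logrank_p=p,
        medians={g: c.median for g, c in curves.items()},
    )


@dataclass
class OddsResult:
    """A 2x2 odds ratio with Woolf 95% CI and Wald p-value."""

    table: np.ndarray  # as analysed (after any Haldane-Anscombe +0.5)
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    fisher_p: float
    corrected: bool

    def to_dict(self) -> dict:
        return {
            "table": self.table.tolist(),
            "odds_ratio": self.or_value,
            "ci95": [self.ci_low, self.ci_high],
            "p_wald": self.p,
            "p_fisher": self.fisher_p,
            "haldane_corrected": self.corrected,
        }


def odds_ratio(table: Sequence[Sequence[float]]) -> OddsResult:
    """Cross-product odds ratio for a 2x2 count table [[a, b], [c, d]].

    OR = ad/bc; 95% CI from the normal approximation on log OR with
    SE = sqrt(1/a + 1/b + 1/c + 1/d) (Woolf); if any cell is zero,
    0.5 is added to every cell (Haldane-Anscombe) before computation.
    The two-sided p comes from the Wald z on log OR; Fisher's exact p
    (on the uncorrected integer table) is reported alongside.
    """
    raw = np.asarray(table, dtype=float)
    if raw.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(raw < 0) or not np.allclose(raw, np.round(raw)):
        raise ValueError("table must hold non-negative integer counts")
    if raw[0].sum() == 0 or raw[1].sum() == 0 or raw[:, 0].sum() == 0 or raw[:, 1].sum() == 0:
        raise ValueError("a row or column of the 2x2 table is all zero")
    corrected = bool((raw == 0).any())
    work = raw + 0.5 if corrected else raw
    a, b = work[0]
    c, d = work[1]
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_value)
    ci_low = math.exp(log_or - 1.959963984540054 * se)
    ci_high = math.exp(log_or + 1.959963984540054 * se)
    z = log_or / se
    p = 2 * stats.norm.sf(abs(z))
    fisher_p = float(stats.fisher_exact(raw.astype(int))[1])
    return OddsResult(
        table=work,
        or_value=float(or_value),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p=float(p),
        fisher_p=fisher_p,
        corrected=corrected,
    )


# -- stratification and cohort-level analyses --------------------------


def pool_blood_type(blood_type: str) -> Optional[str]:
    """A/AB vs B/O pooling (None for unknown/unclassified)."""
    return _POOL.get(blood_type)


def is_forssman_responder(pre_log2: float, post_log2: float) -> bool:
    return (post_log2 - pre_log2) >= FORSSMAN_LOG2_RISE


def stratify(
    cohort: pd.DataFrame, blood_type_column: str = "blood_type"
) -> pd.DataFrame:
    """Assign pooled blood-type groups and Forssman-response strata.

    Adds ``bt_group`` (A/AB vs B/O), ``forssman_response`` and the
    combined four-way ``stratum``.  Patients with unknown or
    unclassified blood type are excluded with a logged count.
    """
    out = cohort.copy()
    out["bt_group"] = out[blood_type_column].map(_POOL)
    n_dropped = int(out["bt_group"].isna().sum())
    if n_dropped:
        logger.warning(
            "excluded %d patient(s) with unknown/unclassified blood type",
            n_dropped,
        )
        out = out.dropna(subset=["bt_group"])
    if {"forssman_pre", "forssman_post"} <= set(out.columns):
        out["forssman_response"] = (
            out["forssman_post"] - out["forssman_pre"]
        ) >= FORSSMAN_LOG2_RISE
        out["stratum"] = out["bt_group"] + np.where(
            out["forssman_response"], " Fs+", " Fs-"
        )
    return out


@dataclass
class OsHpsResult:
    """Survival relative to prognosis (OS - HPS) by pooled blood type."""

    differences: pd.Series
    group_medians: dict[str, float]
    t_statistic: float
    t_p: float  # the stated between-group test (two-tailed t)
    mannwhitney_p: float  # rank-based alternative, reported alongside
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "group_medians": dict(self.group_medians),
            "t_p": self.t_p,
            "mannwhitney_p": self.mannwhitney_p,
            "n_excluded": self.n_excluded,
        }


def os_minus_hps(
    cohort: pd.DataFrame, blood_type_column: str = "blood_type"
) -> OsHpsResult:
    """Per-patient OS - HPS (months) with pooled-group medians.

    Groups are compared with a two-tailed t-test (the conventional
    stated test) and a Mann-Whitney rank-sum test side by side.
    Patients missing either value are excluded with a logged count.
    """
    ok = cohort["os_months"].notna() & cohort["hps_months"].notna()
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("excluded %d patient(s) missing OS or HPS", n_excluded)
    strat = stratify(cohort[ok], blood_type_column=blood_type_column)
    diffs = strat["os_months"] - strat["hps_months"]
    groups = {
        g: diffs[strat["bt_group"] == g].to_numpy() for g in POOLED_GROUPS
    }
    medians = {g: float(np.median(v)) if len(v) else math.nan for g, v in groups.items()}
    g1, g2 = (groups[g] for g in POOLED_GROUPS)
    if len(g1) > 1 and len(g2) > 1:
        if np.ptp(np.concatenate([g1, g2])) == 0:
            t_stat, t_p, mw_p = 0.0, 1.0, 1.0
        else:
            t_stat, t_p = stats.ttest_ind(g1, g2, equal_var=False)
            mw_p = float(stats.mannwhitneyu(g1, g2, alternative="two-sided")[1])
    else:
        t_stat, t_p, mw_p = math.nan, math.nan, math.nan
    return OsHpsResult(
        differences=diffs,
        group_medians=medians,
        t_statistic=float(t_stat),
        t_p=float(t_p),
        mannwhitney_p=float(mw_p),
        n_excluded=n_excluded,
    )


def compare_survival_by_group(
    cohort: pd.DataFrame,
    group_column: str = "bt_group",
    time_column: str = "os_months",
    event_column: str = "event",
) -> GroupComparison:
    """Log-rank comparison between the two levels of ``group_column``."""
    levels = sorted(cohort[group_column].dropna().unique())
    if len(levels) != 2:
        raise ValueError(
            f"expected exactly two groups in {group_column!r}, got {levels}"
        )
    data = {
        str(g): (
            cohort.loc[cohort[group_column] == g, time_column].to_numpy(dtype=float),
            cohort.loc[cohort[group_column] == g, event_column].to_numpy(dtype=bool),
        )
        for g in levels
    }
    return logrank_test(data)


def longer_than_threshold_odds(
    cohort: pd.DataFrame,
    threshold_months: Optional[float] = None,
    group_column: str = "bt_group",
) -> tuple[OddsResult, float]:
    """Odds that a patient outlives a survival threshold, B/O vs A/AB.

    The default threshold is the whole-cohort median OS.  Returns the
    odds result and the threshold used.  Rows: B/O then A/AB; columns:
    lived longer / did not.
    """
    if threshold_months is None:
        threshold_months = float(cohort["os_months"].median())
    table = []
    for g in ("B/O", "A/AB"):
        sub = cohort[cohort[group_column] == g]
        longer = int((sub["os_months"] > threshold_months).sum())
        table.append([longer, len(sub) - longer])
    return odds_ratio(table), threshold_months


def outlive_prediction_odds(
    cohort: pd.DataFrame, group_column: str = "bt_group"
) -> OddsResult:
    """Odds that a patient outlives their Halabi prediction (OS > HPS),
    B/O vs A/AB."""
    table = []
    for g in ("B/O", "A/AB"):
        sub = cohort[cohort[group_column] == g]
        longer = int((sub["os_months"] > sub["hps_months"]).sum())
        table.append([longer, len(sub) - longer])
    return odds_ratio(table)
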