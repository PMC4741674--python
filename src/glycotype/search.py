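"""Systematic threshold and component optimisation.

This is the method-development half of reverse typing: given training
sera of known blood type, search the space of (component pair, band
thresholds) for two-component methods, or fit the threshold bands of a
fixed multi-component/flow-chart method, maximising accuracy among
classified samples subject to a minimum classification-rate constraint
(accuracy is preferred over classification rate, so accuracy is the
primary objective and the rate breaks ties).

Two-component search is exhaustive over candidate pairs and all
``lower <= upper`` threshold pairs from the grid.  Multi-rule methods
are fitted by coordinate ascent over rules (a fixed rule order, two
full sweeps), which is asserted equivalent to exhaustive search on
small instances in the test suite.

The module also flags suspected mislabels: samples whose confident
stage-1 call contradicts their recorded blood type, ranked by how far
their signals sit from the decision thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .evaluation import EvaluationReport
from .io import ProfileMatrix
from .rules import (
    NEGATIVE,
    POSITIVE,
    UNCLASSIFIED,
    UNCLASSIFIED_CALL,
    ThresholdRule,
    TypingMethod,
    as_frame,
    averaged,
    build_flowchart_method,
    canonical_flowchart_targets,
    predict_types,
    single,
)

Target = tuple[str, str]

# call codes for vectorised scoring
CALL_CODES = {UNCLASSIFIED_CALL: 0, "A": 1, "B": 2, "AB": 3, "O": 4}
CODE_CALLS = {v: k for k, v in CALL_CODES.items()}
# (anti-A band + 1, anti-B band + 1) -> call code
_CODE_TABLE = np.zeros((3, 3), dtype=np.int8)
_CODE_TABLE[POSITIVE + 1, POSITIVE + 1] = CALL_CODES["O"]
_CODE_TABLE[NEGATIVE + 1, POSITIVE + 1] = CALL_CODES["A"]
_CODE_TABLE[POSITIVE + 1, NEGATIVE + 1] = CALL_CODES["B"]
_CODE_TABLE[NEGATIVE + 1, NEGATIVE + 1] = CALL_CODES["AB"]

#: blood types for which the determinant is foreign (elevated signal)
_FOREIGN_TYPES = {"A": ("B", "O"), "B": ("A", "O")}


@dataclass(frozen=True)
class SearchSpec:
    """Search space for two-component method optimisation."""

    candidate_a: tuple[Target, ...]
    candidate_b: tuple[Target, ...]
    grid: tuple[float, ...]
    min_classification_rate: float = 0.80
    objective: str = "accuracy_then_rate"

    def __post_init__(self) -> None:
        if not self.candidate_a or not self.candidate_b:
            raise ValueError("candidate lists must be non-empty")
        if len(self.grid) < 2:
            raise ValueError("grid needs at least 2 points")
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("grid must be strictly increasing")
        # rates > 1 are permitted and simply infeasible (empty result)
        if self.min_classification_rate <= 0:
            raise ValueError("min_classification_rate must be positive")
        if self.objective != "accuracy_then_rate":
            raise ValueError(f"unknown objective {self.objective!r}")


def default_grid(values: np.ndarray, step: float = 0.25) -> tuple[float, ...]:
    """A threshold grid in ``step`` log2-unit increments spanning (and
    slightly exceeding) the observed signal range."""
    lo = np.floor(np.min(values) / step) * step - step
    hi = np.ceil(np.max(values) / step) * step + step
    n = int(round((hi - lo) / step)) + 1
    return tuple(np.round(lo + step * np.arange(n), 10))


def _coerce_labels(frame: pd.DataFrame, labels) -> pd.Series:
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(frame.index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValueError(f"no blood-type label for sample(s) {missing[:5]}")
    return labels.astype(str)


def _label_codes(labels: pd.Series) -> np.ndarray:
    unknown = set(labels.unique()) - set(CALL_CODES)
    if unknown:
        raise ValueError(f"unknown blood type label(s) {sorted(unknown)}")
    return labels.map(CALL_CODES).to_numpy(dtype=np.int8)


def _target_signal(frame: pd.DataFrame, target: Target) -> np.ndarray:
    if target not in frame.columns:
        raise KeyError(
            f"profile matrix lacks target component={target[0]!r} "
            f"isotype={target[1]!r}"
        )
    sig = frame[target].to_numpy(dtype=float)
    if not np.isfinite(sig).all():
        raise ValueError(f"non-finite signal in target {target!r}")
    return sig


def _band_matrix(sig: np.ndarray, lowers: np.ndarray, uppers: np.ndarray) -> np.ndarray:
    """(n, k) band codes for one signal against k threshold pairs."""
    s = sig[:, None]
    return (s > uppers[None, :]).astype(np.int8) - (s < lowers[None, :]).astype(np.int8)


def _grid_pairs(grid: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """All lower <= upper pairs from a grid."""
    g = np.asarray(grid, dtype=float)
    ii, jj = np.triu_indices(len(g))
    return g[ii], g[jj]


def _acc_rate(
    calls: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accuracy-among-classified and classification rate, vectorised
    over trailing axes of ``calls`` (samples on axis 0)."""
    classified = calls != 0
    n = calls.shape[0]
    n_cls = classified.sum(axis=0)
    n_corr = (classified & (calls == y.reshape((-1,) + (1,) * (calls.ndim - 1)))).sum(
        axis=0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        acc = np.where(n_cls > 0, n_corr / np.maximum(n_cls, 1), -1.0)
    return acc, n_cls / n, n_cls, n_corr


# -- two-component exhaustive search -----------------------------------


@dataclass
class SearchResult:
    """Ranked survivors of a grid search, plus a status message."""

    ranked: list[tuple[TypingMethod, EvaluationReport]] = field(default_factory=list)
    status: str = "ok"

    def __iter__(self):
        return iter(self.ranked)

    def __len__(self) -> int:
        return len(self.ranked)

    def __getitem__(self, i):
        return self.ranked[i]

    @property
    def best(self) -> Optional[tuple[TypingMethod, EvaluationReport]]:
        return self.ranked[0] if self.ranked else None


def grid_search_two_component(
    train: Union[ProfileMatrix, pd.DataFrame],
    labels: Union[Mapping[str, str], pd.Series],
    spec: SearchSpec,
    max_results: Optional[int] = None,
) -> SearchResult:
    """Exhaustively evaluate all (A candidate, B candidate, thresholds).

    Survivors meet the minimum classification rate on the training data;
    they are ranked by accuracy among classified, then classification
    rate, then smaller total band width, then lexicographic target
    names, then threshold values (full determinism).
    """
    frame = as_frame(train)
    y = _label_codes(_coerce_labels(frame, labels))
    present = set(np.unique(y))
    if len(present) < 1 or len(frame) == 0:
        raise ValueError("empty training data")

    lowers, uppers = _grid_pairs(spec.grid)
    widths = uppers - lowers
    k = len(lowers)
    n = len(frame)
    rows = []
    for a_target in spec.candidate_a:
        sig_a = _target_signal(frame, a_target)
        bands_a = _band_matrix(sig_a, lowers, uppers)  # (n, k)
        for b_target in spec.candidate_b:
            sig_b = _target_signal(frame, b_target)
            bands_b = _band_matrix(sig_b, lowers, uppers)
            # chunk over A threshold pairs to bound memory
            chunk = max(1, int(2e7) // max(1, n * k))
            for start in range(0, k, chunk):
                sl = slice(start, min(start + chunk, k))
                calls = _CODE_TABLE[
                    bands_a[:, sl, None] + 1, bands_b[:, None, :] + 1
                ]  # (n, ka, k)
                acc, rate, n_cls, n_corr = _acc_rate(calls, y)
                ok = rate + 1e-12 >= spec.min_classification_rate
                ia, ib = np.nonzero(ok)
                for i, j in zip(ia, ib):
                    gi = start + i
                    rows.append(
                        (
                            -acc[i, j],
                            -rate[i, j],
                            widths[gi] + widths[j],
                            a_target[0],
                            a_target[1],
                            b_target[0],
                            b_target[1],
                            lowers[gi],
                            uppers[gi],
                            lowers[j],
                            uppers[j],
                            int(n_cls[i, j]),
                            int(n_corr[i, j]),
                        )
                    )
    if not rows:
        return SearchResult(
            [],
            status=(
                "no method met the minimum classification rate "
                f"{spec.min_classification_rate:g} on the training data"
            ),
        )
    rows.sort()
    if max_results is not None:
        rows = rows[:max_results]
    ranked = []
    for row in rows:
        (_, _, _, a_comp, a_iso, b_comp, b_iso, la, ua, lb, ub, n_cls, n_corr) = row
        method = TypingMethod(
            a_rules=(single(a_comp, a_iso, la, ua),),
            b_rules=(single(b_comp, b_iso, lb, ub),),
            combination="pairwise",
        )
        report = EvaluationReport(
            n_total=n, n_classified=n_cls, n_correct=n_corr
        )
        ranked.append((method, report))
    return SearchResult(ranked, status="ok")


# -- multi-rule coordinate-ascent fitting ------------------------------


def _side_agree(bands: Sequence[np.ndarray]) -> np.ndarray:
    """Agreement band over one determinant's rules (arrays broadcast on
    the trailing candidate axis)."""
    agreed = np.broadcast_arrays(*bands)[0].copy() if len(bands) > 1 else bands[0]
    for other in bands[1:]:
        agreed = np.where((agreed == other) & (agreed != UNCLASSIFIED), agreed, UNCLASSIFIED)
    return agreed


def _eval_rulesets(
    band_a: Sequence[np.ndarray],
    band_b: Sequence[np.ndarray],
    y: np.ndarray,
    stage2_a: Optional[Sequence[np.ndarray]] = None,
    stage2_b: Optional[Sequence[np.ndarray]] = None,
):
    """Joint accuracy/rate for an all-agree (optionally two-stage)
    method; band arrays are (n, 1) or (n, k)."""
    calls = _CODE_TABLE[_side_agree(band_a) + 1, _side_agree(band_b) + 1]
    if stage2_a is not None:
        calls2 = _CODE_TABLE[_side_agree(stage2_a) + 1, _side_agree(stage2_b) + 1]
        calls = np.where(calls != 0, calls, calls2)
    acc, rate, n_cls, n_corr = _acc_rate(calls, y)
    return acc, rate


@dataclass
class _Rule:
    key: str
    side: str  # "A" | "B"
    isotype: str
    components: tuple[str, ...]
    signal: np.ndarray
    lower: float = 0.0
    upper: float = 0.0
    in_stage2: bool = False

    def to_threshold_rule(self) -> ThresholdRule:
        if len(self.components) == 1:
            return single(self.components[0], self.isotype, self.lower, self.upper)
        return averaged(self.components, self.isotype, self.lower, self.upper)


def _edge_margin(signal: np.ndarray, lowers: np.ndarray, uppers: np.ndarray) -> np.ndarray:
    """Per threshold pair, the distance from the nearest sample signal
    to the nearer band edge (larger = more robust thresholds)."""
    d_low = np.abs(signal[:, None] - lowers[None, :])
    d_up = np.abs(signal[:, None] - uppers[None, :])
    return np.minimum(d_low, d_up).min(axis=0)


def _init_rule(rule: _Rule, y_types: np.ndarray, grid) -> None:
    """Initialise one rule's band to maximise its own banding
    correctness (foreign samples positive, self samples negative)."""
    lowers, uppers = _grid_pairs(grid)
    foreign = np.isin(y_types, _FOREIGN_TYPES[rule.side])
    bands = _band_matrix(rule.signal, lowers, uppers)  # (n, k)
    correct = np.where(foreign[:, None], bands == POSITIVE, bands == NEGATIVE)
    score = correct.sum(axis=0)
    margin = _edge_margin(rule.signal, lowers, uppers)
    order = np.lexsort((uppers, lowers, uppers - lowers, -margin, -score))
    best = order[0]
    rule.lower, rule.upper = float(lowers[best]), float(uppers[best])


def _ascend(
    rules: list[_Rule],
    y: np.ndarray,
    y_types: np.ndarray,
    grids: Mapping[str, Sequence[float]],
    stringency: Optional[float],
    min_rate: float = 0.80,
    n_sweeps: int = 2,
) -> None:
    """Coordinate ascent over rules in list order, ``n_sweeps`` full
    sweeps, maximising (accuracy, rate, -width) lexicographically among
    candidates meeting the minimum classification rate (accuracy must
    not be bought by refusing to classify); when no candidate is
    feasible the rate itself is maximised first."""
    for rule in rules:
        _init_rule(rule, y_types, grids[rule.key])

    def bands_for(rule: _Rule, lowers: np.ndarray, uppers: np.ndarray) -> np.ndarray:
        return _band_matrix(rule.signal, lowers, uppers)

    for _ in range(n_sweeps):
        for target_rule in rules:
            lowers, uppers = _grid_pairs(grids[target_rule.key])
            widths = uppers - lowers

            def side_bands(side: str, stage2: bool) -> list[np.ndarray]:
                out = []
                for r in rules:
                    if r.side != side or (stage2 and not r.in_stage2):
                        continue
                    widen = stringency if stage2 else 0.0
                    if r is target_rule:
                        out.append(bands_for(r, lowers - widen, uppers + widen))
                    else:
                        out.append(
                            bands_for(
                                r,
                                np.array([r.lower - widen]),
                                np.array([r.upper + widen]),
                            )
                        )
                return out

            stage2_a = side_bands("A", True) if stringency is not None else None
            stage2_b = side_bands("B", True) if stringency is not None else None
            acc, rate = _eval_rulesets(
                side_bands("A", False),
                side_bands("B", False),
                y,
                stage2_a,
                stage2_b,
            )
            feasible = rate + 1e-12 >= min_rate
            # where the joint objective is flat, prefer candidates that
            # band this rule's own signal correctly (foreign positive,
            # self negative), then edges farthest from any training
            # signal (robust thresholds)
            foreign = np.isin(y_types, _FOREIGN_TYPES[target_rule.side])
            own_bands = _band_matrix(target_rule.signal, lowers, uppers)
            own_score = np.where(
                foreign[:, None], own_bands == POSITIVE, own_bands == NEGATIVE
            ).sum(axis=0)
            margin = _edge_margin(target_rule.signal, lowers, uppers)
            if feasible.any():
                keys = (uppers, lowers, widths, -margin, -own_score, -rate, -acc,
                        ~feasible)
            else:
                keys = (uppers, lowers, widths, -margin, -own_score, -acc, -rate)
            order = np.lexsort(keys)
            best = order[0]
            target_rule.lower = float(lowers[best])
            target_rule.upper = float(uppers[best])


def fit_flowchart_thresholds(
    train: Union[ProfileMatrix, pd.DataFrame],
    labels: Union[Mapping[str, str], pd.Series],
    targets: Optional[tuple] = None,
    stringency: float = 1.0,
    grid_step: float = 0.25,
    min_classification_rate: float = 0.80,
    n_sweeps: int = 2,
) -> TypingMethod:
    """Fit the 10-component two-stage flow-chart method.

    The four stage-1 bands (averaged anti-A IgG, anti-A IgM, averaged
    anti-B IgG, anti-B IgM — optimised in that fixed order) are chosen
    from a ``grid_step``-spaced grid by coordinate ascent maximising
    accuracy-then-rate on the training labels, subject to classifying
    at least ``min_classification_rate`` of them; stage 2 keeps only
    the IgG rules with bands widened by ``stringency`` log2 units.
    """
    frame = as_frame(train)
    y_series = _coerce_labels(frame, labels)
    y = _label_codes(y_series)
    y_types = y_series.to_numpy(dtype=object)
    a_igg, a_igm, b_igg, b_igm = targets or canonical_flowchart_targets()

    def avg_signal(components: Sequence[str], isotype: str) -> np.ndarray:
        return np.mean(
            [_target_signal(frame, (c, isotype)) for c in components], axis=0
        )

    rules = [
        _Rule("A_IgG", "A", "IgG", tuple(a_igg), avg_signal(a_igg, "IgG"), in_stage2=True),
        _Rule("A_IgM", "A", "IgM", (a_igm,), _target_signal(frame, (a_igm, "IgM"))),
        _Rule("B_IgG", "B", "IgG", tuple(b_igg), avg_signal(b_igg, "IgG"), in_stage2=True),
        _Rule("B_IgM", "B", "IgM", (b_igm,), _target_signal(frame, (b_igm, "IgM"))),
    ]
    grids = {r.key: default_grid(r.signal, grid_step) for r in rules}
    _ascend(
        rules, y, y_types, grids,
        stringency=stringency,
        min_rate=min_classification_rate,
        n_sweeps=n_sweeps,
    )
    by_key = {r.key: r for r in rules}
    return build_flowchart_method(
        a_igg_band=(by_key["A_IgG"].lower, by_key["A_IgG"].upper),
        a_igm_band=(by_key["A_IgM"].lower, by_key["A_IgM"].upper),
        b_igg_band=(by_key["B_IgG"].lower, by_key["B_IgG"].upper),
        b_igm_band=(by_key["B_IgM"].lower, by_key["B_IgM"].upper),
        stringency=stringency,
        targets=(tuple(a_igg), a_igm, tuple(b_igg), b_igm),
    )


def fit_agreement_thresholds(
    train: Union[ProfileMatrix, pd.DataFrame],
    labels: Union[Mapping[str, str], pd.Series],
    a_targets: Sequence[Target],
    b_targets: Sequence[Target],
    grid_step: float = 0.25,
    min_classification_rate: float = 0.80,
    n_sweeps: int = 2,
) -> TypingMethod:
    """Fit a single-stage all-agree multi-component method (e.g. the
    four-component IgG+IgM systems) by the same coordinate ascent."""
    frame = as_frame(train)
    y_series = _coerce_labels(frame, labels)
    y = _label_codes(y_series)
    y_types = y_series.to_numpy(dtype=object)
    rules = []
    for side, targets in (("A", a_targets), ("B", b_targets)):
        for comp, iso in targets:
            sig = _target_signal(frame, (comp, iso))
            rules.append(_Rule(f"{side}_{comp}_{iso}", side, iso, (comp,), sig))
    grids = {r.key: default_grid(r.signal, grid_step) for r in rules}
    _ascend(
        rules, y, y_types, grids,
        stringency=None,
        min_rate=min_classification_rate,
        n_sweeps=n_sweeps,
    )
    a_rules = tuple(r.to_threshold_rule() for r in rules if r.side == "A")
    b_rules = tuple(r.to_threshold_rule() for r in rules if r.side == "B")
    combination = "pairwise" if len(a_rules) == len(b_rules) == 1 else "all_agree"
    return TypingMethod(a_rules=a_rules, b_rules=b_rules, combination=combination)


# -- mislabel flagging -------------------------------------------------


def flag_suspected_mislabels(
    profiles: Union[ProfileMatrix, pd.DataFrame],
    labels: Union[Mapping[str, str], pd.Series],
    method: TypingMethod,
) -> pd.DataFrame:
    """Samples whose confident (non-unclassified) call contradicts the
    recorded blood type.

    The call is the method's final call (a stage-2 call is as final as
    a stage-1 call); the margin is the minimum distance of any signal
    contributing to the deciding stage to its nearest threshold.
    Output is sorted by descending margin (most confidently
    contradicted first).  Unclassified samples are never flagged.
    """
    frame = as_frame(profiles)
    labels = _coerce_labels(frame, labels)
    result = predict_types(frame, method)
    calls = result["call"]
    suspects = calls.index[(calls != UNCLASSIFIED_CALL) & (calls != labels)]
    rows = []
    stage_rules = {
        1: list(method.a_rules) + list(method.b_rules),
        2: list(method.stage2_a_rules) + list(method.stage2_b_rules),
    }
    for sample in suspects:
        rules = stage_rules[int(result.loc[sample, "stage"])]
        margins = []
        for rule in rules:
            sig = np.mean([frame.at[sample, t] for t in rule.targets])
            margins.append(min(abs(sig - rule.lower), abs(sig - rule.upper)))
        rows.append(
            {
                "sample_id": sample,
                "recorded_blood_type": labels[sample],
                "called_blood_type": calls[sample],
                "margin": float(min(margins)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["sample_id", "recorded_blood_type", "called_blood_type", "margin"],
    )
    return out.sort_values(
        ["margin", "sample_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


# -- sklearn-style estimator -------------------------------------------


class TwoComponentGridSearch(BaseEstimator):
    """Exhaustive two-component method search as an estimator.

    ``fit(X, y)`` runs :func:`grid_search_two_component`; the fitted
    attributes are ``results_`` (a :class:`SearchResult`),
    ``best_method_`` and ``best_report_``.  ``predict`` classifies with
    the best method.
    """

    def __init__(
        self,
        candidate_a: Sequence[Target] = (),
        candidate_b: Sequence[Target] = (),
        grid: Optional[Sequence[float]] = None,
        grid_step: float = 0.25,
        min_classification_rate: float = 0.80,
        max_results: Optional[int] = None,
    ):
        self.candidate_a = candidate_a
        self.candidate_b = candidate_b
        self.grid = grid
        self.grid_step = grid_step
        self.min_classification_rate = min_classification_rate
        self.max_results = max_results

    def fit(self, X, y):
        frame = as_frame(X)
        grid = self.grid
        if grid is None:
            sigs = np.concatenate(
                [
                    _target_signal(frame, tuple(t))
                    for t in list(self.candidate_a) + list(self.candidate_b)
                ]
            )
            grid = default_grid(sigs, self.grid_step)
        spec = SearchSpec(
            candidate_a=tuple(tuple(t) for t in self.candidate_a),
            candidate_b=tuple(tuple(t) for t in self.candidate_b),
            grid=tuple(grid),
            min_classification_rate=self.min_classification_rate,
        )
        self.results_ = grid_search_two_component(
            X, y, spec, max_results=self.max_results
        )
        if self.results_.ranked:
            self.best_method_, self.best_report_ = self.results_.best
        else:
            self.best_method_ = None
            self.best_report_ = None
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "results_"):
            raise AttributeError("estimator is not fitted; call fit first")
        if self.best_method_ is None:
            raise ValueError(f"search produced no method: {self.results_.status}")
        return predict_types(X, self.best_method_)["call"].to_numpy()
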