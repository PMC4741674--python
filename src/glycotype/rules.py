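"""Banded-threshold blood-type classification.

Reverse ABO typing infers blood type from the anti-A and anti-B
antibodies present in serum (Landsteiner's rule: you carry antibodies
against the ABO antigens your own cells lack).  Each piece of evidence
is a threshold band over a log2 RFU signal — either a single
(component, isotype) measurement or the arithmetic mean of several —
partitioned into *negative* (below ``lower``), *positive* (above
``upper``) and *unclassified* (in between, boundaries inclusive).

Anti-A and anti-B band calls combine into a blood type:

========  ========  ====
anti-A    anti-B    call
========  ========  ====
positive  positive  O
negative  positive  A
positive  negative  B
negative  negative  AB
========  ========  ====

with any unclassified band yielding an unclassified call.  Three
combination modes are supported: ``pairwise`` (one rule per
determinant), ``all_agree`` (every rule for a determinant must produce
the same non-unclassified band) and ``flowchart`` (the two-stage
10-component method: stage 1 requires agreement between the averaged
IgG signal over four glycans and a single IgM signal per determinant;
samples left unclassified are re-evaluated at stage 2 with fewer
targets and more stringent — wider — unclassified bands).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin

from .components import (
    normalize_name,
    FLOWCHART_A_IGG,
    FLOWCHART_A_IGM,
    FLOWCHART_B_IGG,
    FLOWCHART_B_IGM,
    FLOWCHART_NAME_VARIANTS,
)
from .io import ProfileMatrix

# band codes
NEGATIVE, UNCLASSIFIED, POSITIVE = -1, 0, 1
BAND_NAMES = {NEGATIVE: "negative", UNCLASSIFIED: "unclassified", POSITIVE: "positive"}

UNCLASSIFIED_CALL = "unclassified"
CALLS = ("A", "B", "AB", "O", UNCLASSIFIED_CALL)

# (anti-A band, anti-B band) -> call
_CALL_TABLE = {
    (POSITIVE, POSITIVE): "O",
    (NEGATIVE, POSITIVE): "A",
    (POSITIVE, NEGATIVE): "B",
    (NEGATIVE, NEGATIVE): "AB",
}


Target = tuple[str, str]  # (component name, isotype)


@dataclass(frozen=True)
class ThresholdRule:
    """One banded threshold over a (possibly averaged) signal.

    ``targets`` is a tuple of (component, isotype) pairs; when more than
    one is given the rule applies to the arithmetic mean of their log2
    signals (averaging happens before banding).
    """

    targets: tuple[Target, ...]
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("a rule needs at least one (component, isotype) target")
        if self.lower > self.upper:
            raise ValueError(
                f"lower ({self.lower}) must not exceed upper ({self.upper})"
            )
        for component, isotype in self.targets:
            if isotype not in ("IgG", "IgM"):
                raise ValueError(f"unknown isotype {isotype!r}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def widen(self, amount: float) -> "ThresholdRule":
        """A more stringent copy: unclassified band widened by ``amount``
        on each side."""
        return replace(self, lower=self.lower - amount, upper=self.upper + amount)

    def describe(self) -> str:
        names = "+".join(f"{c}({i})" for c, i in self.targets)
        return f"{names}[{self.lower:g},{self.upper:g}]"


def single(component: str, isotype: str, lower: float, upper: float) -> ThresholdRule:
    return ThresholdRule(((normalize_name(component), isotype),), lower, upper)


def averaged(
    components: Sequence[str], isotype: str, lower: float, upper: float
) -> ThresholdRule:
    return ThresholdRule(
        tuple((normalize_name(c), isotype) for c in components), lower, upper
    )


def band(signal: float, rule: ThresholdRule) -> str:
    """Band one signal: positive above ``upper``, negative below
    ``lower``, unclassified otherwise (boundary values unclassified)."""
    if not np.isfinite(signal):
        raise ValueError(f"signal must be finite, got {signal!r}")
    return BAND_NAMES[int(band_array(np.asarray([signal]), rule.lower, rule.upper)[0])]


def band_array(signals: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Vectorised banding to codes -1/0/+1.

    Values exactly equal to a threshold are unclassified (conservative:
    accuracy is preferred over classification rate).
    """
    out = np.zeros(np.shape(signals), dtype=np.int8)
    out[signals > upper] = POSITIVE
    out[signals < lower] = NEGATIVE
    return out


def combine_bands(a_band: str, b_band: str) -> str:
    """Combine anti-A and anti-B band calls into a blood type."""
    codes = {v: k for k, v in BAND_NAMES.items()}
    try:
        a, b = codes[a_band], codes[b_band]
    except KeyError as exc:
        raise ValueError(f"unknown band {exc.args[0]!r}") from None
    return _CALL_TABLE.get((a, b), UNCLASSIFIED_CALL)


@dataclass(frozen=True)
class TypingMethod:
    """A complete typing method: anti-A and anti-B rule sets plus
    combination logic, with an optional stricter stage-2 rule set for
    the flow-chart mode."""

    a_rules: tuple[ThresholdRule, ...]
    b_rules: tuple[ThresholdRule, ...]
    combination: str = "pairwise"
    stage2_a_rules: tuple[ThresholdRule, ...] = ()
    stage2_b_rules: tuple[ThresholdRule, ...] = ()

    def __post_init__(self) -> None:
        if self.combination not in ("pairwise", "all_agree", "flowchart"):
            raise ValueError(f"unknown combination {self.combination!r}")
        if not self.a_rules or not self.b_rules:
            raise ValueError("need at least one rule per determinant")
        if self.combination == "pairwise" and (
            len(self.a_rules) != 1 or len(self.b_rules) != 1
        ):
            raise ValueError("pairwise combination takes exactly one rule per side")
        if self.combination == "flowchart" and not (
            self.stage2_a_rules and self.stage2_b_rules
        ):
            raise ValueError("flowchart combination requires stage-2 rules")

    @property
    def rules(self) -> tuple[ThresholdRule, ...]:
        return (
            self.a_rules + self.b_rules + self.stage2_a_rules + self.stage2_b_rules
        )

    def targets(self) -> list[Target]:
        seen: dict[Target, None] = {}
        for rule in self.rules:
            for t in rule.targets:
                seen.setdefault(t, None)
        return list(seen)


@dataclass(frozen=True)
class BloodTypeCall:
    """A single blood-type call with its audit trail."""

    call: str
    stage: Optional[int]  # 1, 2, or None if never classified
    evidence: Mapping[str, str] = field(default_factory=dict)

    @property
    def classified(self) -> bool:
        return self.call != UNCLASSIFIED_CALL


# -- vectorised evaluation --------------------------------------------


def as_frame(profiles: Union[ProfileMatrix, pd.DataFrame]) -> pd.DataFrame:
    frame = profiles.data if isinstance(profiles, ProfileMatrix) else profiles
    if isinstance(profiles, ProfileMatrix) and profiles.scale != "log2":
        raise ValueError("profiles must be log2-normalised before typing")
    return frame

def rule_signal(frame: pd.DataFrame, rule: ThresholdRule) -> np.ndarray:
    """Per-sample signal for a rule (mean over its targets)."""
    cols = []
    for component, isotype in rule.targets:
        if (component, isotype) not in frame.columns:
            raise KeyError(
                f"profile matrix lacks target component={component!r} "
                f"isotype={isotype!r}"
            )
        cols.append(frame[(component, isotype)].to_numpy(dtype=float))
    stacked = np.vstack(cols)
    if not np.isfinite(stacked).all():
        bad = np.argwhere(~np.isfinite(stacked))
        comp, iso = rule.targets[bad[0, 0]]
        raise ValueError(
            f"non-finite signal for sample {frame.index[bad[0, 1]]!r}, "
            f"component {comp!r} ({iso})"
        )
    return stacked.mean(axis=0)


def determinant_bands(
    frame: pd.DataFrame, rules: Sequence[ThresholdRule]
) -> np.ndarray:
    """Agreed band per sample for one determinant.

    Every rule must yield the same non-unclassified band, otherwise the
    determinant is unclassified.
    """
    per_rule = np.vstack(
        [band_array(rule_signal(frame, r), r.lower, r.upper) for r in rules]
    )
    agreed = per_rule[0].copy()
    all_same = (per_rule == agreed).all(axis=0)
    agreed[~all_same] = UNCLASSIFIED
    return agreed


def combine_band_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised band-pair -> call lookup."""
    # index (a+1)*3 + (b+1) into a 9-entry table
    table = np.array(
        [
            _CALL_TABLE.get((ai, bi), UNCLASSIFIED_CALL)
            for ai in (NEGATIVE, UNCLASSIFIED, POSITIVE)
            for bi in (NEGATIVE, UNCLASSIFIED, POSITIVE)
        ],
        dtype=object,
    )
    return table[(a.astype(int) + 1) * 3 + (b.astype(int) + 1)]


def predict_types(
    profiles: Union[ProfileMatrix, pd.DataFrame], method: TypingMethod
) -> pd.DataFrame:
    """Classify every sample; returns a frame with ``call`` and
    ``stage`` columns (stage 0 = never classified).

    Stage-1 calls are final: a sample classified at stage 1 is not
    re-evaluated at stage 2.
    """
    frame = as_frame(profiles)
    a = determinant_bands(frame, method.a_rules)
    b = determinant_bands(frame, method.b_rules)
    calls = combine_band_codes(a, b)
    stage = np.where(calls != UNCLASSIFIED_CALL, 1, 0)
    if method.combination == "flowchart":
        pending = calls == UNCLASSIFIED_CALL
        if pending.any():
            sub = frame.loc[pending]
            a2 = determinant_bands(sub, method.stage2_a_rules)
            b2 = determinant_bands(sub, method.stage2_b_rules)
            calls2 = combine_band_codes(a2, b2)
            calls = calls.copy()
            calls[pending] = calls2
            stage = stage.copy()
            stage[pending] = np.where(calls2 != UNCLASSIFIED_CALL, 2, 0)
    return pd.DataFrame({"call": calls, "stage": stage}, index=frame.index)


def classify(
    profiles: Union[ProfileMatrix, pd.DataFrame],
    sample: str,
    method: TypingMethod,
) -> BloodTypeCall:
    """Classify one sample, retaining the per-rule evidence trail."""
    frame = as_frame(profiles)
    if sample not in frame.index:
        raise KeyError(f"unknown sample {sample!r}")
    row = frame.loc[[sample]]
    result = predict_types(row, method)
    call = result["call"].iloc[0]
    stage_num = int(result["stage"].iloc[0])

    evidence: dict[str, str] = {}
    stages: list[tuple[Sequence[ThresholdRule], Sequence[ThresholdRule], str]]
    stages = [(method.a_rules, method.b_rules, "stage1")]
    if method.combination == "flowchart" and stage_num != 1:
        stages.append((method.stage2_a_rules, method.stage2_b_rules, "stage2"))
    for a_rules, b_rules, label in stages:
        for side, rules in (("anti-A", a_rules), ("anti-B", b_rules)):
            for rule in rules:
                sig = rule_signal(row, rule)[0]
                evidence[f"{label}:{side}:{rule.describe()}"] = BAND_NAMES[
                    int(band_array(np.asarray([sig]), rule.lower, rule.upper)[0])
                ]
    return BloodTypeCall(
        call=call, stage=stage_num if stage_num else None, evidence=evidence
    )


# -- the 10-component flow-chart method --------------------------------


def canonical_flowchart_targets(
    a_igg: Sequence[str] = FLOWCHART_A_IGG,
    a_igm: str = FLOWCHART_A_IGM,
    b_igg: Sequence[str] = FLOWCHART_B_IGG,
    b_igm: str = FLOWCHART_B_IGM,
) -> tuple[tuple[str, ...], str, tuple[str, ...], str]:
    """Normalise the 10 flow-chart component names, warning on the
    published naming variants (e.g. BG-A2-Oct-17 for BG-A2-Oct-16)."""

    def fix(name: str) -> str:
        name = normalize_name(name)
        if name in FLOWCHART_NAME_VARIANTS:
            canonical = FLOWCHART_NAME_VARIANTS[name]
            warnings.warn(
                f"component {name!r} is a published naming variant of "
                f"{canonical!r}; using {canonical!r}",
                stacklevel=3,
            )
            return canonical
        return name

    return (
        tuple(fix(n) for n in a_igg),
        fix(a_igm),
        tuple(fix(n) for n in b_igg),
        fix(b_igm),
    )


def build_flowchart_method(
    a_igg_band: tuple[float, float],
    a_igm_band: tuple[float, float],
    b_igg_band: tuple[float, float],
    b_igm_band: tuple[float, float],
    stringency: float = 1.0,
    targets: Optional[tuple] = None,
) -> TypingMethod:
    """Assemble the two-stage 10-component method from fitted bands.

    Stage 2 keeps only the averaged-IgG rules, with each unclassified
    band widened by ``stringency`` log2 units on both sides (more
    stringent thresholds, fewer glycans).
    """
    a_igg, a_igm, b_igg, b_igm = targets or canonical_flowchart_targets()
    a_igg_rule = averaged(a_igg, "IgG", *a_igg_band)
    b_igg_rule = averaged(b_igg, "IgG", *b_igg_band)
    return TypingMethod(
        a_rules=(a_igg_rule, single(a_igm, "IgM", *a_igm_band)),
        b_rules=(b_igg_rule, single(b_igm, "IgM", *b_igm_band)),
        combination="flowchart",
        stage2_a_rules=(a_igg_rule.widen(stringency),),
        stage2_b_rules=(b_igg_rule.widen(stringency),),
    )


def default_flowchart_method(
    profiles_train: Union[ProfileMatrix, pd.DataFrame],
    labels_train: Union[Mapping[str, str], pd.Series],
    stringency: float = 1.0,
    grid_step: float = 0.25,
    min_classification_rate: float = 0.80,
) -> TypingMethod:
    """Fit the canonical 10-component two-stage method on training data
    (thresholds by coordinate-ascent grid search)."""
    from .search import fit_flowchart_thresholds

    return fit_flowchart_thresholds(
        profiles_train,
        labels_train,
        stringency=stringency,
        grid_step=grid_step,
        min_classification_rate=min_classification_rate,
    )


# -- (de)serialisation -------------------------------------------------


def _rule_to_dict(rule: ThresholdRule) -> dict:
    return {
        "targets": [[c, i] for c, i in rule.targets],
        "lower": float(rule.lower),
        "upper": float(rule.upper),
    }


def _rule_from_dict(d: Mapping) -> ThresholdRule:
    return ThresholdRule(
        tuple((str(c), str(i)) for c, i in d["targets"]),
        float(d["lower"]),
        float(d["upper"]),
    )


def method_to_dict(method: TypingMethod) -> dict:
    out = {
        "combination": method.combination,
        "a_rules": [_rule_to_dict(r) for r in method.a_rules],
        "b_rules": [_rule_to_dict(r) for r in method.b_rules],
    }
    if method.stage2_a_rules:
        out["stage2"] = {
            "a_rules": [_rule_to_dict(r) for r in method.stage2_a_rules],
            "b_rules": [_rule_to_dict(r) for r in method.stage2_b_rules],
        }
    return out


def method_from_dict(d: Mapping) -> TypingMethod:
    stage2 = d.get("stage2") or {}
    return TypingMethod(
        a_rules=tuple(_rule_from_dict(r) for r in d["a_rules"]),
        b_rules=tuple(_rule_from_dict(r) for r in d["b_rules"]),
        combination=d.get("combination", "pairwise"),
        stage2_a_rules=tuple(_rule_from_dict(r) for r in stage2.get("a_rules", [])),
        stage2_b_rules=tuple(_rule_from_dict(r) for r in stage2.get("b_rules", [])),
    )


def save_method(method: TypingMethod, path: Union[str, Path]) -> None:
    Path(path).write_text(
        yaml.safe_dump(method_to_dict(method), sort_keys=True)
    )


def load_method(path: Union[str, Path]) -> TypingMethod:
    return method_from_dict(yaml.safe_load(Path(path).read_text()))


# -- sklearn-style estimators ------------------------------------------


class ThresholdTyper(ClassifierMixin, BaseEstimator):
    """Classifier wrapping a fixed :class:`TypingMethod`.

    ``fit`` only validates that every rule target resolves in the given
    profile frame; thresholds are taken as supplied.  ``predict``
    returns calls in {A, B, AB, O, unclassified}.
    """

    def __init__(self, method: Optional[TypingMethod] = None):
        self.method = method

    def fit(self, X, y=None):
        if self.method is None:
            raise ValueError("ThresholdTyper requires a method")
        frame = as_frame(X)
        for component, isotype in self.method.targets():
            if (component, isotype) not in frame.columns:
                raise KeyError(
                    f"profile matrix lacks target component={component!r} "
                    f"isotype={isotype!r}"
                )
        self.method_ = self.method
        self.classes_ = np.asarray(CALLS, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "method_"):
            raise AttributeError("estimator is not fitted; call fit first")
        return predict_types(X, self.method_)["call"].to_numpy()

    def predict_frame(self, X) -> pd.DataFrame:
        """Calls plus the stage (1, 2, or 0) that produced them."""
        if not hasattr(self, "method_"):
            raise AttributeError("estimator is not fitted; call fit first")
        return predict_types(X, self.method_)


class FlowchartTyper(ClassifierMixin, BaseEstimator):
    """The 10-component two-stage reverse-typing classifier.

    ``fit(X, y)`` learns the four stage-1 threshold bands (averaged
    anti-A IgG, anti-A IgM, averaged anti-B IgG, anti-B IgM) by
    coordinate-ascent grid search maximising accuracy-then-rate on the
    training labels; stage 2 is derived by dropping the IgM rules and
    widening the IgG bands by ``stringency`` log2 units.

    Parameters
    ----------
    stringency:
        Stage-2 band widening in log2 units (0 makes stage 2 identical
        to the stage-1 IgG rules).
    grid_step:
        Threshold grid resolution in log2 units.
    min_classification_rate:
        Training-set classification-rate constraint during threshold
        optimisation (accuracy is optimised subject to it).
    a_igg, a_igm, b_igg, b_igm:
        Target components; default to the canonical 10-component panel.
    """

    def __init__(
        self,
        stringency: float = 1.0,
        grid_step: float = 0.25,
        min_classification_rate: float = 0.80,
        a_igg: Sequence[str] = FLOWCHART_A_IGG,
        a_igm: str = FLOWCHART_A_IGM,
        b_igg: Sequence[str] = FLOWCHART_B_IGG,
        b_igm: str = FLOWCHART_B_IGM,
    ):
        self.stringency = stringency
        self.grid_step = grid_step
        self.min_classification_rate = min_classification_rate
        self.a_igg = a_igg
        self.a_igm = a_igm
        self.b_igg = b_igg
        self.b_igm = b_igm

    def fit(self, X, y):
        from .search import fit_flowchart_thresholds

        targets = canonical_flowchart_targets(
            self.a_igg, self.a_igm, self.b_igg, self.b_igm
        )
        self.method_ = fit_flowchart_thresholds(
            X,
            y,
            targets=targets,
            stringency=self.stringency,
            grid_step=self.grid_step,
            min_classification_rate=self.min_classification_rate,
        )
        self.classes_ = np.asarray(CALLS, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "method_"):
            raise AttributeError("estimator is not fitted; call fit first")
        return predict_types(X, self.method_)["call"].to_numpy()

    def predict_frame(self, X) -> pd.DataFrame:
        if not hasattr(self, "method_"):
            raise AttributeError("estimator is not fitted; call fit first")
        return predict_types(X, self.method_)
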