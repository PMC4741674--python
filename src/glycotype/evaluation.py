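"""Scoring of blood-type calls against reference labels.

The conventions follow standard reverse-typing method evaluation:
*classification rate* is the fraction of samples assigned a definite
type (anything but "unclassified"), and *accuracy* is computed among
classified samples only — an unclassified sample is a refusal, not an
error.  A total-denominator accuracy is also emitted for transparency.
An optional relabel map (sample -> corrected type) replaces reference
labels before scoring, supporting "corrected" accuracy when a subset of
reference labels is known to be wrong (e.g. vendor mislabels confirmed
by re-typing).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import pandas as pd

from .rules import UNCLASSIFIED_CALL

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Typing-method performance on one sample set."""

    n_total: int
    n_classified: int
    n_correct: int
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)
    corrected: bool = False

    @property
    def n_unclassified(self) -> int:
        return self.n_total - self.n_classified

    @property
    def classification_rate(self) -> float:
        return self.n_classified / self.n_total if self.n_total else math.nan

    @property
    def accuracy(self) -> float:
        """Accuracy among classified samples (NaN when none classified)."""
        if self.n_classified == 0:
            return math.nan
        return self.n_correct / self.n_classified

    @property
    def accuracy_total(self) -> float:
        """Accuracy over all samples (unclassified count as incorrect)."""
        return self.n_correct / self.n_total if self.n_total else math.nan

    def to_dict(self) -> dict:
        acc = self.accuracy
        return {
            "n_total": self.n_total,
            "n_classified": self.n_classified,
            "n_unclassified": self.n_unclassified,
            "classification_rate": self.classification_rate,
            "n_correct": self.n_correct,
            "accuracy": None if math.isnan(acc) else acc,
            "accuracy_total": self.accuracy_total,
            "corrected": self.corrected,
            "confusion": {f"{t}->{c}": n for (t, c), n in sorted(self.confusion.items())},
        }

    def summary(self) -> str:
        acc = self.accuracy
        acc_str = "undefined" if math.isnan(acc) else f"{100 * acc:.1f}%"
        return (
            f"classified {self.n_classified}/{self.n_total} "
            f"({100 * self.classification_rate:.1f}%), accuracy {acc_str} "
            f"({self.n_correct}/{self.n_classified})"
        )


def _as_series(values, name: str) -> pd.Series:
    if isinstance(values, pd.Series):
        return values.astype(str)
    if isinstance(values, pd.DataFrame):
        if "call" not in values.columns:
            raise ValueError(f"{name} frame needs a 'call' column")
        return values["call"].astype(str)
    return pd.Series(dict(values), dtype=object).astype(str)


def evaluate(
    calls: Union[Mapping[str, str], pd.Series, pd.DataFrame],
    labels: Union[Mapping[str, str], pd.Series],
    relabel_map: Optional[Mapping[str, str]] = None,
) -> EvaluationReport:
    """Score calls against labels.

    ``calls`` may be a mapping/Series of sample -> call or the frame
    produced by ``predict_types``.  Every call must have a label.
    """
    calls = _as_series(calls, "calls")
    labels = _as_series(labels, "labels")
    missing = calls.index.difference(labels.index)
    if len(missing):
        raise ValueError(f"call(s) without a label: {list(missing)[:5]}")
    labels = labels.reindex(calls.index)
    if relabel_map:
        labels = labels.copy()
        for sample, corrected in relabel_map.items():
            if sample in labels.index:
                labels.loc[sample] = corrected

    classified = calls != UNCLASSIFIED_CALL
    n_total = int(len(calls))
    n_classified = int(classified.sum())
    correct = classified & (calls == labels)
    confusion: dict[tuple[str, str], int] = {}
    for (t, c), n in (
        pd.crosstab(labels[classified], calls[classified]).stack().items()
        if n_classified
        else []
    ):
        if n:
            confusion[(str(t), str(c))] = int(n)
    if n_classified == 0:
        logger.warning("no samples classified; accuracy is undefined")
    return EvaluationReport(
        n_total=n_total,
        n_classified=n_classified,
        n_correct=int(correct.sum()),
        confusion=confusion,
        corrected=bool(relabel_map),
    )


def merge_reports(a: EvaluationReport, b: EvaluationReport) -> EvaluationReport:
    """Pool two disjoint evaluated sets (counts are additive)."""
    confusion = dict(a.confusion)
    for key, n in b.confusion.items():
        confusion[key] = confusion.get(key, 0) + n
    return EvaluationReport(
        n_total=a.n_total + b.n_total,
        n_classified=a.n_classified + b.n_classified,
        n_correct=a.n_correct + b.n_correct,
        confusion=confusion,
        corrected=a.corrected or b.corrected,
    )
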