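"""ANOVA ranking of array components against blood type.

Each component/isotype signal is tested with a one-way fixed-effects
ANOVA on the blood-type factor (four levels A/B/AB/O by default, or the
pooled two-level A+AB vs B+O factor).  Components are ranked by
ascending p-value; no multiple-testing correction enters the ranking
itself, but a Bonferroni-adjusted column is emitted for information.

Degenerate cases follow fixed conventions: a component whose signal is
constant within the tested samples gets F = 0, p = 1; perfect separation
(zero within-group variance with non-zero between-group variance) gets
F = +inf with the p-value floored at 1e-300; components with any group
smaller than two samples are flagged and placed last regardless of p.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import ProfileMatrix
from .rules import as_frame

P_FLOOR = 1e-300


def _coerce_labels(
    frame: pd.DataFrame, labels: Union[Mapping[str, str], pd.Series]
) -> pd.Series:
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(frame.index)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValueError(f"no blood-type label for sample(s) {missing[:5]}")
    return labels.astype(str)


def pool_labels(labels: pd.Series) -> pd.Series:
    """Collapse the four ABO levels into A/AB vs B/O."""
    mapping = {"A": "A/AB", "AB": "A/AB", "B": "B/O", "O": "B/O"}
    return labels.map(mapping).fillna(labels)


def anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int):
    """Vectorised one-way ANOVA over columns of ``values``.

    Parameters
    ----------
    values : (n_samples, n_features)
    codes : integer group code per sample, in [0, n_groups)

    Returns (F, p, dfb, dfw) with the degenerate-case conventions above.
    """
    n, m = values.shape
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    grand = values.mean(axis=0)
    group_sums = np.zeros((n_groups, m))
    np.add.at(group_sums, codes, values)
    group_means = group_sums / counts[:, None]
    ss_between = (counts[:, None] * (group_means - grand) ** 2).sum(axis=0)
    ss_total = ((values - grand) ** 2).sum(axis=0)
    ss_within = ss_total - ss_between
    dfb, dfw = n_groups - 1, n - n_groups
    if dfw <= 0:
        raise ValueError("need more samples than groups for a within-group df")

    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / dfb) / (ss_within / dfw)
    # constant signal: no between- or within-group variation
    constant = np.isclose(ss_total, 0.0)
    f = np.where(constant, 0.0, f)
    separated = np.isclose(ss_within, 0.0) & ~constant
    f = np.where(separated, np.inf, f)
    p = np.where(
        np.isinf(f), P_FLOOR, np.maximum(stats.f.sf(f, dfb, dfw), P_FLOOR)
    )
    p = np.where(constant, 1.0, p)
    return f, p, dfb, dfw


def anova_rank(
    profiles: Union[ProfileMatrix, pd.DataFrame],
    labels: Union[Mapping[str, str], pd.Series],
    isotype: str = "IgG",
    factor: str = "four_level",
) -> pd.DataFrame:
    """Rank one isotype channel's components by blood-type association.

    Returns a frame sorted ascending by p-value (flagged small-group
    components last) with columns ``component, isotype, f_statistic,
    p_value, bonferroni_p, small_group`` and one ``mean_<group>`` column
    per blood-type group.
    """
    frame = as_frame(profiles)
    cols = [c for c in frame.columns if c[1] == isotype]
    if not cols:
        raise ValueError(f"no components carry isotype {isotype!r}")
    labels = _coerce_labels(frame, labels)
    if factor == "pooled":
        labels = pool_labels(labels)
    elif factor != "four_level":
        raise ValueError("factor must be 'four_level' or 'pooled'")

    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two blood-type groups")
    counts = labels.value_counts()
    if (counts < 2).all():
        raise ValueError("every group has fewer than 2 samples")

    codes = labels.map({g: i for i, g in enumerate(groups)}).to_numpy()
    values = frame[cols].to_numpy(dtype=float)
    f, p, dfb, dfw = anova_f(values, codes, len(groups))

    out = pd.DataFrame(
        {
            "component": [c[0] for c in cols],
            "isotype": isotype,
            "f_statistic": f,
            "p_value": p,
            "bonferroni_p": np.minimum(p * len(cols), 1.0),
            "small_group": bool((counts < 2).any()),
        }
    )
    for i, g in enumerate(groups):
        out[f"mean_{g}"] = values[codes == i].mean(axis=0)
    # small-group flagging is global here (the factor is shared across
    # components); per-component NaN patterns are rejected upstream
    out = out.sort_values(
        ["small_group", "p_value", "component"], kind="mergesort"
    ).reset_index(drop=True)
    return out


class AnovaRanker(BaseEstimator):
    """Estimator wrapper: fit computes the per-component ANOVA ranking.

    Attributes (after fit): ``ranking_`` (the frame from
    :func:`anova_rank`), ``top_components_`` (names in rank order).
    """

    def __init__(self, isotype: str = "IgG", factor: str = "four_level"):
        self.isotype = isotype
        self.factor = factor

    def fit(self, X, y):
        self.ranking_ = anova_rank(X, y, isotype=self.isotype, factor=self.factor)
        self.top_components_ = list(self.ranking_["component"])
        return self

    def transform(self, X, top_k: Optional[int] = None) -> pd.DataFrame:
        """Restrict a profile frame to the top-ranked components."""
        if not hasattr(self, "ranking_"):
            raise AttributeError("estimator is not fitted; call fit first")
        keep = self.top_components_ if top_k is None else self.top_components_[:top_k]
        frame = as_frame(X)
        cols = [c for c in frame.columns if c[0] in set(keep)]
        return frame[cols]


def heatmap_export(
    profiles: Union[ProfileMatrix, pd.DataFrame],
    labels: Union[Mapping[str, str], pd.Series],
    ordering: Optional[Sequence[str]] = None,
    path: Union[str, Path] = "heatmap.png",
    isotype: str = "IgG",
) -> tuple[int, int]:
    """Export a deterministic samples x components signal heat map.

    Samples are grouped by blood-type label (then id); components follow
    ``ordering`` when given, else their column order.  Returns the
    (n_samples, n_components) shape drawn.  Uses a non-interactive
    backend so plotting failures cannot abort pipelines calling it with
    ``errors='warn'`` semantics upstream.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    frame = as_frame(profiles)
    if frame.empty:
        raise ValueError("empty profile matrix")
    labels = _coerce_labels(frame, labels)
    sample_order = sorted(frame.index, key=lambda s: (labels[s], s))
    cols = [c for c in frame.columns if c[1] == isotype]
    if ordering is not None:
        by_name = {c[0]: c for c in cols}
        cols = [by_name[n] for n in ordering if n in by_name]
    matrix = frame.loc[sample_order, cols].to_numpy(dtype=float)

    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * len(cols)), max(3, 0.12 * len(sample_order)))
    )
    im = ax.imshow(matrix, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(cols)))
    ax.set_xticklabels([c[0] for c in cols], rotation=90, fontsize=6)
    ax.set_yticks(range(len(sample_order)))
    ax.set_yticklabels(
        [f"{s} ({labels[s]})" for s in sample_order], fontsize=5
    )
    ax.set_title(f"{isotype} anti-glycan signals (log2 RFU)")
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return matrix.shape
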