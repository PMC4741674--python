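"""Synthetic serum-profile and cohort generation.

The generator emulates the statistical structure that reverse typing
relies on: by Landsteiner's rule a subject carries antibodies against
the ABO determinants absent from their own cells, so anti-A signals are
elevated in B and O sera and anti-B signals in A and O sera.  Signals
live on the log2 RFU scale: a compatible (self) determinant sits at a
baseline mean, a foreign determinant is shifted up by an incompatibility
delta scaled by isotype and glycan-density multipliers (IgG separates
better than IgM overall; IgG separation is stronger on high-density
glycans while IgM favours low-density presentations), plus Gaussian
noise.  Recorded blood types can be mislabelled at a configurable rate,
mirroring the handful of vendor mislabels real serum panels contain.

The cohort generator adds blood-type- and arm-dependent survival: only
vaccine-arm B/O patients receive a median-survival multiplier (control
arm survival is blood-type-independent by construction), with an
additional multiplier for vaccine-arm B/O patients who mount a
Forssman antibody response.  Forssman response occurrence itself is
independent of blood type.  The Halabi predicted survival (HPS) is a
noisy, blood-type-independent baseline prognosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .components import Determinant, GlycanComponent, default_components
from .io import ProfileMatrix

#: approximate U.S. population ABO distribution
US_TYPE_FREQS = {"O": 0.44, "A": 0.42, "B": 0.10, "AB": 0.04}

BLOOD_TYPES = ("A", "B", "AB", "O")

#: determinants foreign to each blood type (Landsteiner's rule)
FOREIGN = {
    "O": {Determinant.A, Determinant.B},
    "A": {Determinant.B},
    "B": {Determinant.A},
    "AB": set(),
}


@dataclass(frozen=True)
class SignalModel:
    """Generative model for one antibody signal (log2 RFU).

    mean = baseline_mu
         + incompat_delta * isotype_scale * density_effect   (foreign)
         + crossreact_epsilon                                 (self)
    plus N(0, sigma) noise.
    """

    baseline_mu: float = 8.0
    incompat_delta: float = 4.0
    sigma: float = 1.0
    isotype_scale: Mapping[str, float] = field(
        default_factory=lambda: {"IgG": 1.0, "IgM": 0.7}
    )
    density_effect: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("IgG", "high"): 1.0,
            ("IgG", "low"): 0.6,
            ("IgM", "high"): 0.8,
            ("IgM", "low"): 1.0,
        }
    )
    crossreact_epsilon: float = 0.3
    mislabel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.incompat_delta < 0:
            raise ValueError("incompat_delta must be non-negative")
        if not (0 <= self.mislabel_rate < 0.5):
            raise ValueError("mislabel_rate must be in [0, 0.5)")
        if any(v <= 0 for v in self.isotype_scale.values()) or any(
            v <= 0 for v in self.density_effect.values()
        ):
            raise ValueError("scale multipliers must be positive")

    def scaled_delta(self, component: GlycanComponent, isotype: str) -> float:
        """The mean log2 elevation a foreign determinant produces on
        this component/isotype."""
        dens = component.density_class
        dens_key = "high" if dens is None else dens.value
        return (
            self.incompat_delta
            * self.isotype_scale[isotype]
            * self.density_effect[(isotype, dens_key)]
        )


@dataclass(frozen=True)
class SurvivalModel:
    """Generative model for cohort survival and Forssman response.

    Overall survival is lognormal (or exponential) with median
    ``baseline_median`` months, multiplied by ``vaccine_bo_multiplier``
    only for vaccine-arm B/O patients and further by
    ``forssman_multiplier`` for vaccine-arm B/O Forssman responders.
    The control arm's survival law is identical across blood types, and
    Forssman response occurrence is blood-type-independent.
    """

    os_distribution: str = "lognormal"
    baseline_median: float = 16.0
    vaccine_bo_multiplier: float = 1.8
    forssman_multiplier: float = 1.6
    os_sigma: float = 0.6  # lognormal log-scale SD
    hps_noise_sd: float = 0.3  # lognormal log-scale SD of the HPS draw
    forssman_response_rate: float = 0.4
    censor_rate: float = 0.0  # administrative: P(censoring horizon applies)
    censor_horizon: Optional[float] = None  # months; None = no censoring

    def __post_init__(self) -> None:
        if self.os_distribution not in ("lognormal", "exponential"):
            raise ValueError("os_distribution must be lognormal or exponential")
        if self.baseline_median <= 0:
            raise ValueError("baseline_median must be positive")
        if not (0 <= self.forssman_response_rate <= 1):
            raise ValueError("forssman_response_rate must be a probability")

    def median_for(self, arm: str, blood_type: str, responder: bool) -> float:
        m = self.baseline_median
        if arm == "vaccine" and blood_type in ("B", "O"):
            m *= self.vaccine_bo_multiplier
            if responder:
                m *= self.forssman_multiplier
        return m


def _draw_types(
    n: int, type_freqs: Mapping[str, float], rng: np.random.Generator
) -> np.ndarray:
    freqs = np.array([type_freqs.get(t, 0.0) for t in BLOOD_TYPES], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"type frequencies must sum to 1, got {freqs.sum()!r}")
    return rng.choice(np.asarray(BLOOD_TYPES, dtype=object), size=n, p=freqs)


def _mislabel(
    truth: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    recorded = truth.copy()
    flip = rng.random(truth.shape[0]) < rate
    for i in np.flatnonzero(flip):
        others = [t for t in BLOOD_TYPES if t != truth[i]]
        recorded[i] = others[rng.integers(len(others))]
    return recorded


def inject_label_flips(
    recorded: pd.Series, n_flips: int, rng: Union[int, np.random.Generator]
) -> tuple[pd.Series, list[str]]:
    """Flip the recorded blood type of exactly ``n_flips`` samples to a
    uniformly random *other* type; returns (new labels, flipped ids)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n_flips > len(recorded):
        raise ValueError("cannot flip more labels than samples")
    flipped = pd.Series(recorded, copy=True)
    idx = rng.choice(len(recorded), size=n_flips, replace=False)
    for i in idx:
        current = flipped.iloc[i]
        others = [t for t in BLOOD_TYPES if t != current]
        flipped.iloc[i] = others[rng.integers(len(others))]
    return flipped, [str(recorded.index[i]) for i in sorted(idx)]


def simulate_profiles(
    n: int,
    components: Optional[Sequence[GlycanComponent]] = None,
    model: SignalModel = SignalModel(),
    type_freqs: Mapping[str, float] = US_TYPE_FREQS,
    seed: Union[int, np.random.Generator] = 0,
    sample_prefix: str = "S",
    true_types: Optional[Sequence[str]] = None,
) -> tuple[ProfileMatrix, pd.Series]:
    """Simulate a serum antibody profile matrix.

    Returns the (log2-scale) profile matrix, whose metadata carries the
    possibly-mislabelled ``recorded_blood_type``, together with the true
    blood types as a Series.  Identical seeds give identical output.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    components = list(components) if components is not None else default_components()
    if not components:
        raise ValueError("components list must not be empty")
    dets = {c.determinant for c in components}
    if not (Determinant.A in dets and Determinant.B in dets):
        raise ValueError("components must include at least one A and one B determinant")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    if true_types is None:
        truth = _draw_types(n, type_freqs, rng)
    else:
        truth = np.asarray(list(true_types), dtype=object)
        if truth.shape[0] != n:
            raise ValueError("true_types length must equal n")
    recorded = _mislabel(truth, model.mislabel_rate, rng)

    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n)]
    columns = pd.MultiIndex.from_tuples(
        [(c.name, iso) for c in components for iso in ("IgG", "IgM")],
        names=["component", "isotype"],
    )
    means = np.empty((n, len(columns)))
    foreign_masks = {
        t: np.array(
            [c.determinant in FOREIGN[t] for c in components for _ in ("IgG", "IgM")]
        )
        for t in BLOOD_TYPES
    }
    self_masks = {
        t: np.array(
            [
                c.determinant in (Determinant.A, Determinant.B)
                and c.determinant not in FOREIGN[t]
                for c in components
                for _ in ("IgG", "IgM")
            ]
        )
        for t in BLOOD_TYPES
    }
    deltas = np.array(
        [model.scaled_delta(c, iso) for c in components for iso in ("IgG", "IgM")]
    )
    for i, t in enumerate(truth):
        means[i] = model.baseline_mu
        means[i] += deltas * foreign_masks[t]
        means[i] += model.crossreact_epsilon * self_masks[t]
    signals = means + rng.normal(0.0, model.sigma, size=means.shape)

    data = pd.DataFrame(signals, index=sample_ids, columns=columns).sort_index(axis=1)
    metadata = pd.DataFrame(
        {"recorded_blood_type": recorded, "source": "synthetic"}, index=sample_ids
    )
    truth_series = pd.Series(truth, index=sample_ids, name="true_blood_type")
    return ProfileMatrix(data, metadata, scale="log2"), truth_series


@dataclass(frozen=True)
class CohortRecord:
    """One patient's simulated clinical record."""

    patient_id: str
    arm: str  # vaccine | control
    true_blood_type: str
    recorded_blood_type: str
    os_months: float
    event: bool
    hps_months: float
    forssman_pre: float  # log2 total Ig
    forssman_post: float  # log2 total Ig at the 2-3-month draw
    forssman_responder: bool

    def __post_init__(self) -> None:
        if self.os_months <= 0 or self.hps_months <= 0:
            raise ValueError("os_months and hps_months must be positive")


def _draw_os(
    median: np.ndarray, smodel: SurvivalModel, rng: np.random.Generator
) -> np.ndarray:
    if smodel.os_distribution == "lognormal":
        return median * np.exp(rng.normal(0.0, smodel.os_sigma, size=median.shape))
    # exponential with the requested median
    return rng.exponential(median / np.log(2.0), size=median.shape)


def simulate_cohort(
    n_vaccine: int,
    n_control: int,
    smodel: SurvivalModel = SurvivalModel(),
    sigmodel: SignalModel = SignalModel(),
    type_freqs: Mapping[str, float] = US_TYPE_FREQS,
    seed: Union[int, np.random.Generator] = 0,
    components: Optional[Sequence[GlycanComponent]] = None,
    make_profiles: bool = True,
) -> tuple[pd.DataFrame, Optional[ProfileMatrix]]:
    """Simulate a two-arm patient cohort, optionally with linked serum
    profiles for reverse typing.

    Returns a cohort table (one row per :class:`CohortRecord`) and, when
    ``make_profiles``, a ProfileMatrix whose sample ids match
    ``patient_id``.
    """
    if n_vaccine <= 0 or n_control <= 0:
        raise ValueError("cohort sizes must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = n_vaccine + n_control
    arm = np.array(["vaccine"] * n_vaccine + ["control"] * n_control, dtype=object)
    truth = _draw_types(n, type_freqs, rng)
    recorded = _mislabel(truth, sigmodel.mislabel_rate, rng)
    responder = rng.random(n) < smodel.forssman_response_rate

    medians = np.array(
        [
            smodel.median_for(a, t, r)
            for a, t, r in zip(arm, truth, responder)
        ]
    )
    os_months = _draw_os(medians, smodel, rng)
    hps = smodel.baseline_median * np.exp(
        rng.normal(0.0, smodel.hps_noise_sd, size=n)
    )
    # administrative censoring at a fixed horizon (default off), plus an
    # optional independent random-censoring fraction
    event = np.ones(n, dtype=bool)
    if smodel.censor_horizon is not None:
        over = os_months > smodel.censor_horizon
        os_months = np.where(over, smodel.censor_horizon, os_months)
        event &= ~over
    if smodel.censor_rate > 0:
        randomly_censored = rng.random(n) < smodel.censor_rate
        os_months = np.where(
            randomly_censored, os_months * rng.uniform(0.2, 1.0, size=n), os_months
        )
        event &= ~randomly_censored

    pre = rng.normal(10.0, 0.5, size=n)
    delta = np.where(
        responder,
        2.0 + rng.exponential(0.8, size=n),  # >= 4-fold rise
        rng.uniform(-0.5, 1.5, size=n),  # < 4-fold
    )
    post = pre + delta

    patient_ids = [f"P{i:04d}" for i in range(n)]
    cohort = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "arm": arm,
            "true_blood_type": truth,
            "recorded_blood_type": recorded,
            "os_months": os_months,
            "event": event,
            "hps_months": hps,
            "forssman_pre": pre,
            "forssman_post": post,
            "forssman_responder": responder,
        }
    ).set_index("patient_id", drop=False)
    cohort.index.name = None

    profiles = None
    if make_profiles:
        profiles, _ = simulate_profiles(
            n,
            components=components,
            model=sigmodel,
            type_freqs=type_freqs,
            seed=rng,
            sample_prefix="P",
            true_types=truth,
        )
        profiles.metadata["cohort_arm"] = arm
    return cohort, profiles


def cohort_records(cohort: pd.DataFrame) -> list[CohortRecord]:
    """View a cohort table as typed records (validates invariants)."""
    return [
        CohortRecord(
            patient_id=str(row.patient_id),
            arm=str(row.arm),
            true_blood_type=str(row.true_blood_type),
            recorded_blood_type=str(row.recorded_blood_type),
            os_months=float(row.os_months),
            event=bool(row.event),
            hps_months=float(row.hps_months),
            forssman_pre=float(row.forssman_pre),
            forssman_post=float(row.forssman_post),
            forssman_responder=bool(row.forssman_responder),
        )
        for row in cohort.itertuples(index=False)
    ]
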