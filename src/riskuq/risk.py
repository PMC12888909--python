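"""Multifactorial absolute-risk engine.

A log-additive relative-risk model over a calibrated age-specific baseline
hazard, with 10-year cumulative incidence accounting for competing
mortality, and classification into clinical risk categories
(near-population < 3%, moderate 3-8%, high > 8% for the 10-year risk).

This is a deliberately simple, fully transparent stand-in for a
segregation-analysis model: the uncertainty-quantification machinery built
on top of it is agnostic to the inner risk model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .population import PopulationModel
from .schema import RiskFactorSchema, VariableSpec

__all__ = [
    "MISSING",
    "IndividualProfile",
    "CategoryScheme",
    "relative_risk",
    "relative_risk_frame",
    "calibrate_baseline",
    "absolute_risk",
    "absolute_risk_from_rr",
    "classify",
    "classify_array",
]

#: Sentinel for an unmeasured covariate in a profile.
MISSING = None


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return False


@dataclass
class IndividualProfile:
    """One index person: observed covariate values, missing mask, age, horizon."""

    age: int
    values: dict
    horizon: int = 10

    def __post_init__(self):
        self.age = int(self.age)
        self.horizon = int(self.horizon)
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")

    def missing_variables(self, schema: RiskFactorSchema) -> list:
        return [v.name for v in schema if _is_missing(self.values.get(v.name))]

    def observed_variables(self, schema: RiskFactorSchema) -> list:
        return [v.name for v in schema if not _is_missing(self.values.get(v.name))]

    def is_complete(self, schema: RiskFactorSchema) -> bool:
        return not self.missing_variables(schema)

    def validate(self, schema: RiskFactorSchema, pop: PopulationModel | None = None):
        for v in schema:
            val = self.values.get(v.name)
            if not _is_missing(val):
                v.check_value(val)
        for name in self.values:
            if name not in schema:
                raise ValueError(f"profile variable {name!r} not in schema")
        if pop is not None:
            pop.age_index(self.age)
            if self.age + self.horizon > pop.age_grid[-1] + 1:
                raise ValueError("age + horizon exceeds the population age grid")

    def with_values(self, **updates) -> "IndividualProfile":
        vals = dict(self.values)
        vals.update(updates)
        return IndividualProfile(age=self.age, values=vals, horizon=self.horizon)


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered risk cut-points and category labels.

    Default: the NICE 10-year bands — near-population (<3%), moderate
    (3%-8%, both boundaries inclusive), high (>8%).
    """

    thresholds: tuple = (0.03, 0.08)
    labels: tuple = ("near-population", "moderate", "high")

    def __post_init__(self):
        th = tuple(float(t) for t in self.thresholds)
        if any(not (0.0 < t < 1.0) for t in th):
            raise ValueError("thresholds must lie in (0, 1)")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.labels) != len(th) + 1:
            raise ValueError("need one more label than thresholds")
        object.__setattr__(self, "thresholds", th)
        object.__setattr__(self, "labels", tuple(self.labels))


def classify(risk: float, scheme: CategoryScheme = CategoryScheme()) -> str:
    """Risk category of a single risk value.

    Boundary rule: a risk equal to the lowest threshold belongs to the
    category above it, a risk equal to any other threshold to the category
    below it — so with the default scheme both 3% and 8% are "moderate".
    """
    r = float(risk)
    if not (0.0 <= r <= 1.0):
        raise ValueError(f"risk must be in [0, 1], got {r}")
    return scheme.labels[_category_index(np.array([r]), scheme.thresholds)[0]]


def _category_index(risks: np.ndarray, thresholds) -> np.ndarray:
    th = np.asarray(thresholds, dtype=float)
    # strictly-greater count, then pull boundary hits (except the lowest
    # threshold) down into the band below
    idx = np.searchsorted(th, risks, side="right")
    on_lower = risks == th[0]
    for j, t in enumerate(th):
        hit = risks == t
        idx[hit] = j  # equal to threshold j -> band below it ...
    idx[on_lower] = 1  # ... except the lowest threshold -> band above
    return idx


def classify_array(risks: np.ndarray, scheme: CategoryScheme = CategoryScheme()) -> np.ndarray:
    """Vectorized :func:`classify`; returns integer category indices."""
    risks = np.asarray(risks, dtype=float)
    if np.any((risks < 0) | (risks > 1)):
        raise ValueError("risks must be in [0, 1]")
    return _category_index(risks, scheme.thresholds)


def relative_risk(profile: IndividualProfile, schema: RiskFactorSchema) -> float:
    """Multiplicative relative risk of a complete profile.

    exp of the sum of per-variable log-RR contributions; equals 1.0 when
    every variable sits at its reference value.
    """
    missing = profile.missing_variables(schema)
    if missing:
        raise ValueError(
            f"profile has missing variables {missing}; use the uncertainty "
            "module (risk_distribution) for profiles with missing data"
        )
    log_rr = 0.0
    for v in schema:
        log_rr += v.log_rr(profile.values[v.name])
    return math.exp(log_rr)


def _log_rr_column(spec: VariableSpec, col: pd.Series) -> np.ndarray:
    """Vectorized per-variable log-RR over a column of values."""
    if spec.is_categorical:
        return col.map(spec.risk_effect).to_numpy(dtype=float)
    if spec.kind == "binary":
        x = col.to_numpy(dtype=float)
        return float(spec.risk_effect) * x
    x = col.to_numpy(dtype=float)
    if spec.kind == "semicontinuous-zero-inflated":
        out = np.zeros_like(x)
        pos = x > 0
        t = np.log(x[pos]) if spec.transform == "log" else x[pos]
        out[pos] = float(spec.risk_effect) * (t - spec.center) / spec.scale
        return out
    t = np.log(x) if spec.transform == "log" else x
    return float(spec.risk_effect) * (t - spec.center) / spec.scale


def relative_risk_frame(frame: pd.DataFrame, schema: RiskFactorSchema) -> np.ndarray:
    """Relative risks for every (complete) row of a covariate table."""
    log_rr = np.zeros(len(frame))
    for v in schema:
        col = frame[v.name]
        if col.isna().any():
            raise ValueError(f"column {v.name} contains missing entries")
        log_rr += _log_rr_column(v, col)
    return np.exp(log_rr)


def calibrate_baseline(
    pop: PopulationModel, schema: RiskFactorSchema, cohort
) -> PopulationModel:
    """Constrain the baseline so the cohort-average hazard equals incidence.

    With age-independent relative risks the constraint reduces to dividing
    the baseline hazard by the cohort mean relative risk at every age.
    Returns a new, calibrated :class:`PopulationModel`.
    """
    frame = cohort.records if hasattr(cohort, "records") else cohort
    if len(frame) == 0:
        raise ValueError("cannot calibrate on an empty cohort")
    rr = relative_risk_frame(frame, schema)
    mean_rr = float(np.mean(rr))
    out = PopulationModel(
        age_grid=pop.age_grid.copy(),
        incidence=pop.incidence.copy(),
        mortality=pop.mortality.copy(),
        pv_frequencies=dict(pop.pv_frequencies),
        calibration=np.full_like(pop.incidence, mean_rr),
    )
    out.calibrated = True
    return out


def absolute_risk_from_rr(
    rr, pop: PopulationModel, age: int, horizon: int
) -> np.ndarray:
    """Cumulative disease incidence over [age, age+horizon) for given RRs.

    Hazards are piecewise constant over each one-year interval; within each
    year the cause-specific cumulative incidence is integrated exactly:
    P(event in year t) = S(t) * lam/(lam+mu) * (1 - exp(-(lam+mu))), where
    S(t) is survival (event-free and alive) to the start of year t. This is
    exact for constant hazards and converges to the continuous-time answer
    for age-varying annual rates.
    """
    rr_arr = np.atleast_1d(np.asarray(rr, dtype=float))
    if horizon == 0:
        out = np.zeros_like(rr_arr)
        return out if np.ndim(rr) else float(out[0])
    base = pop.baseline_hazard(age, horizon)  # (T,)
    mu = pop.mortality_hazard(age, horizon)  # (T,)
    lam = rr_arr[:, None] * base[None, :]  # (M, T)
    tot = lam + mu[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, lam / np.where(tot > 0, tot, 1.0), 0.0)
    year_prob = frac * (1.0 - np.exp(-tot))
    surv = np.exp(-np.cumsum(tot, axis=1))
    surv = np.concatenate([np.ones((len(rr_arr), 1)), surv[:, :-1]], axis=1)
    risks = np.sum(surv * year_prob, axis=1)
    return risks if np.ndim(rr) else float(risks[0])


def absolute_risk(
    profile: IndividualProfile, pop: PopulationModel, schema: RiskFactorSchema
) -> float:
    """Absolute (cumulative) disease risk over the profile's horizon.

    Requires a complete profile and a calibrated population model; always in
    [0, 1) and non-decreasing in the horizon.
    """
    profile.validate(schema, pop)
    rr = relative_risk(profile, schema)
    return float(absolute_risk_from_rr(rr, pop, profile.age, profile.horizon))
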