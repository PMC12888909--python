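"""Monte Carlo risk distributions under missing data.

For an individual with an arbitrary pattern of missing risk factors, the
missing covariates are drawn repeatedly from their joint conditional
distribution given the observed data (chained-equations imputation), each
completed covariate vector is mapped through the absolute-risk engine, and
the resulting set of risks forms the individual's uncertainty distribution:
its mean is the risk point estimate, its empirical quantiles give the
uncertainty interval (UI), and the empirical category frequencies give the
probability that the risk would fall in each clinical band once the
missing data were measured.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .mice import CompletedProfileSet, ConvergenceReport, ImputationModelSet, chained_impute
from .population import PopulationModel
from .risk import (
    CategoryScheme,
    IndividualProfile,
    absolute_risk_from_rr,
    classify_array,
    relative_risk_frame,
)
from .schema import RiskFactorSchema

__all__ = [
    "RiskDistribution",
    "risk_distribution",
    "uncertainty_interval",
    "category_probabilities",
    "pgs_sweep",
]


@dataclass
class RiskDistribution:
    """M Monte Carlo risks for one person plus derived summaries.

    ``point_estimate`` is exactly the arithmetic mean of the samples (the
    mean risk over unmeasured covariates); ``ui`` is the equal-tailed
    empirical quantile interval at ``level``; ``category_probs`` are exact
    empirical frequencies and sum to 1.
    """

    samples: np.ndarray
    horizon: int
    scheme: CategoryScheme
    level: float = 0.95
    seed: int | None = None
    provenance: dict = field(default_factory=dict)
    convergence: ConvergenceReport | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any((self.samples < 0) | (self.samples > 1)):
            raise ValueError("risk samples must lie in [0, 1]")

    @property
    def M(self) -> int:
        return len(self.samples)

    @property
    def point_estimate(self) -> float:
        return float(np.mean(self.samples))

    @property
    def ui(self) -> tuple:
        return uncertainty_interval(self, self.level)

    @property
    def category_probs(self) -> dict:
        return category_probabilities(self, self.scheme)

    def summary(self) -> dict:
        lo, hi = self.ui
        return {
            "M": self.M,
            "horizon": self.horizon,
            "point_estimate": self.point_estimate,
            "ui_level": self.level,
            "ui_lower": lo,
            "ui_upper": hi,
            "category_probs": self.category_probs,
            "seed": self.seed,
            **self.provenance,
        }


def risk_distribution(
    profile: IndividualProfile,
    models: ImputationModelSet,
    pop: PopulationModel,
    schema: RiskFactorSchema | None = None,
    M: int = 1000,
    n_iter: int = 10,
    n_chains: int = 4,
    seed: int = 0,
    scheme: CategoryScheme = CategoryScheme(),
    level: float = 0.95,
    proper: bool = True,
) -> RiskDistribution:
    """Monte Carlo risk distribution of one profile under missing data.

    Runs ``M`` chained imputations of the missing covariates and maps each
    completed vector through the absolute-risk engine. With a fully
    observed profile all samples coincide (zero-width UI, one category with
    probability 1).
    """
    schema = schema or models.schema
    if not pop.calibrated:
        raise ValueError("population model must be calibrated (calibrate_baseline)")
    profile.validate(schema, pop)
    completed = chained_impute(
        profile, models, M=M, n_iter=n_iter, n_chains=n_chains, seed=seed, proper=proper
    )
    rr = relative_risk_frame(completed.data, schema)
    risks = absolute_risk_from_rr(rr, pop, profile.age, profile.horizon)
    conv = ConvergenceReport.from_completed(completed) if completed.traces else None
    return RiskDistribution(
        samples=risks,
        horizon=profile.horizon,
        scheme=scheme,
        level=level,
        seed=seed,
        provenance={
            "n_iter": n_iter,
            "n_chains": n_chains,
            "missing_variables": profile.missing_variables(schema),
        },
        convergence=conv,
    )


def uncertainty_interval(dist, level: float = 0.95) -> tuple:
    """Equal-tailed empirical quantile interval of a risk distribution.

    Quantiles use the inclusive linear-interpolation convention between
    closest order statistics (numpy's default), so results are
    bit-reproducible. ``level=0`` degenerates to (median, median).
    """
    samples = dist.samples if isinstance(dist, RiskDistribution) else np.asarray(dist, float)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for an uncertainty interval")
    if not (0.0 <= level < 1.0):
        raise ValueError("level must lie in [0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def category_probabilities(dist, scheme: CategoryScheme | None = None) -> dict:
    """Empirical probability of each risk category; sums to 1 exactly."""
    if isinstance(dist, RiskDistribution):
        samples = dist.samples
        scheme = scheme or dist.scheme
    else:
        samples = np.asarray(dist, dtype=float)
        scheme = scheme or CategoryScheme()
    idx = classify_array(samples, scheme)
    counts = np.bincount(idx, minlength=len(scheme.labels))
    # empirical frequencies: the counts sum to M exactly, and the correctly
    # rounded float sum (math.fsum) of counts/M is exactly 1.0
    return {lab: int(c) / len(samples) for lab, c in zip(scheme.labels, counts)}


def pgs_sweep(
    profile: IndividualProfile,
    models: ImputationModelSet,
    pop: PopulationModel,
    schema: RiskFactorSchema | None = None,
    percentiles=(10, 20, 30, 40, 50, 60, 70, 80, 90),
    M: int = 1000,
    n_iter: int = 10,
    seed: int = 0,
    scheme: CategoryScheme = CategoryScheme(),
    level: float = 0.95,
) -> dict:
    """Risk distributions with the polygenic score fixed at given percentiles.

    For each percentile p the PGS is set to the standard-normal quantile
    Phi^-1(p/100) and the distribution over the remaining missing
    covariates is computed. The same seed drives every percentile (common
    random numbers), so sweep curves are directly comparable. Returns an
    ordered dict {percentile: RiskDistribution}.
    """
    schema = schema or models.schema
    if schema.pgs_variable is None:
        raise ValueError("schema declares no polygenic-score variable")
    if schema.pgs_variable not in profile.missing_variables(schema):
        raise ValueError("the polygenic score must be missing in the input profile")
    for p in percentiles:
        if not (0 < p < 100):
            raise ValueError(f"percentile {p} outside (0, 100)")
    out = {}
    for p in sorted(percentiles):
        q = float(ndtri(p / 100.0))
        prof_p = profile.with_values(**{schema.pgs_variable: q})
        out[p] = risk_distribution(
            prof_p, models, pop, schema, M=M, n_iter=n_iter, seed=seed,
            scheme=scheme, level=level,
        )
    return out
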