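"""Stepwise measurement of risk-factor groups and reclassification flows.

Simulates successively measuring groups of missing risk factors
(questionnaire factors, mammographic density, genetic factors) in a chosen
order. Each of M Monte Carlo trajectories draws the newly "measured" group
from its conditional distribution given everything known so far and holds
it fixed; at every stage the trajectory's risk point estimate is computed
with the still-unmeasured groups left missing (marginalized by an inner
Monte Carlo mean over M_inner imputations) and classified. The per-stage
category memberships and stage-to-stage transition matrices are the
Sankey-flow summary; the probability of leaving a category after further
measurement is the reclassification probability.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import models as _m
from .mice import ImputationModelSet, _encode_value
from .population import PopulationModel
from .risk import (
    CategoryScheme,
    IndividualProfile,
    absolute_risk_from_rr,
    classify_array,
    relative_risk_frame,
)
from .schema import GROUPS, RiskFactorSchema

__all__ = ["ReclassificationFlow", "stepwise_measurement", "reclassification_probability"]


@dataclass
class ReclassificationFlow:
    """Per-stage category memberships and transition matrices.

    ``membership[k]`` sums to 1; ``transitions[k]`` holds joint trajectory
    proportions (row = category at stage k, column = category at stage
    k+1), so each row sums to that category's stage-k membership and each
    column sum equals the stage-(k+1) membership — mass is conserved
    exactly.
    """

    stage_labels: list
    categories: tuple
    membership_counts: np.ndarray  # (n_stages, n_categories), integer trajectories
    transition_counts: list  # per consecutive pair: integer (n_cat, n_cat) arrays
    stage_risks: np.ndarray  # (n_stages, M) per-trajectory point estimates
    group_order: list
    M: int
    seed: int
    skipped_groups: list = field(default_factory=list)

    @property
    def membership(self) -> np.ndarray:
        """Per-stage category proportions (rows sum to 1)."""
        return self.membership_counts / self.M

    @property
    def transitions(self) -> list:
        """Joint stage-to-stage proportions; row sums equal the previous
        stage's membership and column sums the next stage's (exact in the
        underlying trajectory counts)."""
        return [T / self.M for T in self.transition_counts]

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    def modal_category(self, stage: int) -> int:
        return int(np.argmax(self.membership[stage]))

    def to_tidy_rows(self) -> list:
        """Tidy (stage_from, stage_to, category_from, category_to, proportion)."""
        rows = []
        for k, T in enumerate(self.transitions):
            for i, ci in enumerate(self.categories):
                for j, cj in enumerate(self.categories):
                    rows.append(
                        {
                            "stage_from": self.stage_labels[k],
                            "stage_to": self.stage_labels[k + 1],
                            "category_from": ci,
                            "category_to": cj,
                            "proportion": float(T[i, j]),
                        }
                    )
        return rows


def _impute_rows(codes, missing_names, models, n_iter, rng, proper=True):
    """In-place chained imputation of the named variables over all rows.

    Initializes from the marginal pools, then sweeps the visit order
    ``n_iter`` times with per-row parameter draws.
    """
    schema = models.schema
    n = len(next(iter(codes.values())))
    order = [v for v in models.visit_order if v in missing_names]
    for name in order:
        codes[name] = rng.choice(models.marginal_pools[name], size=n, replace=True)
    for _ in range(n_iter):
        for name in order:
            X = _m.predictor_matrix(codes, schema, name)
            codes[name] = models.models[name].draw(X, rng, proper=proper)
    return codes


def _risks_from_codes(codes, schema, pop, age, horizon):
    frame = _m.decode_codes(codes, schema)
    rr = relative_risk_frame(frame, schema)
    return absolute_risk_from_rr(rr, pop, age, horizon)


def stepwise_measurement(
    profile: IndividualProfile,
    group_order: list,
    models: ImputationModelSet,
    pop: PopulationModel,
    schema: RiskFactorSchema | None = None,
    M: int = 1000,
    M_inner: int = 100,
    n_iter: int = 10,
    seed: int = 0,
    scheme: CategoryScheme = CategoryScheme(),
    proper: bool = True,
) -> ReclassificationFlow:
    """Simulate measuring groups of missing risk factors in order.

    Stage 0 is the baseline (only the profile's observed data); stage k
    additionally "measures" the k-th group in ``group_order`` by drawing
    its missing variables from their conditional distribution given all
    information accumulated along the trajectory. Stage risks are point
    estimates with the remaining unmeasured covariates still missing
    (inner Monte Carlo mean over ``M_inner`` imputations); the final stage,
    once every group is measured, needs no inner marginalization.

    Groups without missing variables are skipped with a warning.
    """
    schema = schema or models.schema
    if not pop.calibrated:
        raise ValueError("population model must be calibrated (calibrate_baseline)")
    profile.validate(schema, pop)
    for g in group_order:
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")

    missing = set(profile.missing_variables(schema))
    stages, skipped = [], []
    for g in group_order:
        vars_g = [v for v in schema.group_members(g) if v in missing]
        if not vars_g:
            warnings.warn(f"group {g} has no missing variables in the profile; skipped")
            skipped.append(g)
        else:
            stages.append((g, vars_g))

    rng = np.random.default_rng(seed)
    n_cat = len(scheme.labels)

    # trajectory state: encoded values fixed so far (observed + measured)
    codes = {}
    for spec in schema:
        if spec.name in missing:
            codes[spec.name] = np.full(M, np.nan)
        else:
            codes[spec.name] = np.full(M, _encode_value(spec, profile.values[spec.name]))

    def point_estimates(still_missing):
        """Per-trajectory risk point estimate marginalizing *still_missing*."""
        if not still_missing:
            return _risks_from_codes(codes, schema, pop, profile.age, profile.horizon)
        inner = {k: np.repeat(v, M_inner) for k, v in codes.items()}
        _impute_rows(inner, still_missing, models, n_iter, rng, proper)
        risks = _risks_from_codes(inner, schema, pop, profile.age, profile.horizon)
        return risks.reshape(M, M_inner).mean(axis=1)

    unmeasured = [v for v in models.visit_order if v in missing]
    stage_labels = ["baseline"]
    # Baseline: every trajectory shares the same information, hence the same
    # point estimate — one inner Monte Carlo run of size M, broadcast.
    if unmeasured:
        base = {k: v[:1].repeat(M) for k, v in codes.items()}
        _impute_rows(base, unmeasured, models, n_iter, rng, proper)
        r0 = float(_risks_from_codes(base, schema, pop, profile.age, profile.horizon).mean())
    else:
        r0 = float(_risks_from_codes(codes, schema, pop, profile.age, profile.horizon)[0])
    stage_risks = [np.full(M, r0)]
    for g, vars_g in stages:
        # draw this group's variables jointly with the rest, keep the group
        work = {k: v.copy() for k, v in codes.items()}
        _impute_rows(work, unmeasured, models, n_iter, rng, proper)
        for v in vars_g:
            codes[v] = work[v]
        unmeasured = [v for v in unmeasured if v not in vars_g]
        stage_labels.append(f"+{g}")
        stage_risks.append(point_estimates(unmeasured))

    stage_risks = np.vstack(stage_risks)
    cats = classify_array(stage_risks.reshape(-1), scheme).reshape(stage_risks.shape)
    membership_counts = np.stack(
        [np.bincount(cats[k], minlength=n_cat) for k in range(len(stage_labels))]
    )
    transition_counts = []
    for k in range(len(stage_labels) - 1):
        T = np.zeros((n_cat, n_cat), dtype=np.int64)
        np.add.at(T, (cats[k], cats[k + 1]), 1)
        transition_counts.append(T)

    return ReclassificationFlow(
        stage_labels=stage_labels,
        categories=scheme.labels,
        membership_counts=membership_counts,
        transition_counts=transition_counts,
        stage_risks=stage_risks,
        group_order=list(group_order),
        M=M,
        seed=seed,
        skipped_groups=skipped,
    )


def reclassification_probability(
    flow: ReclassificationFlow, from_stage=0, to_stage=-1
) -> float:
    """Probability of ending outside the from-stage modal category.

    The modal category at ``from_stage`` (for the baseline stage: the
    category of the baseline point estimate, shared by every trajectory) is
    taken as the current classification; returns 1 minus its membership at
    ``to_stage``. Stages may be given by index or by label.
    """
    def _idx(s):
        if isinstance(s, str):
            return flow.stage_labels.index(s)
        return range(flow.n_stages)[s]

    i, j = _idx(from_stage), _idx(to_stage)
    c0 = flow.modal_category(i)
    return float(1.0 - flow.membership[j][c0])
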