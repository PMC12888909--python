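"""Risk-factor schema: declarative description of every covariate.

Each covariate carries its statistical type (which decides the conditional
imputation model family), the transform used inside imputation models, the
measurement group it belongs to (questionnaire, mammographic density,
genetic factors, family history), and its effect on disease risk.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "VariableSpec",
    "RiskFactorSchema",
    "default_schema",
    "KINDS",
    "GROUPS",
]

KINDS = (
    "continuous",
    "continuous-positive",
    "semicontinuous-zero-inflated",
    "binary",
    "categorical",
    "ordinal-count",
)

#: Measurement groups: questionnaire risk factors, mammographic density,
#: genetic factors (polygenic score + pathogenic variants), family history.
GROUPS = ("QRF", "MD", "GF", "FH")


@dataclass(frozen=True)
class VariableSpec:
    """One covariate in the risk model.

    Parameters
    ----------
    name:
        Unique identifier, used as the column name in cohorts/profiles.
    kind:
        One of :data:`KINDS`; decides the conditional model family used in
        imputation and the domain checks applied to values.
    transform:
        ``"identity"`` or ``"log"``; the scale on which linear imputation
        models operate. ``"log"`` is only valid for positive-valued kinds.
    group:
        Measurement group, one of :data:`GROUPS`.
    levels:
        Level labels for categorical/ordinal/binary variables (binary may
        omit them, in which case 0/1 is assumed).
    risk_effect:
        Log relative risk. For continuous variables this is per unit of the
        transformed, standardized value ``(transform(x) - center) / scale``;
        for categorical/ordinal variables a dict mapping every level to its
        log-RR, with the reference level at 0; for binary a single log-RR for
        the "1"/exposed state.
    center, scale:
        Standardization constants applied after the transform when computing
        the risk contribution of a continuous variable. For a polygenic
        score standardized in the population these are 0 and 1.
    reference:
        Reference level (categorical/ordinal); defaults to the first level.
    zero_is_reference:
        Semicontinuous variables only: the structural zero contributes log-RR
        0 (it is the reference state); positive values contribute on the
        standardized log scale.
    """

    name: str
    kind: str
    group: str
    transform: str = "identity"
    levels: tuple = ()
    risk_effect: object = 0.0
    center: float = 0.0
    scale: float = 1.0
    reference: object = None
    description: str = ""

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.name}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.name}")
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "log" and self.kind not in (
            "continuous-positive",
            "semicontinuous-zero-inflated",
        ):
            raise ValueError(
                f"{self.name}: log transform only valid for positive-valued kinds"
            )
        if self.kind in ("categorical", "ordinal-count"):
            if not self.levels:
                raise ValueError(f"{self.name}: {self.kind} requires levels")
            if not isinstance(self.risk_effect, dict):
                raise ValueError(f"{self.name}: categorical risk_effect must be a dict")
            if set(self.risk_effect) != set(self.levels):
                raise ValueError(
                    f"{self.name}: risk_effect must have one entry per level"
                )
            ref = self.reference if self.reference is not None else self.levels[0]
            if self.risk_effect[ref] != 0.0:
                raise ValueError(
                    f"{self.name}: reference level {ref!r} must have risk_effect 0"
                )
            object.__setattr__(self, "reference", ref)
        if self.scale <= 0:
            raise ValueError(f"{self.name}: scale must be positive")

    @property
    def is_continuous(self) -> bool:
        return self.kind in (
            "continuous",
            "continuous-positive",
            "semicontinuous-zero-inflated",
        )

    @property
    def is_categorical(self) -> bool:
        return self.kind in ("categorical", "ordinal-count")

    def check_value(self, value) -> None:
        """Raise ValueError if *value* is outside the variable's domain."""
        if self.is_categorical:
            if value not in self.levels:
                raise ValueError(
                    f"{self.name}: level {value!r} not in declared levels {self.levels}"
                )
        elif self.kind == "binary":
            if self.levels:
                if value not in self.levels:
                    raise ValueError(f"{self.name}: {value!r} not a declared level")
            elif value not in (0, 1, 0.0, 1.0, False, True):
                raise ValueError(f"{self.name}: binary value must be 0/1, got {value!r}")
        else:
            v = float(value)
            if not math.isfinite(v):
                raise ValueError(f"{self.name}: non-finite value")
            if self.kind == "continuous-positive" and v <= 0:
                raise ValueError(f"{self.name}: must be > 0, got {v}")
            if self.kind == "semicontinuous-zero-inflated" and v < 0:
                raise ValueError(f"{self.name}: must be >= 0, got {v}")

    def log_rr(self, value) -> float:
        """Log relative-risk contribution of this variable at *value*."""
        if self.is_categorical:
            return float(self.risk_effect[value])
        if self.kind == "binary":
            if self.levels:
                value = self.levels.index(value)
            return float(self.risk_effect) * float(value)
        v = float(value)
        if self.kind == "semicontinuous-zero-inflated":
            if v == 0.0:
                return 0.0  # structural zero is the reference state
            t = math.log(v) if self.transform == "log" else v
        elif self.transform == "log":
            t = math.log(v)
        else:
            t = v
        return float(self.risk_effect) * (t - self.center) / self.scale


@dataclass(frozen=True)
class RiskFactorSchema:
    """Ordered collection of :class:`VariableSpec` plus special-role markers.

    ``pv_variable`` names the single 9-category pathogenic-variant covariate
    (one "no PV" reference level plus eight susceptibility genes; at most one
    PV per person by construction). ``pgs_variable`` names the polygenic
    score, standardized to N(0, 1) marginally in the population. Reduced
    schemas (e.g. validation toy models) may omit either marker.
    """

    variables: tuple
    pv_variable: str | None = None
    pgs_variable: str | None = None

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if self.pv_variable is not None:
            pv = self[self.pv_variable]
            if pv.kind != "categorical" or len(pv.levels) != 9:
                raise ValueError(
                    "pathogenic-variant variable must be categorical with 9 levels"
                )
        if self.pgs_variable is not None:
            pgs = self[self.pgs_variable]
            if pgs.kind != "continuous":
                raise ValueError("polygenic-score variable must be continuous")

    def __iter__(self):
        return iter(self.variables)

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    @property
    def names(self) -> list:
        return [v.name for v in self.variables]

    def group_members(self, group: str) -> list:
        """Names of all variables in a measurement group."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return [v.name for v in self.variables if v.group == group]


#: The eight susceptibility genes carried as a single 9-level covariate.
PV_LEVELS = (
    "none",
    "BRCA1",
    "BRCA2",
    "PALB2",
    "CHEK2",
    "ATM",
    "BARD1",
    "RAD51C",
    "RAD51D",
)

# Illustrative per-gene relative risks (log scale). These stand in for the
# age-dependent gene effects of a full segregation-analysis model and are
# deliberately round numbers of the right order: high-risk genes ~5-10x,
# moderate-risk genes ~2x.
_PV_LOG_RR = {
    "none": 0.0,
    "BRCA1": math.log(10.0),
    "BRCA2": math.log(8.0),
    "PALB2": math.log(5.0),
    "CHEK2": math.log(2.5),
    "ATM": math.log(2.1),
    "BARD1": math.log(2.0),
    "RAD51C": math.log(2.0),
    "RAD51D": math.log(2.0),
}


def default_schema() -> RiskFactorSchema:
    """Default breast-cancer risk-factor schema.

    Six questionnaire risk factors (BMI, alcohol, age at menarche, parity,
    HRT use, oral-contraceptive use), mammographic density, a standardized
    polygenic score, the 9-level pathogenic-variant covariate and a
    first-degree-relative family-history count (0 / 1 / 2+ affected).

    Effect sizes are illustrative defaults of realistic magnitude; they are
    not calibrated to any proprietary risk model.
    """
    variables = (
        VariableSpec(
            name="bmi",
            kind="continuous-positive",
            transform="log",
            group="QRF",
            risk_effect=math.log(1.10),
            center=math.log(26.0),
            scale=0.18,
            description="body mass index, kg/m^2 (log-normal)",
        ),
        VariableSpec(
            name="alcohol",
            kind="semicontinuous-zero-inflated",
            transform="log",
            group="QRF",
            risk_effect=math.log(1.08),
            center=math.log(6.0),
            scale=0.9,
            description="alcohol intake, g/day; structural zero for non-drinkers",
        ),
        VariableSpec(
            name="menarche_age",
            kind="continuous",
            transform="identity",
            group="QRF",
            risk_effect=math.log(0.95),
            center=13.0,
            scale=1.6,
            description="age at menarche, years",
        ),
        VariableSpec(
            name="parity",
            kind="ordinal-count",
            group="QRF",
            levels=("0", "1", "2", "3+"),
            risk_effect={
                "0": 0.0,
                "1": math.log(0.95),
                "2": math.log(0.90),
                "3+": math.log(0.85),
            },
            description="number of full-term pregnancies",
        ),
        VariableSpec(
            name="hrt_use",
            kind="binary",
            group="QRF",
            risk_effect=math.log(1.25),
            description="current/recent hormone-replacement therapy use",
        ),
        VariableSpec(
            name="oc_use",
            kind="binary",
            group="QRF",
            risk_effect=math.log(1.08),
            description="ever use of oral contraceptives",
        ),
        VariableSpec(
            name="mammographic_density",
            kind="continuous-positive",
            transform="log",
            group="MD",
            risk_effect=math.log(1.35),
            center=math.log(20.0),
            scale=0.55,
            description="percent mammographic density (log-normal)",
        ),
        VariableSpec(
            name="pgs",
            kind="continuous",
            transform="identity",
            group="GF",
            risk_effect=math.log(1.6),
            center=0.0,
            scale=1.0,
            description="breast-cancer polygenic score, population SD units",
        ),
        VariableSpec(
            name="pv",
            kind="categorical",
            group="GF",
            levels=PV_LEVELS,
            risk_effect=dict(_PV_LOG_RR),
            reference="none",
            description="rare pathogenic variant status (at most one PV)",
        ),
        VariableSpec(
            name="family_history",
            kind="ordinal-count",
            group="FH",
            levels=("0", "1", "2+"),
            risk_effect={"0": 0.0, "1": math.log(1.9), "2+": math.log(3.3)},
            description="affected first-degree relatives",
        ),
    )
    return RiskFactorSchema(variables=variables, pv_variable="pv", pgs_variable="pgs")
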