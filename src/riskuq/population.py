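"""Population disease model: baseline incidence, competing mortality, PV frequencies.

Hazards are annual rates on an integer age grid. The calibration vector is
set by :func:`riskuq.risk.calibrate_baseline` so that the cohort-averaged
individual hazard reproduces the population incidence at every age.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import PV_LEVELS

__all__ = ["PopulationModel", "default_population", "read_population", "write_population"]


@dataclass
class PopulationModel:
    """Age-specific baseline hazards plus pathogenic-variant carrier frequencies.

    Attributes
    ----------
    age_grid:
        Strictly increasing integer ages (years).
    incidence:
        Baseline breast-cancer hazard per year at each age.
    mortality:
        Competing (non-breast-cancer) all-cause hazard per year at each age.
    pv_frequencies:
        Carrier probability per PV category; the reference ("none") category
        is the remainder. Each non-reference frequency must be <= 0.01
        (rare-disease assumption).
    calibration:
        Per-age constant dividing the baseline hazard; 1.0 until
        :func:`~riskuq.risk.calibrate_baseline` is applied.
    """

    age_grid: np.ndarray
    incidence: np.ndarray
    mortality: np.ndarray
    pv_frequencies: dict
    calibration: np.ndarray = None
    calibrated: bool = False

    def __post_init__(self):
        self.age_grid = np.asarray(self.age_grid, dtype=int)
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.mortality = np.asarray(self.mortality, dtype=float)
        if self.calibration is None:
            self.calibration = np.ones_like(self.incidence)
        else:
            self.calibration = np.asarray(self.calibration, dtype=float)
        if not (np.all(np.diff(self.age_grid) > 0)):
            raise ValueError("age_grid must be strictly increasing")
        for name, arr in (("incidence", self.incidence), ("mortality", self.mortality)):
            if arr.shape != self.age_grid.shape:
                raise ValueError(f"{name} must match age_grid shape")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} hazards must be finite and >= 0")
        freqs = dict(self.pv_frequencies or {})
        if freqs:  # empty = pathogenic variants not modelled (reduced schemas)
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("pv_frequencies must sum to 1")
            ref = PV_LEVELS[0]
            for level, f in freqs.items():
                if level != ref and f > 0.01 + 1e-12:
                    raise ValueError(
                        f"PV frequency for {level} exceeds 0.01 (rare-disease assumption)"
                    )
        self.pv_frequencies = freqs

    def age_index(self, age: int) -> int:
        idx = np.searchsorted(self.age_grid, age)
        if idx >= len(self.age_grid) or self.age_grid[idx] != age:
            raise ValueError(f"age {age} not on the population age grid")
        return int(idx)

    def baseline_hazard(self, age: int, horizon: int) -> np.ndarray:
        """Calibrated baseline hazards for the years [age, age+horizon)."""
        i = self.age_index(age)
        if age + horizon > self.age_grid[-1] + 1:
            raise ValueError("age + horizon exceeds the population age grid")
        return self.incidence[i : i + horizon] / self.calibration[i : i + horizon]

    def mortality_hazard(self, age: int, horizon: int) -> np.ndarray:
        i = self.age_index(age)
        return self.mortality[i : i + horizon]


#: Default PV carrier frequencies (per-gene, order of magnitude of published
#: population frequencies; illustrative).
DEFAULT_PV_FREQUENCIES = {
    "BRCA1": 0.0006,
    "BRCA2": 0.0010,
    "PALB2": 0.0006,
    "CHEK2": 0.0050,
    "ATM": 0.0040,
    "BARD1": 0.0010,
    "RAD51C": 0.0004,
    "RAD51D": 0.0004,
}


def default_population(age_min: int = 20, age_max: int = 80) -> PopulationModel:
    """Smooth synthetic population model on an integer age grid.

    Incidence follows the familiar shape of female breast-cancer registry
    rates (steep rise through the 40s, plateau ~3/1,000 per year after 60);
    competing mortality is Gompertz-like. Values are illustrative, not a
    specific national registry.
    """
    ages = np.arange(age_min, age_max + 1)
    a = ages.astype(float)
    # logistic ramp: ~1e-4 at 30, ~1.2e-3 at 40, ~2.9e-3 at 65+
    incidence = 3.0e-3 / (1.0 + np.exp(-(a - 47.0) / 6.5))
    mortality = 4.0e-4 * np.exp(0.085 * (a - 40.0))
    freqs = dict(DEFAULT_PV_FREQUENCIES)
    freqs["none"] = 1.0 - sum(freqs.values())
    return PopulationModel(
        age_grid=ages, incidence=incidence, mortality=mortality, pv_frequencies=freqs
    )


def write_population(pop: PopulationModel, path) -> None:
    """Write the model as CSV (age, incidence, mortality, calibration)."""
    df = pd.DataFrame(
        {
            "age": pop.age_grid,
            "incidence": pop.incidence,
            "mortality": pop.mortality,
            "calibration": pop.calibration,
        }
    )
    # PV frequencies ride along as comment-style header lines
    with open(path, "w") as fh:
        for level, f in pop.pv_frequencies.items():
            fh.write(f"# pv_frequency {level} {f!r}\n")
        df.to_csv(fh, index=False)


def read_population(path) -> PopulationModel:
    freqs = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("# pv_frequency"):
            _, _, level, f = line.split()
            freqs[level] = float(f)
        else:
            data_lines.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(data_lines)))
    pop = PopulationModel(
        age_grid=df["age"].to_numpy(),
        incidence=df["incidence"].to_numpy(),
        mortality=df["mortality"].to_numpy(),
        pv_frequencies=freqs,
        calibration=df["calibration"].to_numpy() if "calibration" in df else None,
    )
    pop.calibrated = "calibration" in df and not np.allclose(df["calibration"], 1.0)
    return pop
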