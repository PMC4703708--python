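"""All-cause mortality adjustment for BRCA2 mutation carriers.

BRCA2 carriers face excess breast- and ovarian-cancer mortality on top of
general-population all-cause mortality.  The adjustment convolves the *excess*
(carrier minus general-population) annual cancer incidence with the
cancer-attributable death distribution implied by a relative-survival curve:

    excess(a) = sum_{d=start}^{a} [inc_carrier(d) - inc_genpop(d)] * m(a - d)

where ``m(t) = RS(t) - RS(t+1)`` is the probability of cancer-attributable
death ``t`` years after diagnosis and ``m = 0`` beyond the last point of the
relative-survival curve.  Only the *excess* incidence is added because the base
life table already contains general-population breast/ovarian deaths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "CancerIncidenceSchedule",
    "RelativeSurvivalCurve",
    "AdjustedMortalitySchedule",
    "SurvivalTruncationWarning",
    "excess_cancer_mortality",
    "adjust_life_table",
    "baseline_schedule",
]

AGE_LO, AGE_HI = 20, 100
AGES = np.arange(AGE_LO, AGE_HI + 1)


class SurvivalTruncationWarning(UserWarning):
    """Relative-survival curve shorter than the projection horizon."""


def _check_age_grid(age: np.ndarray, what: str) -> None:
    if not np.array_equal(np.asarray(age, dtype=int), AGES):
        raise ValueError(f"{what} must cover every integer age {AGE_LO}-{AGE_HI} with no gaps")


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause probability of death by single year of age (20-100)."""

    age: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        _check_age_grid(self.age, "life table")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("life-table probabilities must be in [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.age, "q": self.q}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(age=df["age"].to_numpy(), q=df["q"].to_numpy())


@dataclass(frozen=True)
class CancerIncidenceSchedule:
    """Annual diagnosis probability by age, for carriers and the general population."""

    cancer: str  # "breast" | "ovarian"
    age: np.ndarray
    q_carrier: np.ndarray
    q_genpop: np.ndarray

    def __post_init__(self) -> None:
        _check_age_grid(self.age, f"{self.cancer} incidence schedule")
        for arr, name in ((self.q_carrier, "q_carrier"), (self.q_genpop, "q_genpop")):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} must be in [0, 1]")
        if np.any(self.q_carrier < self.q_genpop - 1e-12):
            raise ValueError("carrier incidence must be >= general-population incidence")

    @property
    def excess(self) -> np.ndarray:
        return np.clip(self.q_carrier - self.q_genpop, 0.0, None)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age": self.age, "q_carrier": self.q_carrier, "q_genpop": self.q_genpop}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cancer: str) -> "CancerIncidenceSchedule":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            cancer=cancer,
            age=df["age"].to_numpy(),
            q_carrier=df["q_carrier"].to_numpy(),
            q_genpop=df["q_genpop"].to_numpy(),
        )


@dataclass(frozen=True)
class RelativeSurvivalCurve:
    """Relative survival by whole years since diagnosis (non-increasing, in (0, 1])."""

    cancer: str
    years: np.ndarray
    rs: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.years, dtype=int)
        if y[0] != 0 or np.any(np.diff(y) != 1):
            raise ValueError("relative-survival years must be 0, 1, 2, ... with no gaps")
        if np.any((self.rs <= 0) | (self.rs > 1)):
            raise ValueError("relative survival must be in (0, 1]")
        if np.any(np.diff(self.rs) > 1e-12):
            raise ValueError("relative survival must be non-increasing")

    def death_mass(self, horizon: int) -> np.ndarray:
        """m(t) = RS(t) - RS(t+1) for t = 0..horizon-1, zero beyond the curve."""
        if horizon > len(self.rs) - 1:
            warnings.warn(
                f"{self.cancer} relative-survival curve ends at "
                f"{len(self.rs) - 1} y < horizon {horizon} y; assuming no "
                "cancer-attributable deaths beyond the last point",
                SurvivalTruncationWarning,
                stacklevel=3,
            )
        m = np.zeros(horizon)
        n = min(horizon, len(self.rs) - 1)
        m[:n] = self.rs[:n] - self.rs[1 : n + 1]
        return m

    def to_csv(self, path) -> None:
        pd.DataFrame({"years": self.years, "rs": self.rs}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cancer: str) -> "RelativeSurvivalCurve":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(cancer=cancer, years=df["years"].to_numpy(), rs=df["rs"].to_numpy())


@dataclass(frozen=True)
class AdjustedMortalitySchedule:
    """Age-indexed annual all-cause death probability, possibly BRCA2-adjusted."""

    age: np.ndarray
    q: np.ndarray
    provenance: str = "baseline"  # "baseline" | "brca2-adjusted"

    def __post_init__(self) -> None:
        _check_age_grid(self.age, "mortality schedule")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("mortality probabilities must be in [0, 1]")

    def per_cycle(self, cycles_per_year: int) -> np.ndarray:
        """Constant-hazard subdivision of the annual probabilities.

        Returns one per-cycle probability for each year of age 20-99.
        """
        q = self.q[:-1]
        return 1.0 - (1.0 - q) ** (1.0 / cycles_per_year)

    def annual_at(self, age: int) -> float:
        return float(self.q[int(age) - AGE_LO])

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.age, "q": self.q}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "baseline") -> "AdjustedMortalitySchedule":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(age=df["age"].to_numpy(), q=df["q"].to_numpy(), provenance=provenance)


def excess_cancer_mortality(
    incidence: CancerIncidenceSchedule,
    survival: RelativeSurvivalCurve,
    cohort_start_age: int = AGE_LO,
) -> np.ndarray:
    """Annual excess death probability by age from one cancer site.

    Convolves the excess annual incidence (from ``cohort_start_age`` on) with
    the conditional death mass of the relative-survival curve; floored at 0.
    Returns an array on the age grid 20-100.
    """
    horizon = AGE_HI - cohort_start_age + 1
    m = survival.death_mass(horizon)
    exc_inc = incidence.excess
    excess = np.zeros(len(AGES))
    start_i = cohort_start_age - AGE_LO
    # excess(a) = sum_d exc_inc(d) * m(a - d); np.convolve does exactly this.
    conv = np.convolve(exc_inc[start_i:], m)[: len(AGES) - start_i]
    excess[start_i:] = conv
    return np.clip(excess, 0.0, None)


def adjust_life_table(
    base: LifeTable, *excess_curves: np.ndarray
) -> AdjustedMortalitySchedule:
    """Add excess cancer mortality to a general-population life table.

    adjusted(a) = min(1, base(a) + sum of excess curves at a).
    """
    q = base.q.astype(float).copy()
    for exc in excess_curves:
        exc = np.asarray(exc, dtype=float)
        if exc.shape != q.shape:
            raise ValueError(
                f"excess curve length {exc.shape} does not match the life-table "
                f"age grid {q.shape}; all curves must share the 20-100 grid"
            )
        q = q + exc
    any_excess = len(excess_curves) > 0 and any(np.any(e > 0) for e in excess_curves)
    return AdjustedMortalitySchedule(
        age=base.age.copy(),
        q=np.clip(q, 0.0, 1.0),
        provenance="brca2-adjusted" if any_excess else "baseline",
    )


def baseline_schedule(base: LifeTable) -> AdjustedMortalitySchedule:
    """The unadjusted life table as a mortality schedule."""
    return AdjustedMortalitySchedule(age=base.age.copy(), q=base.q.astype(float).copy())
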