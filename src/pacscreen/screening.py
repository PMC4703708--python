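"""Screening strategies, MRI test performance, and downstream lesion management.

Error semantics are pathway-specific.  In the solid pathway only undetected
*localized* cancer is visible to the test: a false negative is a missed
localized cancer, a false positive is a healthy patient misread as having PAC
(and sent to surgery).  In the cystic pathway low-risk cysts, high-risk cysts
and localized cancer are all detectable; a detected low-risk cyst may be
misclassified as high-risk (probability ``1 - specificity``) and operated on,
otherwise it enters a ten-year annual surveillance programme.  Healthy
patients are never misread as having a cyst.  Screen results are independent
between visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import (
    CYST_HR,
    CYST_LR,
    CYST_PRELOC,
    DEATH_STATES,
    DEATH_SURGERY,
    N_STATES,
    NORMAL,
    NORMAL_UNSCREENED,
    POSTSURG_CURED,
    POSTSURG_LOC,
    SOLID_PRELOC,
    SURV_HR,
    SURV_PRELOC,
    SURVEIL,
)

__all__ = [
    "TestPerformance",
    "ScreeningStrategy",
    "ManagementPolicy",
    "StudyCounts",
    "ScreenEvents",
    "screen_ages",
    "apply_screen",
    "surveillance_visit",
    "surgery_outcome",
    "pooled_test_performance",
    "screen_matrix",
    "surveillance_matrix",
]

#: surgery indications tracked by the cohort trace
SURGERY_KEYS = (
    "localized_pac",
    "high_risk_cyst",
    "solid_false_positive",
    "cyst_misclassification",
    "surveillance_progression",
)

#: screen-detected lesion categories
DETECTION_KEYS = (
    "solid_pac",
    "cyst_pac",
    "low_risk_cyst",
    "high_risk_cyst",
    "surveillance_high_risk",
    "surveillance_pac",
)


@dataclass(frozen=True)
class TestPerformance:
    """Operating characteristics of the (composite MRI ± EUS) screening test."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class ScreeningStrategy:
    """A screening regimen: none, one-time at ``start_age``, or repeated at a
    fixed interval from ``start_age`` through ``stop_age``."""

    mode: str = "none"  # none | one_time | interval
    start_age: float = 50.0
    stop_age: float = 80.0
    interval_years: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "one_time", "interval"):
            raise ValueError(f"unknown strategy mode {self.mode!r}")
        if self.mode != "none":
            if not 20.0 <= self.start_age <= self.stop_age <= 100.0:
                raise ValueError(
                    "require 20 <= start_age <= stop_age <= 100, got "
                    f"({self.start_age}, {self.stop_age})"
                )
        if self.mode == "interval" and self.interval_years <= 0:
            raise ValueError("interval_years must be positive")

    @classmethod
    def none(cls) -> "ScreeningStrategy":
        return cls(mode="none")

    @classmethod
    def one_time(cls, start_age: float = 50.0) -> "ScreeningStrategy":
        return cls(mode="one_time", start_age=start_age, stop_age=start_age)

    @classmethod
    def annual(cls, start_age: float = 50.0, stop_age: float = 80.0) -> "ScreeningStrategy":
        return cls(mode="interval", start_age=start_age, stop_age=stop_age, interval_years=1.0)


@dataclass(frozen=True)
class ManagementPolicy:
    """What happens after a positive screen.

    surgical_mortality
        Probability of perioperative death, applied to every pancreatic
        resection regardless of indication (default 1%, literature range 1-6%).
    surveillance_years
        Length of the annual surveillance programme for screen-detected
        low-risk cysts (fixed at 10 in the base case).
    high_risk_fraction
        Share of screen-detected cysts that are high-risk; the state space
        tracks cyst risk level explicitly, so this is configuration consumed by
        the synthetic-truth generator rather than by `apply_screen`.
    resume_screening_after_fp
        If True (default), survivors of a false-positive surgery return to the
        screen-eligible Normal state; if False they are exempted from further
        screening.
    """

    surgical_mortality: float = 0.01
    surveillance_years: int = 10
    high_risk_fraction: float = 0.10
    resume_screening_after_fp: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.surgical_mortality <= 1.0:
            raise ValueError("surgical_mortality must be in [0, 1]")
        if not 0.0 <= self.high_risk_fraction <= 1.0:
            raise ValueError("high_risk_fraction must be in [0, 1]")
        if self.surveillance_years < 1:
            raise ValueError("surveillance_years must be >= 1")


@dataclass(frozen=True)
class StudyCounts:
    """2x2 classification counts from one screening study."""

    study_id: str
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ScreenEvents:
    """Event-mass increments produced by one screen or surveillance visit."""

    screens: float = 0.0
    surgeries: dict = field(default_factory=lambda: {k: 0.0 for k in SURGERY_KEYS})
    detections: dict = field(default_factory=lambda: {k: 0.0 for k in DETECTION_KEYS})


def screen_ages(strategy: ScreeningStrategy, cycles_per_year: int = 12) -> list[float]:
    """Ages (in years, rounded to the cycle grid) at which screens occur."""
    grid = cycles_per_year

    def snap(a: float) -> float:
        return round(a * grid) / grid

    if strategy.mode == "none":
        return []
    if strategy.mode == "one_time":
        return [snap(strategy.start_age)]
    ages = []
    k = 0
    while True:
        a = strategy.start_age + k * strategy.interval_years
        a_snapped = snap(a)
        if a_snapped > strategy.stop_age + 1e-9:
            break
        ages.append(a_snapped)
        k += 1
    return ages


def surgery_outcome(mass: float, surgical_mortality: float, destination: int):
    """Split a probability mass undergoing surgery into survivors (sent to
    ``destination``) and perioperative deaths.  Returns
    ``(survivor_mass, death_mass)``; the caller routes them."""
    if mass < 0:
        raise ValueError("mass must be non-negative")
    dead = mass * surgical_mortality
    return mass - dead, dead


def _resection_split(mass: float, m: float, cure_fraction: float):
    """Survivors of a PAC resection split into cured and residual-risk strata."""
    alive, dead = surgery_outcome(mass, m, POSTSURG_LOC)
    return alive * cure_fraction, alive * (1.0 - cure_fraction), dead


def apply_screen(
    dist: np.ndarray,
    test: TestPerformance,
    policy: ManagementPolicy,
    cure_fraction: float = 0.0,
) -> tuple[np.ndarray, ScreenEvents]:
    """Apply one screen to a cohort distribution.

    Occupancy is conserved exactly: every moved mass is subtracted from its
    source and added to a destination (possibly ``Death_Surgery``).  With an
    inert test (sensitivity 0, specificity 1) all deltas are exactly zero and
    the returned array is bitwise equal to a copy of the input.
    """
    sens = test.sensitivity
    spec = test.specificity
    m = policy.surgical_mortality

    d = dist.copy()
    ev = ScreenEvents()
    ev.screens = float(dist.sum() - dist[list(DEATH_STATES)].sum())

    fp_return = NORMAL if policy.resume_screening_after_fp else NORMAL_UNSCREENED

    # Normal: false positives go to surgery; survivors return healthy.
    fp = dist[NORMAL] * (1.0 - spec)
    if fp != 0.0:
        alive, dead = surgery_outcome(fp, m, fp_return)
        d[NORMAL] -= fp
        d[fp_return] += alive
        d[DEATH_SURGERY] += dead
        ev.surgeries["solid_false_positive"] += fp

    # Undetected localized solid-pathway cancer: true positives are resected.
    det = dist[SOLID_PRELOC] * sens
    if det != 0.0:
        cured, residual, dead = _resection_split(det, m, cure_fraction)
        d[SOLID_PRELOC] -= det
        d[POSTSURG_CURED] += cured
        d[POSTSURG_LOC] += residual
        d[DEATH_SURGERY] += dead
        ev.surgeries["localized_pac"] += det
        ev.detections["solid_pac"] += det

    # Low-risk cyst: detected with `sens`; a detected low-risk cyst is
    # misclassified as high-risk (surgery) with probability 1 - specificity,
    # otherwise enrolled in annual surveillance.
    det = dist[CYST_LR] * sens
    if det != 0.0:
        misclass = det * (1.0 - spec)
        alive, dead = surgery_outcome(misclass, m, NORMAL)
        d[CYST_LR] -= det
        d[NORMAL] += alive
        d[DEATH_SURGERY] += dead
        d[SURVEIL[0]] += det - misclass
        ev.surgeries["cyst_misclassification"] += misclass
        ev.detections["low_risk_cyst"] += det

    # High-risk cyst: detection prompts resection; survivors return to Normal.
    det = dist[CYST_HR] * sens
    if det != 0.0:
        alive, dead = surgery_outcome(det, m, NORMAL)
        d[CYST_HR] -= det
        d[NORMAL] += alive
        d[DEATH_SURGERY] += dead
        ev.surgeries["high_risk_cyst"] += det
        ev.detections["high_risk_cyst"] += det

    # Undetected localized cancer in the cystic pathway: resected like solid.
    det = dist[CYST_PRELOC] * sens
    if det != 0.0:
        cured, residual, dead = _resection_split(det, m, cure_fraction)
        d[CYST_PRELOC] -= det
        d[POSTSURG_CURED] += cured
        d[POSTSURG_LOC] += residual
        d[DEATH_SURGERY] += dead
        ev.surgeries["localized_pac"] += det
        ev.detections["cyst_pac"] += det

    return d, ev


def surveillance_visit(
    dist: np.ndarray,
    policy: ManagementPolicy,
    cure_fraction: float = 0.0,
) -> tuple[np.ndarray, ScreenEvents]:
    """One annual surveillance visit.

    Progression since the last visit is detected with probability 1: high-risk
    cysts and localized cancers found under surveillance go to surgery.  Clean
    surveillance years advance by one; after the final year the cyst returns to
    the undetected low-risk pool.
    """
    m = policy.surgical_mortality
    d = dist.copy()
    ev = ScreenEvents()

    hr = dist[SURV_HR]
    if hr != 0.0:
        alive, dead = surgery_outcome(hr, m, NORMAL)
        d[SURV_HR] -= hr
        d[NORMAL] += alive
        d[DEATH_SURGERY] += dead
        ev.surgeries["surveillance_progression"] += hr
        ev.detections["surveillance_high_risk"] += hr

    pac = dist[SURV_PRELOC]
    if pac != 0.0:
        cured, residual, dead = _resection_split(pac, m, cure_fraction)
        d[SURV_PRELOC] -= pac
        d[POSTSURG_CURED] += cured
        d[POSTSURG_LOC] += residual
        d[DEATH_SURGERY] += dead
        ev.surgeries["surveillance_progression"] += pac
        ev.detections["surveillance_pac"] += pac

    # Advance surveillance years (last year exits back to the undetected pool).
    exiting = dist[SURVEIL[-1]]
    for k in range(len(SURVEIL) - 1, 0, -1):
        d[SURVEIL[k]] += dist[SURVEIL[k - 1]]
        d[SURVEIL[k - 1]] -= dist[SURVEIL[k - 1]]
    if exiting != 0.0:
        d[SURVEIL[-1]] -= exiting
        d[CYST_LR] += exiting

    return d, ev


def _operator_matrix(op, *args, **kwargs) -> np.ndarray:
    """Row-stochastic matrix representation of a linear distribution operator."""
    M = np.zeros((N_STATES, N_STATES))
    for s in range(N_STATES):
        e = np.zeros(N_STATES)
        e[s] = 1.0
        M[s], _ = op(e, *args, **kwargs)
    return M


def screen_matrix(test: TestPerformance, policy: ManagementPolicy, cure_fraction: float = 0.0) -> np.ndarray:
    """`apply_screen` as a row-stochastic matrix (used by the microsimulator)."""
    return _operator_matrix(apply_screen, test, policy, cure_fraction)


def surveillance_matrix(policy: ManagementPolicy, cure_fraction: float = 0.0) -> np.ndarray:
    return _operator_matrix(surveillance_visit, policy, cure_fraction)


def pooled_test_performance(studies: list[StudyCounts]) -> TestPerformance:
    """Pool per-study 2x2 counts into overall sensitivity and specificity.

    sensitivity = sum(TP) / sum(TP + FN); specificity = sum(TN) / sum(TN + FP).
    """
    tp = sum(s.tp for s in studies)
    fn = sum(s.fn for s in studies)
    tn = sum(s.tn for s in studies)
    fp = sum(s.fp for s in studies)
    if tp + fn == 0:
        raise ValueError("no diseased cases across studies: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no disease-free cases across studies: specificity undefined")
    return TestPerformance(sensitivity=tp / (tp + fn), specificity=tn / (tn + fp))
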