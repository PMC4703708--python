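"""Synthetic stand-ins for every external input the analysis needs.

Real analyses of this kind calibrate to registry summaries (SEER incidence,
stage mix, stage survival), U.S. life tables, and published BRCA2 breast and
ovarian cancer incidence — none of which ship with the package.  This module
generates shaped synthetic versions with *known ground truth*: a
Gompertz–Makeham life table, unimodal BRCA2 cancer-incidence schedules with
exponential relative-survival decay, and a truth parameter set whose
registry-style summaries become the calibration targets.  Every downstream
stage (competing-mortality adjustment, calibration recovery, screening
evaluation) therefore runs offline and is testable against known truth.

The stated world of the default fixture: ~1.3% baseline lifetime PAC risk,
10% of cancers via the cystic pathway, MRI sensitivity 56% / specificity 97%,
surgical mortality 1%, and cohort relative risks 3.5 / 4.5 / 6.4 / 32.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .calibration import CalibrationTargets, predict_targets
from .competing_mortality import (
    AGES,
    AdjustedMortalitySchedule,
    CancerIncidenceSchedule,
    LifeTable,
    RelativeSurvivalCurve,
    SurvivalTruncationWarning,
    adjust_life_table,
    baseline_schedule,
    excess_cancer_mortality,
)
from .natural_history import AgeBandSchedule, NaturalHistoryParams, evolve, lifetime_pac_incidence
from .screening import ManagementPolicy, StudyCounts, TestPerformance

__all__ = [
    "FixtureBundle",
    "make_life_table",
    "make_brca2_schedules",
    "make_calibration_targets",
    "make_truth_params",
    "make_studies",
    "default_fixture",
]

#: cohort relative risks of PAC versus the general population
COHORT_RR = {"primary": 3.5, "fdr1": 4.5, "fdr2": 6.4, "fdr3plus": 32.0}

LIFETIME_PAC_RISK = 0.013
CYSTIC_FRACTION = 0.10


def make_life_table(
    baseline_hazard: float = 2.5e-4,
    slope: float = 0.088,
    constant: float = 4.0e-4,
) -> LifeTable:
    """Gompertz–Makeham life table: q(a) = baseline * exp(slope*(a-20)) + constant.

    Annual death probabilities are strictly increasing with age for any
    positive slope; values reaching 1 before age 100 are clamped with a
    warning.
    """
    q = baseline_hazard * np.exp(slope * (AGES - 20.0)) + constant
    if np.any(q >= 1.0):
        warnings.warn("life-table q reached 1 before age 100; clamping", UserWarning)
        q = np.clip(q, 0.0, 1.0)
    return LifeTable(age=AGES.copy(), q=q)


def _gaussian_incidence(peak_age: float, sd: float, lifetime_risk: float) -> np.ndarray:
    shape = np.exp(-0.5 * ((AGES - peak_age) / sd) ** 2)
    return lifetime_risk * shape / shape.sum()


def make_brca2_schedules(
    breast_peak_age: float = 50.0,
    breast_sd: float = 13.0,
    breast_lifetime_carrier: float = 0.45,
    breast_lifetime_genpop: float = 0.12,
    breast_survival_decay: float = 0.021,
    ovarian_peak_age: float = 60.0,
    ovarian_sd: float = 11.0,
    ovarian_lifetime_carrier: float = 0.15,
    ovarian_lifetime_genpop: float = 0.013,
    ovarian_survival_decay: float = 0.16,
    survival_years: int = 20,
):
    """Smooth unimodal incidence curves and exponential relative-survival decay.

    Carrier and general-population curves share a shape (scaled to their
    lifetime risks), which guarantees carrier >= general-population incidence
    at every age.  Cumulative incidence over ages 20-100 equals the requested
    lifetime risk by construction.  Returns
    (breast incidence, ovarian incidence, breast RS, ovarian RS).
    """
    for name, carrier, genpop in (
        ("breast", breast_lifetime_carrier, breast_lifetime_genpop),
        ("ovarian", ovarian_lifetime_carrier, ovarian_lifetime_genpop),
    ):
        if not 0.0 < carrier < 1.0:
            raise ValueError(f"{name} carrier lifetime risk must be in (0, 1)")
        if genpop > carrier:
            raise ValueError(f"{name} carrier risk must exceed general-population risk")

    breast = CancerIncidenceSchedule(
        cancer="breast",
        age=AGES.copy(),
        q_carrier=_gaussian_incidence(breast_peak_age, breast_sd, breast_lifetime_carrier),
        q_genpop=_gaussian_incidence(breast_peak_age, breast_sd, breast_lifetime_genpop),
    )
    ovarian = CancerIncidenceSchedule(
        cancer="ovarian",
        age=AGES.copy(),
        q_carrier=_gaussian_incidence(ovarian_peak_age, ovarian_sd, ovarian_lifetime_carrier),
        q_genpop=_gaussian_incidence(ovarian_peak_age, ovarian_sd, ovarian_lifetime_genpop),
    )
    years = np.arange(survival_years + 1)
    breast_rs = RelativeSurvivalCurve(
        "breast", years, np.exp(-breast_survival_decay * years)
    )
    ovarian_rs = RelativeSurvivalCurve(
        "ovarian", years, np.exp(-ovarian_survival_decay * years)
    )
    return breast, ovarian, breast_rs, ovarian_rs


# --- truth natural-history parameters -------------------------------------

_BAND_EDGES = tuple(float(a) for a in range(30, 90, 5))


def _onset_shape() -> np.ndarray:
    """Exponential rise across 5-year bands from age 30, flat from 85."""
    los = np.array(_BAND_EDGES)
    return np.exp(0.075 * (np.minimum(los, 85.0) - 30.0))


def _monthly(p_annual: float) -> float:
    return 1.0 - (1.0 - p_annual) ** (1.0 / 12.0)


def make_truth_params(
    mortality: AdjustedMortalitySchedule,
    seed: int = 0,
    lifetime_risk: float = LIFETIME_PAC_RISK,
    cystic_fraction: float = CYSTIC_FRACTION,
    cycles_per_year: int = 12,
) -> NaturalHistoryParams:
    """Ground-truth parameters tuned to the stated lifetime risk and pathway split.

    Progression/detection/survival values are fixed a priori (see the methods
    note), with a small seeded jitter (+-2%) so different fixture seeds yield
    distinct truths; the onset schedules are then tuned by two nested scalar
    searches so that the baseline lifetime PAC incidence and the cystic
    pathway fraction hit their stated values regardless of the jitter.
    """
    rng = np.random.default_rng(seed)
    j = 1.0 + 0.02 * rng.uniform(-1.0, 1.0, size=6)

    shape = _onset_shape()
    params = NaturalHistoryParams(
        onset_solid=AgeBandSchedule(_BAND_EDGES, tuple(1e-6 * shape)),
        onset_cyst=AgeBandSchedule(_BAND_EDGES, tuple(2e-6 * shape)),
        prog_lr_hr=_monthly(0.02) * j[0],
        prog_hr_pac=_monthly(0.15) * j[1],
        prog_loc_reg=(1.0 / 18.0) * j[2],  # mean preclinical localized sojourn ~18 mo
        prog_reg_dist=(1.0 / 12.0) * j[3],
        detect_clin_loc=0.00617 * j[4],
        detect_clin_reg=0.0417 * j[5],
        detect_clin_dist=0.25,
        surv_dx_loc=1.0 - 0.25 ** (1.0 / 60.0),
        surv_dx_reg=1.0 - 0.10 ** (1.0 / 60.0),
        surv_dx_dist=1.0 - 0.02 ** (1.0 / 60.0),
        cure_fraction_resected=0.20,
    )

    def summaries(p: NaturalHistoryParams):
        trace = evolve(p, mortality, cycles_per_year=cycles_per_year)
        onsets = trace.onset_flow.sum(axis=0)
        frac = onsets[1] / onsets.sum() if onsets.sum() > 0 else 0.0
        return lifetime_pac_incidence(trace), frac

    for _ in range(3):
        # cystic multiplier: pathway split is monotone in it
        def frac_err(log_m: float) -> float:
            p = params.replace(onset_cyst=params.onset_cyst.scaled(np.exp(log_m)))
            return summaries(p)[1] - cystic_fraction

        log_m = scipy.optimize.brentq(frac_err, -8.0, 8.0, xtol=1e-8)
        params = params.replace(onset_cyst=params.onset_cyst.scaled(np.exp(log_m)))

        # overall multiplier: lifetime incidence is monotone in it
        def life_err(log_m: float) -> float:
            m = np.exp(log_m)
            p = params.replace(
                onset_solid=params.onset_solid.scaled(m),
                onset_cyst=params.onset_cyst.scaled(m),
            )
            return summaries(p)[0] - lifetime_risk

        log_m = scipy.optimize.brentq(life_err, -6.0, 6.0, xtol=1e-8)
        m = np.exp(log_m)
        params = params.replace(
            onset_solid=params.onset_solid.scaled(m),
            onset_cyst=params.onset_cyst.scaled(m),
        )
    return params


def make_calibration_targets(
    truth: NaturalHistoryParams,
    mortality: AdjustedMortalitySchedule,
    cycles_per_year: int = 12,
) -> CalibrationTargets:
    """Registry-style targets generated from known truth (exactly
    ``predict_targets(truth, mortality)``), stored with the fixture so
    calibration-recovery tests have a noise-free ground truth."""
    return predict_targets(truth, mortality, cycles_per_year=cycles_per_year)


def make_studies() -> list[StudyCounts]:
    """Synthetic six-study MRI classification table.

    The per-study split is invented (the source studies' individual counts are
    not reproduced here); the pooled totals are exact: sensitivity 5/9,
    specificity 739/760.
    """
    rows = [
        ("study1", 1, 1, 110, 4),
        ("study2", 1, 0, 75, 2),
        ("study3", 0, 1, 140, 5),
        ("study4", 2, 1, 200, 6),
        ("study5", 1, 0, 94, 3),
        ("study6", 0, 1, 120, 1),
    ]
    return [StudyCounts(sid, tp, fn, tn, fp) for sid, tp, fn, tn, fp in rows]


@dataclass
class FixtureBundle:
    """Everything the pipeline consumes, generated with known ground truth."""

    life_table: LifeTable
    breast_incidence: CancerIncidenceSchedule
    ovarian_incidence: CancerIncidenceSchedule
    breast_relsurv: RelativeSurvivalCurve
    ovarian_relsurv: RelativeSurvivalCurve
    mortality_baseline: AdjustedMortalitySchedule
    mortality_adjusted: AdjustedMortalitySchedule
    truth_params: NaturalHistoryParams
    targets: CalibrationTargets
    cohorts: dict[str, float]
    test: TestPerformance
    policy: ManagementPolicy
    studies: list[StudyCounts]
    seed: int

    @property
    def mortality(self) -> AdjustedMortalitySchedule:
        """The analysis cohort's (BRCA2-adjusted) mortality schedule."""
        return self.mortality_adjusted

    def studies_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.study_id, s.tp, s.fn, s.tn, s.fp) for s in self.studies],
            columns=["study_id", "tp", "fn", "tn", "fp"],
        )


def default_fixture(seed: int = 0) -> FixtureBundle:
    """The shipped synthetic world (deterministic given ``seed``)."""
    life = make_life_table()
    breast, ovarian, breast_rs, ovarian_rs = make_brca2_schedules()
    with warnings.catch_warnings():
        # default RS curves stop at 20 y; the m=0 tail rule is intended here
        warnings.simplefilter("ignore", SurvivalTruncationWarning)
        exc_b = excess_cancer_mortality(breast, breast_rs)
        exc_o = excess_cancer_mortality(ovarian, ovarian_rs)
    adjusted = adjust_life_table(life, exc_b, exc_o)
    truth = make_truth_params(adjusted, seed=seed)
    targets = make_calibration_targets(truth, adjusted)
    return FixtureBundle(
        life_table=life,
        breast_incidence=breast,
        ovarian_incidence=ovarian,
        breast_relsurv=breast_rs,
        ovarian_relsurv=ovarian_rs,
        mortality_baseline=baseline_schedule(life),
        mortality_adjusted=adjusted,
        truth_params=truth,
        targets=targets,
        cohorts=dict(COHORT_RR),
        test=TestPerformance(sensitivity=0.56, specificity=0.97),
        policy=ManagementPolicy(surgical_mortality=0.01),
        studies=make_studies(),
        seed=seed,
    )
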