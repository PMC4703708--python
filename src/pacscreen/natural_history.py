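"""Cycle-by-cycle Markov evolution of a cohort from age 20 to death or age 100.

The cohort starts healthy at age 20 and is propagated in monthly cycles
(12 cycles/year by default).  Within each cycle events are composed in a fixed
order: any scheduled surveillance visit, then any scheduled screen, then the
natural-history transition, which itself applies (1) other-cause death and
(2) disease transitions conditional on surviving (1).  Disease events leaving a
state are mutually exclusive within a cycle.

Two engines share the same operator sequence: :func:`evolve` propagates the
occupancy distribution exactly (matrix engine), and :func:`microsimulate`
samples individual trajectories and serves as its independent Monte-Carlo
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import states as S
from .screening import (
    DETECTION_KEYS,
    SURGERY_KEYS,
    ManagementPolicy,
    ScreenEvents,
    ScreeningStrategy,
    TestPerformance,
    apply_screen,
    screen_ages,
    screen_matrix,
    surveillance_matrix,
    surveillance_visit,
)

__all__ = [
    "AgeBandSchedule",
    "NaturalHistoryParams",
    "CohortTrace",
    "MicrosimTrace",
    "TraceCounters",
    "ParameterizationError",
    "InvariantError",
    "transition_matrix",
    "evolve",
    "microsimulate",
    "lifetime_pac_incidence",
]

START_AGE = 20
END_AGE = 100
N_YEARS = END_AGE - START_AGE


class ParameterizationError(ValueError):
    """A composed transition probability left [0, 1]."""


class InvariantError(RuntimeError):
    """An internal conservation invariant was violated."""


@dataclass(frozen=True)
class AgeBandSchedule:
    """Piecewise-constant per-cycle probability on age bands.

    ``edges[i]`` is the starting age of band ``i``; the schedule is 0 before
    the first edge and flat at the last value beyond the last edge.
    """

    edges: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.values):
            raise ValueError("edges and values must have equal length")
        if list(self.edges) != sorted(self.edges):
            raise ValueError("band edges must be ascending")
        if any(not 0.0 <= v <= 1.0 for v in self.values):
            raise ValueError("schedule values must be probabilities in [0, 1]")

    def at(self, age: float) -> float:
        i = int(np.searchsorted(self.edges, age, side="right")) - 1
        if i < 0:
            return 0.0
        return self.values[i]

    def scaled(self, factor: float) -> "AgeBandSchedule":
        return AgeBandSchedule(self.edges, tuple(v * factor for v in self.values))

    @classmethod
    def constant(cls, value: float) -> "AgeBandSchedule":
        return cls((float(START_AGE),), (value,))

    @classmethod
    def zero(cls) -> "AgeBandSchedule":
        return cls((float(START_AGE),), (0.0,))


@dataclass(frozen=True)
class NaturalHistoryParams:
    """All transition probabilities of the natural-history model.

    Every field is a *per-cycle* (monthly, by default) probability.  Onset
    schedules are age-dependent; progression, clinical-presentation and
    diagnosed-state death probabilities are age-invariant.
    """

    onset_solid: AgeBandSchedule
    onset_cyst: AgeBandSchedule
    prog_lr_hr: float  # low-risk cyst -> high-risk cyst
    prog_hr_pac: float  # high-risk cyst -> undetected localized cancer
    prog_loc_reg: float  # preclinical localized -> regional
    prog_reg_dist: float  # preclinical regional -> distant
    detect_clin_loc: float  # clinical presentation from preclinical localized
    detect_clin_reg: float
    detect_clin_dist: float
    surv_dx_loc: float  # per-cycle PAC death probability, diagnosed localized
    surv_dx_reg: float
    surv_dx_dist: float
    cure_fraction_resected: float = 0.0

    _SCALARS = (
        "prog_lr_hr",
        "prog_hr_pac",
        "prog_loc_reg",
        "prog_reg_dist",
        "detect_clin_loc",
        "detect_clin_reg",
        "detect_clin_dist",
        "surv_dx_loc",
        "surv_dx_reg",
        "surv_dx_dist",
        "cure_fraction_resected",
    )

    def __post_init__(self) -> None:
        for name in self._SCALARS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterizationError(f"{name} must be in [0, 1], got {v}")
        if not self.surv_dx_dist >= self.surv_dx_reg >= self.surv_dx_loc:
            raise ParameterizationError(
                "diagnosed-stage death probabilities must satisfy "
                "surv_dx_dist >= surv_dx_reg >= surv_dx_loc"
            )
        if self.detect_clin_dist < self.detect_clin_loc:
            raise ParameterizationError("require detect_clin_dist >= detect_clin_loc")

    def replace(self, **kwargs) -> "NaturalHistoryParams":
        return replace(self, **kwargs)


def transition_matrix(
    params: NaturalHistoryParams, acm_hazard: float, age: float
) -> np.ndarray:
    """Row-stochastic per-cycle transition matrix at a given age.

    Other-cause death (``acm_hazard``) applies first to every alive state;
    disease events, mutually exclusive, apply to the survivors.
    """
    if not 0.0 <= acm_hazard <= 1.0:
        raise ParameterizationError(f"acm_hazard must be in [0, 1], got {acm_hazard}")
    if not START_AGE <= age <= END_AGE:
        raise ValueError(f"age must be in [{START_AGE}, {END_AGE}], got {age}")

    M = np.zeros((S.N_STATES, S.N_STATES))
    for d in S.DEATH_STATES:
        M[d, d] = 1.0

    def fill(row: int, events: dict[int, float]) -> None:
        total = 0.0
        for dest, p in events.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterizationError(
                    f"transition {S.STATES[row]} -> {S.STATES[dest]} has "
                    f"probability {p} outside [0, 1]"
                )
            total += p
        if total > 1.0 + 1e-12:
            raise ParameterizationError(
                f"disease-event probabilities out of state {S.STATES[row]} "
                f"sum to {total} > 1"
            )
        surv = 1.0 - acm_hazard
        M[row, S.DEATH_OTHER] = acm_hazard
        for dest, p in events.items():
            M[row, dest] += surv * p
        M[row, row] += surv * (1.0 - total)

    p = params
    onset = {
        S.SOLID_PRELOC: p.onset_solid.at(age),
        S.CYST_LR: p.onset_cyst.at(age),
    }
    fill(S.NORMAL, onset)
    fill(S.NORMAL_UNSCREENED, {S.SOLID_PRELOC: onset[S.SOLID_PRELOC], S.CYST_LR: onset[S.CYST_LR]})
    fill(S.SOLID_PRELOC, {S.SOLID_PREREG: p.prog_loc_reg, S.DX_LOC: p.detect_clin_loc})
    fill(S.SOLID_PREREG, {S.SOLID_PREDIST: p.prog_reg_dist, S.DX_REG: p.detect_clin_reg})
    fill(S.SOLID_PREDIST, {S.DX_DIST: p.detect_clin_dist})
    fill(S.CYST_LR, {S.CYST_HR: p.prog_lr_hr})
    fill(S.CYST_HR, {S.CYST_PRELOC: p.prog_hr_pac})
    # Cystic cancers merge into the solid preclinical chain past localized stage.
    fill(S.CYST_PRELOC, {S.SOLID_PREREG: p.prog_loc_reg, S.DX_LOC: p.detect_clin_loc})
    for row in S.SURVEIL:
        fill(row, {S.SURV_HR: p.prog_lr_hr})
    fill(S.SURV_HR, {S.SURV_PRELOC: p.prog_hr_pac})
    fill(S.SURV_PRELOC, {S.SOLID_PREREG: p.prog_loc_reg, S.DX_LOC: p.detect_clin_loc})
    fill(S.DX_LOC, {S.DEATH_PAC: p.surv_dx_loc})
    fill(S.DX_REG, {S.DEATH_PAC: p.surv_dx_reg})
    fill(S.DX_DIST, {S.DEATH_PAC: p.surv_dx_dist})
    fill(S.POSTSURG_LOC, {S.DEATH_PAC: p.surv_dx_loc})
    fill(S.POSTSURG_CURED, {})
    return M


@dataclass
class TraceCounters:
    """Cumulative event masses accumulated along a cohort trace."""

    screens_performed: float = 0.0
    surgeries: dict = field(default_factory=lambda: {k: 0.0 for k in SURGERY_KEYS})
    deaths: dict = field(default_factory=lambda: {"pac": 0.0, "other": 0.0, "surgery": 0.0})
    screen_detections: dict = field(default_factory=lambda: {k: 0.0 for k in DETECTION_KEYS})
    clinical_diagnoses: dict = field(
        default_factory=lambda: {"localized": 0.0, "regional": 0.0, "distant": 0.0}
    )

    def absorb(self, ev: ScreenEvents) -> None:
        self.screens_performed += ev.screens
        for k, v in ev.surgeries.items():
            self.surgeries[k] += v
        for k, v in ev.detections.items():
            self.screen_detections[k] += v


@dataclass
class CohortTrace:
    """Per-cycle occupancy plus cumulative event counters.

    ``occupancy[k]`` is the distribution at the *start* of cycle ``k`` (after
    any same-cycle screening events have been applied for k >= 1 rows the end
    of the previous cycle).  ``clin_dx_flow[k]`` / ``onset_flow[k]`` are the
    diagnosis and cancer-onset masses occurring during cycle ``k``.
    """

    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    cycles_per_year: int
    counters: TraceCounters
    clin_dx_flow: np.ndarray  # (n_cycles, 3) localized/regional/distant
    onset_flow: np.ndarray  # (n_cycles, 2) solid/cystic

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        """Age at the start of each occupancy row."""
        return START_AGE + np.arange(self.occupancy.shape[0]) / self.cycles_per_year

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, list(S.ALIVE_STATES)].sum(axis=1)

    def occupancy_at_age(self, age: float) -> np.ndarray:
        k = round((age - START_AGE) * self.cycles_per_year)
        return self.occupancy[k]

    def validate(self, tol: float = 1e-9) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > tol):
            raise InvariantError(f"occupancy drift {np.max(np.abs(sums - 1.0)):.3e}")
        if np.any(self.occupancy < -tol):
            raise InvariantError("negative occupancy")


@dataclass
class MicrosimTrace(CohortTrace):
    """Monte-Carlo estimate of a cohort trace."""

    n_individuals: int = 0
    seed: int = 0

    def occupancy_se(self) -> np.ndarray:
        """Binomial standard error of each occupancy estimate."""
        p = self.occupancy
        return np.sqrt(np.clip(p * (1.0 - p), 0.0, None) / self.n_individuals)


def _schedule_cycles(
    strategy: ScreeningStrategy | None, cycles_per_year: int, n_cycles: int
):
    """Cycle indices of screens and of annual surveillance visits."""
    if strategy is None or strategy.mode == "none":
        return set(), set()
    scr = {
        round((a - START_AGE) * cycles_per_year)
        for a in screen_ages(strategy, cycles_per_year)
    }
    start = round((strategy.start_age - START_AGE) * cycles_per_year)
    visits = set(range(start + cycles_per_year, n_cycles, cycles_per_year))
    return scr, visits


def _year_matrices(
    params: NaturalHistoryParams, mortality, cycles_per_year: int
) -> np.ndarray:
    q_cycle = mortality.per_cycle(cycles_per_year)
    return np.stack(
        [
            transition_matrix(params, q_cycle[y], START_AGE + y)
            for y in range(N_YEARS)
        ]
    )


def evolve(
    params: NaturalHistoryParams,
    mortality,
    strategy: ScreeningStrategy | None = None,
    test: TestPerformance | None = None,
    policy: ManagementPolicy | None = None,
    cycles_per_year: int = 12,
) -> CohortTrace:
    """Propagate the cohort distribution from age 20 to age 100.

    ``mortality`` is an :class:`~pacscreen.competing_mortality.AdjustedMortalitySchedule`
    (or anything with a ``per_cycle(cycles_per_year)`` method).  When a
    strategy is supplied, screening and surveillance operators are applied at
    the start of their scheduled cycles, before the natural-history step.
    """
    n_cycles = N_YEARS * cycles_per_year
    screening_on = strategy is not None and strategy.mode != "none"
    if screening_on and (test is None or policy is None):
        raise ValueError("screening strategy requires test and policy")
    scr_cycles, visit_cycles = _schedule_cycles(strategy, cycles_per_year, n_cycles)

    mats = _year_matrices(params, mortality, cycles_per_year)
    matsT = mats.transpose(0, 2, 1).copy()

    occ = np.empty((n_cycles + 1, S.N_STATES))
    d = np.zeros(S.N_STATES)
    d[S.NORMAL] = 1.0
    occ[0] = d

    counters = TraceCounters()
    clin_dx_flow = np.zeros((n_cycles, 3))
    onset_flow = np.zeros((n_cycles, 2))
    cure = params.cure_fraction_resected

    for k in range(n_cycles):
        if screening_on:
            if k in visit_cycles:
                d, ev = surveillance_visit(d, policy, cure)
                counters.absorb(ev)
            if k in scr_cycles:
                d, ev = apply_screen(d, test, policy, cure)
                counters.absorb(ev)
            occ[k] = d  # post-screen snapshot for this cycle start
        y = k // cycles_per_year
        M = mats[y]
        # flows recorded before the state update
        onset_flow[k, 0] = (
            d[S.NORMAL] * M[S.NORMAL, S.SOLID_PRELOC]
            + d[S.NORMAL_UNSCREENED] * M[S.NORMAL_UNSCREENED, S.SOLID_PRELOC]
        )
        onset_flow[k, 1] = (
            d[S.CYST_HR] * M[S.CYST_HR, S.CYST_PRELOC]
            + d[S.SURV_HR] * M[S.SURV_HR, S.SURV_PRELOC]
        )
        for j, dx in enumerate(S.DX_STATES):
            clin_dx_flow[k, j] = d @ M[:, dx] - d[dx] * M[dx, dx]
        d = matsT[y] @ d
        total = d.sum()
        if abs(total - 1.0) > 1e-9:
            raise InvariantError(f"occupancy drift {total - 1.0:.3e} at cycle {k}")
        occ[k + 1] = d

    for key, dx in (("localized", S.DX_LOC), ("regional", S.DX_REG), ("distant", S.DX_DIST)):
        counters.clinical_diagnoses[key] = clin_dx_flow[:, S.DX_STATES.index(dx)].sum()
    counters.deaths["pac"] = occ[-1, S.DEATH_PAC]
    counters.deaths["other"] = occ[-1, S.DEATH_OTHER]
    counters.deaths["surgery"] = occ[-1, S.DEATH_SURGERY]

    trace = CohortTrace(occ, cycles_per_year, counters, clin_dx_flow, onset_flow)
    trace.validate()
    return trace


def microsimulate(
    params: NaturalHistoryParams,
    mortality,
    strategy: ScreeningStrategy | None,
    test: TestPerformance | None,
    policy: ManagementPolicy | None,
    n_individuals: int,
    seed: int,
    cycles_per_year: int = 12,
) -> MicrosimTrace:
    """Individual-level Monte-Carlo simulation of the same stochastic process.

    Shares the operator sequence with :func:`evolve` but samples state paths,
    so its occupancy estimates are unbiased for the matrix engine's output.
    Reproducible given ``seed``.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    n_cycles = N_YEARS * cycles_per_year
    screening_on = strategy is not None and strategy.mode != "none"
    if screening_on and (test is None or policy is None):
        raise ValueError("screening strategy requires test and policy")
    scr_cycles, visit_cycles = _schedule_cycles(strategy, cycles_per_year, n_cycles)
    cure = params.cure_fraction_resected

    mats = _year_matrices(params, mortality, cycles_per_year)
    cum_year = np.cumsum(mats, axis=2)
    cum_year[:, :, -1] = 1.0
    if screening_on:
        cum_screen = np.cumsum(screen_matrix(test, policy, cure), axis=1)
        cum_screen[:, -1] = 1.0
        cum_visit = np.cumsum(surveillance_matrix(policy, cure), axis=1)
        cum_visit[:, -1] = 1.0

    rng = np.random.default_rng(seed)
    state = np.full(n_individuals, S.NORMAL, dtype=np.int64)
    occ = np.zeros((n_cycles + 1, S.N_STATES))
    occ[0] = np.bincount(state, minlength=S.N_STATES) / n_individuals

    counters = TraceCounters()
    clin_dx_flow = np.zeros((n_cycles, 3))
    onset_flow = np.zeros((n_cycles, 2))
    dead_codes = np.array(S.DEATH_STATES)

    def step(cum: np.ndarray) -> None:
        nonlocal state
        u = rng.random(n_individuals)
        new = state.copy()
        for s in np.unique(state):
            if s in S.DEATH_STATES:
                continue
            idx = np.nonzero(state == s)[0]
            new[idx] = np.searchsorted(cum[s], u[idx], side="right")
        state = new

    for k in range(n_cycles):
        if screening_on:
            if k in visit_cycles:
                step(cum_visit)
            if k in scr_cycles:
                counters.screens_performed += float(
                    (~np.isin(state, dead_codes)).sum()
                ) / n_individuals
                step(cum_screen)
            occ[k] = np.bincount(state, minlength=S.N_STATES) / n_individuals
        prev = state
        step(cum_year[k // cycles_per_year])
        for j, dx in enumerate(S.DX_STATES):
            clin_dx_flow[k, j] = ((state == dx) & (prev != dx)).sum() / n_individuals
        onset_flow[k, 0] = (
            ((state == S.SOLID_PRELOC) & np.isin(prev, (S.NORMAL, S.NORMAL_UNSCREENED))).sum()
            / n_individuals
        )
        onset_flow[k, 1] = (
            (((state == S.CYST_PRELOC) & (prev == S.CYST_HR))
             | ((state == S.SURV_PRELOC) & (prev == S.SURV_HR))).sum()
            / n_individuals
        )
        occ[k + 1] = np.bincount(state, minlength=S.N_STATES) / n_individuals

    for key, j in (("localized", 0), ("regional", 1), ("distant", 2)):
        counters.clinical_diagnoses[key] = clin_dx_flow[:, j].sum()
    counters.deaths["pac"] = occ[-1, S.DEATH_PAC]
    counters.deaths["other"] = occ[-1, S.DEATH_OTHER]
    counters.deaths["surgery"] = occ[-1, S.DEATH_SURGERY]

    return MicrosimTrace(
        occ, cycles_per_year, counters, clin_dx_flow, onset_flow,
        n_individuals=n_individuals, seed=seed,
    )


def lifetime_pac_incidence(trace: CohortTrace) -> float:
    """Cumulative probability of ever developing detected PAC.

    Counts clinical diagnoses at any stage plus cancers found by screening or
    surveillance (which never pass through a diagnosed state).
    """
    c = trace.counters
    total = (
        sum(c.clinical_diagnoses.values())
        + c.screen_detections["solid_pac"]
        + c.screen_detections["cyst_pac"]
        + c.screen_detections["surveillance_pac"]
    )
    return float(min(max(total, 0.0), 1.0))
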