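"""Fit natural-history parameters to registry-style targets.

The unscreened model is summarized by the same quantities a cancer registry
reports: clinical-diagnosis incidence per 100,000 person-years in 5-year age
bands, the stage distribution at diagnosis, the fraction of cancers arising
via the cystic pathway, and 5-year survival by stage.  Calibration minimizes a
weighted sum of squared relative deviations with a derivative-free simplex
search over transformed (log/logit) parameters; diagnosed-state death
probabilities are recovered in closed form from the stage-survival targets.

Risk-scaled cohorts (relative risk ``rr`` versus the general population) are
re-calibrated against targets with incidence multiplied by ``rr`` — and an
explicit lifetime-incidence component, since under competing mortality
matching age-band rates alone does not pin the cumulative-incidence ratio.
Only the onset schedules are re-fitted, so stage mix and pathway split are
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.optimize

from .natural_history import (
    CohortTrace,
    NaturalHistoryParams,
    evolve,
    lifetime_pac_incidence,
)

__all__ = [
    "AGE_BANDS",
    "CalibrationTargets",
    "CalibrationWeights",
    "CalibrateOptions",
    "CalibrationResult",
    "CalibrationError",
    "predict_targets",
    "loss",
    "calibrate",
    "scale_to_relative_risk",
]

#: (lo, hi, label): 5-year bands 30-84 plus an open 85+ band, registry style.
AGE_BANDS: tuple[tuple[float, float, str], ...] = tuple(
    (float(lo), float(lo + 5), f"{lo}-{lo + 4}") for lo in range(30, 85, 5)
) + ((85.0, 100.0, "85+"),)

STAGES = ("localized", "regional", "distant")


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationTargets:
    """Registry-style summaries the unscreened model must reproduce."""

    incidence: np.ndarray  # per band, annual clinical diagnoses per 100,000
    stage_mix: np.ndarray  # (localized, regional, distant), sums to 1
    cystic_fraction: float
    stage_survival: np.ndarray  # 5-year survival by diagnosed stage
    lifetime_incidence: float | None = None
    band_labels: tuple[str, ...] = tuple(b[2] for b in AGE_BANDS)

    def __post_init__(self) -> None:
        if len(self.incidence) != len(self.band_labels):
            raise ValueError("one incidence value per age band required")
        if np.any(np.asarray(self.incidence) < 0):
            raise ValueError("incidence must be non-negative")
        sm = np.asarray(self.stage_mix, dtype=float)
        if not np.all(np.isnan(sm)) and abs(sm.sum() - 1.0) > 1e-6:
            raise ValueError(f"stage mix must sum to 1, got {sm.sum()}")
        if not np.isnan(self.cystic_fraction) and not 0.0 <= self.cystic_fraction <= 1.0:
            raise ValueError("cystic_fraction must be in [0, 1]")

    @property
    def stage_mix_defined(self) -> bool:
        return not np.any(np.isnan(self.stage_mix))

    def to_frame(self) -> pd.DataFrame:
        rows = [("incidence", lab, v) for lab, v in zip(self.band_labels, self.incidence)]
        rows += [("stage_mix", s, v) for s, v in zip(STAGES, self.stage_mix)]
        rows += [("cystic_fraction", "", self.cystic_fraction)]
        rows += [("stage_survival", s, v) for s, v in zip(STAGES, self.stage_survival)]
        if self.lifetime_incidence is not None:
            rows += [("lifetime_incidence", "", self.lifetime_incidence)]
        return pd.DataFrame(rows, columns=["component", "label", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTargets":
        df = pd.read_csv(path, float_precision="round_trip").fillna({"label": ""})
        inc = df[df.component == "incidence"]
        life = df[df.component == "lifetime_incidence"]
        return cls(
            incidence=inc["value"].to_numpy(),
            stage_mix=df[df.component == "stage_mix"]["value"].to_numpy(),
            cystic_fraction=float(df[df.component == "cystic_fraction"]["value"].iloc[0]),
            stage_survival=df[df.component == "stage_survival"]["value"].to_numpy(),
            lifetime_incidence=float(life["value"].iloc[0]) if len(life) else None,
            band_labels=tuple(inc["label"].astype(str)),
        )


@dataclass(frozen=True)
class CalibrationWeights:
    """Per-component loss weights.  Single-number targets (stage mix, pathway
    split) are up-weighted against the many incidence bands."""

    incidence: float = 1.0
    stage_mix: float = 5.0
    cystic_fraction: float = 5.0
    stage_survival: float = 5.0
    lifetime_incidence: float = 10.0

    def __post_init__(self) -> None:
        for name in ("incidence", "stage_mix", "cystic_fraction", "stage_survival", "lifetime_incidence"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be non-negative")


@dataclass(frozen=True)
class CalibrateOptions:
    max_iter: int = 1500  # function-evaluation budget per start
    tol: float = 1e-3
    seed: int = 0
    n_restarts: int = 0
    free: tuple[str, ...] = ("onset", "progression", "detection")


@dataclass
class CalibrationResult:
    params: NaturalHistoryParams
    loss: float
    converged: bool
    iterations: int
    seed: int
    table: pd.DataFrame

    def to_json_dict(self) -> dict:
        from .io import params_to_dict

        return {
            "loss": self.loss,
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "seed": int(self.seed),
            "params": params_to_dict(self.params),
            "table": self.table.to_dict(orient="records"),
        }


def predict_targets(
    params: NaturalHistoryParams,
    mortality,
    cycles_per_year: int = 12,
    trace: CohortTrace | None = None,
) -> CalibrationTargets:
    """Registry-style summaries of the unscreened model.

    Incidence and stage mix come from clinical-diagnosis flows of a full
    unscreened run; 5-year stage survival comes from the diagnosed-state
    hazards in closed form.  With zero onset, stage mix and cystic fraction
    are undefined and returned as NaN.
    """
    if trace is None:
        trace = evolve(params, mortality, strategy=None, cycles_per_year=cycles_per_year)
    cpy = trace.cycles_per_year
    ages = trace.ages[:-1]  # age at start of each cycle
    alive = trace.alive[:-1]
    dx_total_per_cycle = trace.clin_dx_flow.sum(axis=1)

    incidence = np.zeros(len(AGE_BANDS))
    for i, (lo, hi, _) in enumerate(AGE_BANDS):
        in_band = (ages >= lo) & (ages < hi)
        py = alive[in_band].sum() / cpy
        flow = dx_total_per_cycle[in_band].sum()
        incidence[i] = 1e5 * flow / py if py > 0 else 0.0

    dx_by_stage = trace.clin_dx_flow.sum(axis=0)
    total_dx = dx_by_stage.sum()
    stage_mix = dx_by_stage / total_dx if total_dx > 0 else np.full(3, np.nan)

    onsets = trace.onset_flow.sum(axis=0)
    cystic_fraction = onsets[1] / onsets.sum() if onsets.sum() > 0 else float("nan")

    n5 = 5 * cpy
    stage_survival = np.array(
        [
            (1.0 - params.surv_dx_loc) ** n5,
            (1.0 - params.surv_dx_reg) ** n5,
            (1.0 - params.surv_dx_dist) ** n5,
        ]
    )
    return CalibrationTargets(
        incidence=incidence,
        stage_mix=stage_mix,
        cystic_fraction=cystic_fraction,
        stage_survival=stage_survival,
        lifetime_incidence=lifetime_pac_incidence(trace),
    )


def _component_terms(predicted: CalibrationTargets, targets: CalibrationTargets,
                     weights: CalibrationWeights):
    """(weight, predicted, target) triples, one per scalar component."""
    terms = []
    for p, t in zip(predicted.incidence, targets.incidence):
        terms.append((weights.incidence, p, t))
    if targets.stage_mix_defined:
        pm = np.nan_to_num(np.asarray(predicted.stage_mix, dtype=float))
        for p, t in zip(pm, targets.stage_mix):
            terms.append((weights.stage_mix, p, t))
    if not np.isnan(targets.cystic_fraction):
        p = predicted.cystic_fraction
        terms.append((weights.cystic_fraction, 0.0 if np.isnan(p) else p, targets.cystic_fraction))
    for p, t in zip(predicted.stage_survival, targets.stage_survival):
        terms.append((weights.stage_survival, p, t))
    if targets.lifetime_incidence is not None and predicted.lifetime_incidence is not None:
        terms.append((weights.lifetime_incidence, predicted.lifetime_incidence, targets.lifetime_incidence))
    return terms


def loss(
    predicted: CalibrationTargets,
    targets: CalibrationTargets,
    weights: CalibrationWeights | None = None,
) -> float:
    """Weighted sum of squared relative deviations (absolute where the target
    is zero).  Zero iff every predicted component equals its target."""
    weights = weights or CalibrationWeights()
    total = 0.0
    for w, p, t in _component_terms(predicted, targets, weights):
        dev = (p - t) / t if t != 0 else (p - t)
        total += w * dev * dev
    return float(total)


_LOGIT_EPS = 1e-9


def _logit(p: float) -> float:
    p = min(max(p, _LOGIT_EPS), 1.0 - _LOGIT_EPS)
    return float(np.log(p / (1.0 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


_PROGRESSION = ("prog_lr_hr", "prog_hr_pac", "prog_loc_reg", "prog_reg_dist")
_DETECTION = ("detect_clin_loc", "detect_clin_reg", "detect_clin_dist")


def _pack(initial: NaturalHistoryParams, free: tuple[str, ...]) -> np.ndarray:
    x = []
    if "onset" in free:
        x += [0.0, 0.0]  # log multipliers on the initial onset schedules
    if "progression" in free:
        x += [_logit(getattr(initial, n)) for n in _PROGRESSION]
    if "detection" in free:
        x += [_logit(getattr(initial, n)) for n in _DETECTION]
    return np.array(x)


def _unpack(
    x: np.ndarray,
    initial: NaturalHistoryParams,
    free: tuple[str, ...],
    surv: np.ndarray,
) -> NaturalHistoryParams:
    i = 0
    kwargs: dict = {}
    if "onset" in free:
        kwargs["onset_solid"] = initial.onset_solid.scaled(float(np.exp(x[i])))
        kwargs["onset_cyst"] = initial.onset_cyst.scaled(float(np.exp(x[i + 1])))
        i += 2
        for sched in ("onset_solid", "onset_cyst"):
            if any(v > 1.0 for v in kwargs[sched].values):
                raise CalibrationError(
                    f"{sched} multiplier pushes a per-cycle probability above 1; "
                    "use a finer cycle length"
                )
    if "progression" in free:
        for n in _PROGRESSION:
            kwargs[n] = _expit(x[i])
            i += 1
    if "detection" in free:
        vals = [_expit(x[i + j]) for j in range(3)]
        i += 3
        vals[2] = max(vals[2], vals[0])  # enforce detect_clin_dist >= detect_clin_loc
        kwargs.update(dict(zip(_DETECTION, vals)))
    kwargs.update(surv_dx_loc=surv[0], surv_dx_reg=surv[1], surv_dx_dist=surv[2])
    return initial.replace(**kwargs)


def _surv_from_targets(targets: CalibrationTargets, cycles_per_year: int) -> np.ndarray:
    """Invert 5-year stage survival to per-cycle death probabilities."""
    n5 = 5 * cycles_per_year
    s5 = np.clip(np.asarray(targets.stage_survival, dtype=float), 1e-12, 1.0)
    q = 1.0 - s5 ** (1.0 / n5)
    return np.maximum.accumulate(q)  # guard monotonicity loc <= reg <= dist


def calibrate(
    initial: NaturalHistoryParams,
    targets: CalibrationTargets,
    weights: CalibrationWeights | None = None,
    options: CalibrateOptions | None = None,
    mortality=None,
    cycles_per_year: int = 12,
) -> CalibrationResult:
    """Simplex search for parameters reproducing the targets.

    Deterministic given ``options.seed``; the final loss never exceeds the
    loss at ``initial``.  ``converged`` is True iff the final loss is below
    ``options.tol``.
    """
    if mortality is None:
        raise ValueError("calibrate requires the mortality schedule the targets refer to")
    weights = weights or CalibrationWeights()
    options = options or CalibrateOptions()
    surv = _surv_from_targets(targets, cycles_per_year)

    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        params = _unpack(x, initial, options.free, surv)
        predicted = predict_targets(params, mortality, cycles_per_year)
        val = loss(predicted, targets, weights)
        if not np.isfinite(val):
            raise CalibrationError(f"non-finite loss at parameters {params}")
        return val

    x0 = _pack(initial, options.free)
    rng = np.random.default_rng(options.seed)
    starts = [x0] + [x0 + rng.normal(0.0, 0.25, size=x0.shape) for _ in range(options.n_restarts)]

    best_x, best_val = x0, objective(x0)
    initial_val = best_val
    for xs in starts:
        res = scipy.optimize.minimize(
            objective,
            xs,
            method="Nelder-Mead",
            options={
                "maxfev": options.max_iter,
                "xatol": 1e-4,
                "fatol": options.tol * 1e-3,
                "adaptive": True,
            },
        )
        if res.fun < best_val:
            best_x, best_val = res.x, res.fun
    # never worse than the starting point
    if best_val > initial_val:
        best_x, best_val = x0, initial_val

    params = _unpack(best_x, initial, options.free, surv)
    predicted = predict_targets(params, mortality, cycles_per_year)
    table = targets.to_frame().rename(columns={"value": "target"})
    table["predicted"] = predicted.to_frame()["value"].reindex(table.index)
    return CalibrationResult(
        params=params,
        loss=best_val,
        converged=bool(best_val < options.tol),
        iterations=n_eval,
        seed=options.seed,
        table=table,
    )


def scale_to_relative_risk(
    base_params: NaturalHistoryParams,
    rr: float,
    base_targets: CalibrationTargets,
    mortality,
    options: CalibrateOptions | None = None,
    weights: CalibrationWeights | None = None,
    cycles_per_year: int = 12,
) -> NaturalHistoryParams:
    """Re-calibrate the model for a cohort at ``rr`` times general-population risk.

    Builds scaled targets (incidence and lifetime incidence multiplied by
    ``rr``; stage mix, pathway split and stage survival unchanged) and re-fits
    the onset schedules starting from the base schedules pre-multiplied by
    ``rr``.  After the weighted fit, a final scalar root-find on an overall
    onset multiplier pins the lifetime incidence to exactly ``rr`` times the
    base value: under competing mortality the band rates and the cumulative
    incidence cannot both scale by ``rr``, and the lifetime ratio is the
    quantity the risk factor is defined on (band rates then overshoot ``rr``
    at high risk; see the methods note).
    """
    if rr < 1.0:
        raise ValueError(f"relative risk must be >= 1, got {rr}")
    if base_targets.lifetime_incidence is None:
        raise ValueError("base targets must carry lifetime_incidence for risk scaling")
    initial = base_params.replace(
        onset_solid=base_params.onset_solid.scaled(rr),
        onset_cyst=base_params.onset_cyst.scaled(rr),
    )
    for sched in (initial.onset_solid, initial.onset_cyst):
        if any(v > 1.0 for v in sched.values):
            raise ValueError(
                f"relative risk {rr} pushes a per-cycle onset probability above 1; "
                "use a finer cycle length"
            )
    scaled = replace(
        base_targets,
        incidence=np.asarray(base_targets.incidence) * rr,
        lifetime_incidence=base_targets.lifetime_incidence * rr,
    )
    options = options or CalibrateOptions(max_iter=400, free=("onset",))
    options = replace(options, free=("onset",))
    weights = weights or CalibrationWeights(lifetime_incidence=50.0)
    result = calibrate(
        initial, scaled, weights=weights, options=options,
        mortality=mortality, cycles_per_year=cycles_per_year,
    )
    fitted = result.params

    target_lifetime = scaled.lifetime_incidence

    def lifetime_err(log_m: float) -> float:
        p = fitted.replace(
            onset_solid=fitted.onset_solid.scaled(float(np.exp(log_m))),
            onset_cyst=fitted.onset_cyst.scaled(float(np.exp(log_m))),
        )
        pred = predict_targets(p, mortality, cycles_per_year)
        return pred.lifetime_incidence - target_lifetime

    log_m = scipy.optimize.brentq(lifetime_err, -2.0, 2.0, xtol=1e-10)
    m = float(np.exp(log_m))
    return fitted.replace(
        onset_solid=fitted.onset_solid.scaled(m),
        onset_cyst=fitted.onset_cyst.scaled(m),
    )
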