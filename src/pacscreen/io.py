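"""Serialization of fixtures, parameters and reports (CSV/YAML/JSON)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .calibration import CalibrationTargets
from .competing_mortality import (
    AdjustedMortalitySchedule,
    CancerIncidenceSchedule,
    LifeTable,
    RelativeSurvivalCurve,
)
from .natural_history import AgeBandSchedule, NaturalHistoryParams
from .screening import ManagementPolicy, ScreeningStrategy, StudyCounts, TestPerformance
from .synthetic_data import FixtureBundle

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "strategy_from_dict",
    "write_fixture",
    "read_fixture",
    "directory_hash",
]

_FIXTURE_FILES = (
    "life_table.csv",
    "incidence_breast.csv",
    "incidence_ovarian.csv",
    "relsurv_breast.csv",
    "relsurv_ovarian.csv",
    "mortality_adjusted.csv",
    "truth_params.yaml",
    "targets.csv",
    "studies.csv",
    "fixture.yaml",
)


def params_to_dict(p: NaturalHistoryParams) -> dict:
    d = {
        "units": "per-cycle probability (12 cycles/year)",
        "onset_solid": {
            "band_start_ages": list(p.onset_solid.edges),
            "values": [float(v) for v in p.onset_solid.values],
        },
        "onset_cyst": {
            "band_start_ages": list(p.onset_cyst.edges),
            "values": [float(v) for v in p.onset_cyst.values],
        },
    }
    for name in NaturalHistoryParams._SCALARS:
        d[name] = float(getattr(p, name))
    return d


def params_from_dict(d: dict) -> NaturalHistoryParams:
    def sched(key: str) -> AgeBandSchedule:
        s = d[key]
        return AgeBandSchedule(tuple(s["band_start_ages"]), tuple(s["values"]))

    scalars = {name: float(d[name]) for name in NaturalHistoryParams._SCALARS}
    return NaturalHistoryParams(onset_solid=sched("onset_solid"), onset_cyst=sched("onset_cyst"), **scalars)


def strategy_from_dict(d: dict) -> ScreeningStrategy:
    return ScreeningStrategy(
        mode=d.get("mode", "none"),
        start_age=float(d.get("start_age", 50.0)),
        stop_age=float(d.get("stop_age", d.get("start_age", 80.0))),
        interval_years=float(d.get("interval_years", 1.0)),
    )


def write_fixture(bundle: FixtureBundle, out_dir) -> Path:
    """Write a fixture directory; re-reading it reproduces the bundle bit-exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.life_table.to_csv(out / "life_table.csv")
    bundle.breast_incidence.to_csv(out / "incidence_breast.csv")
    bundle.ovarian_incidence.to_csv(out / "incidence_ovarian.csv")
    bundle.breast_relsurv.to_csv(out / "relsurv_breast.csv")
    bundle.ovarian_relsurv.to_csv(out / "relsurv_ovarian.csv")
    bundle.mortality_adjusted.to_csv(out / "mortality_adjusted.csv")
    bundle.targets.to_csv(out / "targets.csv")
    bundle.studies_frame().to_csv(out / "studies.csv", index=False)
    with open(out / "truth_params.yaml", "w") as fh:
        yaml.safe_dump(params_to_dict(bundle.truth_params), fh, sort_keys=True)
    meta = {
        "seed": int(bundle.seed),
        "cohorts": {k: float(v) for k, v in bundle.cohorts.items()},
        "test": {
            "sensitivity": float(bundle.test.sensitivity),
            "specificity": float(bundle.test.specificity),
        },
        "policy": {
            "surgical_mortality": float(bundle.policy.surgical_mortality),
            "surveillance_years": int(bundle.policy.surveillance_years),
            "high_risk_fraction": float(bundle.policy.high_risk_fraction),
            "resume_screening_after_fp": bool(bundle.policy.resume_screening_after_fp),
        },
    }
    with open(out / "fixture.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    manifest = {"hash": directory_hash(out), "seed": int(bundle.seed)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def read_fixture(fixture_dir) -> FixtureBundle:
    from .competing_mortality import baseline_schedule

    d = Path(fixture_dir)
    life = LifeTable.from_csv(d / "life_table.csv")
    with open(d / "fixture.yaml") as fh:
        meta = yaml.safe_load(fh)
    with open(d / "truth_params.yaml") as fh:
        truth = params_from_dict(yaml.safe_load(fh))
    studies_df = pd.read_csv(d / "studies.csv", float_precision="round_trip")
    studies = [
        StudyCounts(str(r.study_id), int(r.tp), int(r.fn), int(r.tn), int(r.fp))
        for r in studies_df.itertuples()
    ]
    return FixtureBundle(
        life_table=life,
        breast_incidence=CancerIncidenceSchedule.from_csv(d / "incidence_breast.csv", "breast"),
        ovarian_incidence=CancerIncidenceSchedule.from_csv(d / "incidence_ovarian.csv", "ovarian"),
        breast_relsurv=RelativeSurvivalCurve.from_csv(d / "relsurv_breast.csv", "breast"),
        ovarian_relsurv=RelativeSurvivalCurve.from_csv(d / "relsurv_ovarian.csv", "ovarian"),
        mortality_baseline=baseline_schedule(life),
        mortality_adjusted=AdjustedMortalitySchedule.from_csv(
            d / "mortality_adjusted.csv", provenance="brca2-adjusted"
        ),
        truth_params=truth,
        targets=CalibrationTargets.from_csv(d / "targets.csv"),
        cohorts={k: float(v) for k, v in meta["cohorts"].items()},
        test=TestPerformance(**meta["test"]),
        policy=ManagementPolicy(**meta["policy"]),
        studies=studies,
        seed=int(meta["seed"]),
    )


def directory_hash(path) -> str:
    """SHA-256 over the fixture files' bytes, in a fixed order."""
    h = hashlib.sha256()
    for name in _FIXTURE_FILES:
        p = Path(path) / name
        if p.exists():
            h.update(name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
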