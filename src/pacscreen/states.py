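"""Health-state space for the pancreatic adenocarcinoma (PAC) natural-history model.

The model distinguishes two routes to invasive cancer: a *solid* pathway whose
precursors (PanIN lesions) are not detectable by imaging, and a *cystic* pathway
(predominantly IPMN) whose precursor cysts are screen-detectable.  Undetected
invasive cancer progresses through SEER historic stages (localized, regional,
distant) until it presents clinically; diagnosed disease carries stage-specific
mortality.  Screen-detected low-risk cysts enter a ten-year annual surveillance
programme; high-risk cysts and screen-detected localized cancers go to surgery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "STATES",
    "IDX",
    "N_STATES",
    "HealthStateSpace",
    "STATE_SPACE",
]

_SURVEILLANCE_YEARS = 10

STATES: tuple[str, ...] = (
    "Normal",
    "Normal_Unscreened",
    "Solid_PreLocalized",
    "Solid_PreRegional",
    "Solid_PreDistant",
    "Cyst_LowRisk",
    "Cyst_HighRisk",
    "Cyst_PreLocalized",
    *[f"Surveillance_Y{k}" for k in range(1, _SURVEILLANCE_YEARS + 1)],
    "Surv_HighRisk",
    "Surv_PreLocalized",
    "Dx_Localized",
    "Dx_Regional",
    "Dx_Distant",
    "PostSurgery_Localized",
    "PostSurgery_Cured",
    "Death_PAC",
    "Death_Other",
    "Death_Surgery",
)

IDX: dict[str, int] = {name: i for i, name in enumerate(STATES)}
N_STATES: int = len(STATES)

# Short index aliases used throughout the engine.
NORMAL = IDX["Normal"]
NORMAL_UNSCREENED = IDX["Normal_Unscreened"]
SOLID_PRELOC = IDX["Solid_PreLocalized"]
SOLID_PREREG = IDX["Solid_PreRegional"]
SOLID_PREDIST = IDX["Solid_PreDistant"]
CYST_LR = IDX["Cyst_LowRisk"]
CYST_HR = IDX["Cyst_HighRisk"]
CYST_PRELOC = IDX["Cyst_PreLocalized"]
SURVEIL = tuple(IDX[f"Surveillance_Y{k}"] for k in range(1, _SURVEILLANCE_YEARS + 1))
SURV_HR = IDX["Surv_HighRisk"]
SURV_PRELOC = IDX["Surv_PreLocalized"]
DX_LOC = IDX["Dx_Localized"]
DX_REG = IDX["Dx_Regional"]
DX_DIST = IDX["Dx_Distant"]
POSTSURG_LOC = IDX["PostSurgery_Localized"]
POSTSURG_CURED = IDX["PostSurgery_Cured"]
DEATH_PAC = IDX["Death_PAC"]
DEATH_OTHER = IDX["Death_Other"]
DEATH_SURGERY = IDX["Death_Surgery"]

DEATH_STATES = (DEATH_PAC, DEATH_OTHER, DEATH_SURGERY)
ALIVE_STATES = tuple(i for i in range(N_STATES) if i not in DEATH_STATES)
DX_STATES = (DX_LOC, DX_REG, DX_DIST)

#: states a screen can act on (everything else passes through unchanged)
SCREENABLE = (NORMAL, SOLID_PRELOC, CYST_LR, CYST_HR, CYST_PRELOC)

_PATHWAY = {
    "Solid_PreLocalized": "solid",
    "Solid_PreRegional": "solid",
    "Solid_PreDistant": "solid",
    "Cyst_LowRisk": "cystic",
    "Cyst_HighRisk": "cystic",
    "Cyst_PreLocalized": "cystic",
    "Surv_HighRisk": "cystic",
    "Surv_PreLocalized": "cystic",
    **{f"Surveillance_Y{k}": "cystic" for k in range(1, _SURVEILLANCE_YEARS + 1)},
}

_DETECTABLE = {
    "Solid_PreLocalized",
    "Cyst_LowRisk",
    "Cyst_HighRisk",
    "Cyst_PreLocalized",
}


@dataclass(frozen=True)
class HealthStateSpace:
    """Ordered state identifiers with absorbing/pathway/detectability annotations.

    ``pathway_tag`` is ``"none"`` for states outside both carcinogenesis
    pathways; ``detectability_tag`` marks the states a screening test can find.
    """

    states: tuple[str, ...]
    absorbing: frozenset[str]
    pathway_tag: dict[str, str] = field(repr=False)
    detectability_tag: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("state identifiers must be unique")
        missing = self.absorbing - set(self.states)
        if missing:
            raise ValueError(f"absorbing states not in state list: {sorted(missing)}")

    def index(self, name: str) -> int:
        return self.states.index(name)

    def is_absorbing(self, name: str) -> bool:
        return name in self.absorbing


STATE_SPACE = HealthStateSpace(
    states=STATES,
    absorbing=frozenset({"Death_PAC", "Death_Other", "Death_Surgery"}),
    pathway_tag={s: _PATHWAY.get(s, "none") for s in STATES},
    detectability_tag={
        s: ("screen-detectable" if s in _DETECTABLE else "not") for s in STATES
    },
)
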