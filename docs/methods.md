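# Methods

## Model structure

`pacscreen` is a deterministic Markov cohort model. A cohort enters the
`Normal` state at age 20 and is propagated in monthly cycles (12 cycles/year)
to age 100. The state space (`pacscreen.states`) has 28 states:

- **Solid pathway** (~90% of PAC): `Normal → Solid_PreLocalized →
  Solid_PreRegional → Solid_PreDistant`, each preclinical stage also able to
  present clinically (`Dx_Localized/Regional/Distant`). Solid precursors
  (PanIN) are collapsed into onset because they are not screen-detectable.
- **Cystic pathway** (~10%, IPMN-type): `Normal → Cyst_LowRisk →
  Cyst_HighRisk → Cyst_PreLocalized`; cystic cancers merge into the solid
  preclinical chain past localized stage (the stage machinery exists once;
  pathway attribution is done on onset flows).
- **Surveillance**: screen-detected low-risk cysts occupy `Surveillance_Y1…Y10`
  with monthly progression risk into `Surv_HighRisk`/`Surv_PreLocalized`;
  annual visits detect progression with probability 1 and trigger surgery;
  after ten clean years the cyst returns to the undetected pool.
- **Post-surgery**: resected localized cancers split once, at surgery, into
  `PostSurgery_Cured` (no further cancer hazard) and `PostSurgery_Localized`
  (localized diagnosed-stage mortality), by `cure_fraction_resected`.
- **Absorbing**: `Death_PAC`, `Death_Other`, `Death_Surgery`.

Within a cycle the event order is fixed: (1) scheduled surveillance visit,
(2) scheduled screen, (3) natural-history transition, which itself applies
other-cause death first and disease events (mutually exclusive) to the
survivors. The fixed order makes the row-stochastic matrix, the enumeration
oracle used in tests, and the microsimulator all well-defined and mutually
consistent.

Two engines share the same operator sequence: `evolve` (exact matrix
propagation of the occupancy distribution) and `microsimulate` (seeded
individual-level sampling). The microsimulator is the independent oracle: its
occupancy estimates are unbiased for `evolve`'s output, and the test suite
checks agreement at ages 50/65/80 within 3 Monte-Carlo standard errors
(plus a 3/n cushion so states with expected count below one do not trigger
spurious Poisson-tail failures).

## Competing mortality (BRCA2 adjustment)

Carrier excess breast/ovarian incidence is convolved with the
cancer-attributable annual death mass `m(t) = RS(t) − RS(t+1)` of a
relative-survival curve and added to the base life table, capped at 1.
Only the *excess* over general-population incidence is added (the base table
already contains general-population cancer deaths). Beyond the last
relative-survival point, `m = 0` (warning emitted). PAC deaths are *not*
removed from the base table; at ~1.3% lifetime risk the double count is
negligible. The cohort is treated as all-female by default; a male profile is
a matter of supplying different incidence schedules. Annual probabilities are
subdivided to monthly ones by constant hazard: `1 − (1 − q)^(1/12)`.

## Screening semantics

Sensitivity applies to every detectable lesion (localized cancer in either
pathway, low- and high-risk cysts). Specificity enters twice: healthy
patients are misread as having PAC with probability `1 − specificity`
(→ surgery, the dominant harm), and *detected* low-risk cysts are misread as
high-risk with the same probability (→ surgery instead of surveillance).
Healthy patients are never misread as having a cyst. Results are independent
between screens, so false positives accumulate across repeat examinations —
with specificity 0.97, 31 annual screens give ≈ 1 − 0.97³¹ ≈ 60% of
ever-screened healthy person-mass a false-positive surgery at some point.
Every resection carries the same surgical mortality (default 1%).
Survivors of false-positive surgery return to `Normal` and remain
screen-eligible (`resume_screening_after_fp=True`; the `False` setting parks
them in a screen-exempt healthy state, which exempts only the healthy state —
subsequent disease re-enters the screened pool, a known simplification).
`ManagementPolicy.high_risk_fraction` (0.10) is carried as configuration but
is informational here: the explicit cyst states determine the high-risk share
endogenously (~12% of detectable cyst mass at age 50 on the default fixture,
consistent with the 0.10 anchor).

Surveillance visits are scheduled annually from the *strategy start age*;
for fractional screening intervals an enrolee's first surveillance year can
therefore be shorter than 12 months (documented approximation).

## Calibration

`predict_targets` summarizes an unscreened run as: clinical-diagnosis
incidence per 100,000 person-years in 5-year age bands (30–84 plus 85+),
stage mix at diagnosis, cystic-pathway share of cancer onsets, 5-year stage
survival (closed form from the diagnosed-state hazards), and lifetime
incidence. The loss is a weighted sum of squared relative deviations
(absolute where a target is zero), weights 1 per incidence band and 5 for
each single-number component (stage mix, cystic fraction, stage survival) —
single numbers would otherwise be drowned by twelve bands — and 10 for
lifetime incidence.

`calibrate` runs Nelder–Mead over transformed parameters (log onset-schedule
multipliers, logit scalars) with optional seeded restarts; diagnosed-state
death probabilities are inverted in closed form from the stage-survival
targets. Onset multipliers are scalars on the band shape, so the age *shape*
of onset is treated as structural and only its level is fitted; this keeps
the search 9-dimensional and is sufficient for the recovery contract
(lifetime incidence within 2%, stage mix within 0.02 from a ±25% perturbed
start).

**Risk scaling.** For a cohort at relative risk `rr`, targets are scaled
(incidence × rr, lifetime incidence × rr, everything else unchanged) and only
the onset schedules are re-fitted. Under competing mortality the band rates
and the cumulative lifetime incidence cannot both scale by `rr` (PAC deaths
deplete person-years at high risk), so after the weighted fit a scalar
root-find on an overall onset multiplier pins the lifetime-incidence ratio to
exactly `rr` — the quantity the published relative risks describe. Band
rates consequently overshoot `rr` × base at high risk (~20% at rr = 32).

## The synthetic world

`synthetic_data.default_fixture` generates every external input with known
ground truth. Stated values: lifetime PAC risk 1.3%, cystic share 10%, MRI
sensitivity 0.56 / specificity 0.97, surgical mortality 1%, cohort relative
risks 3.5/4.5/6.4/32.0, surveillance 10 years. Chosen-once defaults where no
value is stated, with rationale:

| Quantity | Default | Why |
|---|---|---|
| Life table | Gompertz–Makeham, q(a)=2.5e-4·e^(0.088(a−20))+4e-4 | US-like all-cause shape; LE past 20 ≈ 58 y |
| Breast (carrier/genpop lifetime) | 0.45 / 0.12, peak 50, σ 13 | BRCA2 carrier literature range |
| Ovarian (carrier/genpop) | 0.15 / 0.013, peak 60, σ 11 | BRCA2 carrier literature range |
| Relative-survival decay | e^(−0.021t) breast, e^(−0.16t) ovarian | ≈ 90% / 45% 5-y relative survival |
| Onset age shape | e^(0.075·(age−30)) per 5-y band, flat 85+ | registry-like exponential rise |
| Localized / regional preclinical sojourn | 18 / 12 months mean | short preclinical window consistent with PAC aggressiveness |
| Cyst progression | low→high 2%/y; high→invasive 15%/y | slow benign pool, high-risk lesions dangerous |
| Stage mix at diagnosis | 0.10 / 0.30 / 0.60 | registry-like PAC stage distribution |
| 5-y stage survival | 0.25 / 0.10 / 0.02 | registry-like PAC survival |
| Cure fraction after resection | 0.20 | anchored to <20% 5-y survival after R0 resection |

A ±2% seeded jitter on progression/detection truth values makes different
fixture seeds produce distinct worlds; two nested scalar root-finds then
re-tune the onset schedules so every seed hits the stated lifetime risk and
cystic share exactly. The generated calibration targets are noise-free (they
are `predict_targets` of the truth), so a green recovery test establishes
identifiability of the summaries, not robustness to registry noise; real
registry data would add sampling error, cohort effects, and stage-coding
drift that this world does not emulate.

## Outcomes and numerics

Life expectancy past 20 is the trapezoid (half-cycle-corrected) integral of
alive occupancy; net benefit is reported in days (365.25/year). No
discounting. Thresholds are located on documented grids (coarse step with a
10× refinement inside each sign-change bracket; defaults 0.02/0.002 for test
characteristics, 0.005/0.0005 for surgical mortality) and reported with
their brackets; every reported threshold re-evaluates to |net days| < 0.5 by
a direct model run. Ties in the optimal start age break toward the younger
age. Occupancy conservation is enforced at 1e-9 every cycle; transition-row
sums are exact to 1e-12. An inert test (sensitivity 0, specificity 1)
reproduces the unscreened trajectory bitwise, so inert net benefit is exactly
zero, not merely small.

## Known limitations

- Benefit and harm levels depend on quantities no registry reports directly
  (preclinical dwell times, benign-cyst pool size, cure fraction). On this
  synthetic world, one-time screening at 50 is marginally net-negative below
  about 5× population risk and the annual-vs-one-time crossover sits near
  10× — the qualitative harm/benefit structure (false-positive harm grows
  with screen count; aggressive screening pays only at high risk) is robust,
  but the precise crossover risk level is world-dependent and should not be
  read as a clinical estimate.
- No individual covariates (sex-specific PAC risk, smoking), no lead-time or
  quality-of-life adjustment, no EUS-first strategies, no costs.
- Diagnosed-state mortality is a constant per-cycle hazard plus a cure
  fraction, not a time-since-diagnosis survival curve.
- Screening past a false-positive exemption, and surveillance-visit phase for
  fractional intervals, are approximated as described above.
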