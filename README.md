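# pacscreen

A Markov cohort (state-transition) simulation of MRI-based screening for
pancreatic adenocarcinoma (PAC) in BRCA2 mutation carriers.

BRCA2 carriers face elevated PAC risk — roughly 3.5× the general population,
and far higher with affected first-degree relatives (FDRs) — but PAC screening
is a knife-edge trade: MRI (± endoscopic-ultrasound confirmation) has modest
sensitivity (~56%) and imperfect specificity (~97%), and a false-positive
result leads to pancreatic surgery with ~1% perioperative mortality.
`pacscreen` quantifies that trade in life-expectancy terms: it evolves a
cohort from age 20 to age 100 through a two-pathway natural-history model of
PAC (solid, ~90% of cancers, with undetectable precursors; cystic/IPMN, ~10%,
with screen-detectable precursor cysts), overlays screening strategies, and
reports the net days of life expectancy gained or lost versus no screening.

## Model sketch

States: healthy → (solid pathway) undetected localized/regional/distant
cancer, or (cystic pathway) low-risk cyst → high-risk cyst → undetected
localized cancer; clinically diagnosed disease by SEER historic stage with
stage-specific mortality; surveillance states for screen-detected low-risk
cysts (10 years, annual visits); post-resection states with a cure fraction;
three absorbing death states (cancer, other causes, surgery).

Per monthly cycle, other-cause death (from a BRCA2-adjusted life table) acts
first; disease transitions act on the survivors. The BRCA2 adjustment adds the
excess of carrier over general-population breast/ovarian incidence, convolved
with the death deficit of a relative-survival curve, to the base life table:

    excess(a) = Σ_d [inc_carrier(d) − inc_genpop(d)] · (RS(a−d) − RS(a−d+1))

Screening applies pathway-specific error semantics: missed localized cancer
and missed cysts are the false negatives; healthy patients misread as having
PAC, and low-risk cysts misread as high-risk, are the false positives that
drive surgical harm. All parameters are calibrated so the unscreened model
reproduces registry-style targets (age-band incidence, stage mix at diagnosis,
cystic-pathway share, stage survival); risk-scaled cohorts are re-calibrated
so lifetime incidence scales by the cohort's relative risk.

No real SEER or life-table data ship with the package: `pacscreen.synthetic_data`
generates a fully synthetic stand-in world with known ground truth
(Gompertz–Makeham life table, ~1.3% baseline lifetime PAC risk, 10% cystic
share), so the entire pipeline runs offline and is testable.

## Worked example

```python
import pacscreen as pk
from pacscreen.outcomes import EvalContext, net_days
from pacscreen.screening import ScreeningStrategy

bundle = pk.default_fixture(seed=1)          # synthetic world, known truth
params = pk.scale_to_relative_risk(          # re-calibrate to rr = 6.4 (2 FDRs)
    bundle.truth_params, 6.4, bundle.targets, bundle.mortality_adjusted
)
ctx = EvalContext(params, bundle.mortality_adjusted, bundle.test, bundle.policy)
print(net_days(ctx, ScreeningStrategy.one_time(50.0)))   # 1.03
print(net_days(ctx, ScreeningStrategy.annual(50.0, 80.0)))  # -6.58
```

On the synthetic world, one-time MRI screening at age 50 for a carrier cohort
at 6.4× population risk gains about **1.0 day** of life expectancy per person,
while *annual* screening from 50–80 **loses about 6.6 days**: the cumulative
false-positive surgeries of 31 screens outweigh the extra cancers caught at a
curable stage. At 32× risk (≥3 FDRs) the ordering flips decisively (+18 days
one-time, +168 days annual) — screening aggressiveness should scale with
risk. The command-line interface exposes the same pipeline
(`pacscreen make-fixture | calibrate | evaluate | sweep`).

Thresholds and sweeps come from `pacscreen.outcomes`: one-way grids over
sensitivity, specificity, surgical mortality, start age, or screening
interval; zero-crossing and strategy-crossover thresholds by bracketed linear
interpolation; and a two-way surgical-mortality × specificity winner map.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full pipeline from scratch — synthetic world generation, pooled
test-performance computation, per-cohort risk re-calibration, and the
net-life-expectancy evaluation of one-time versus annual screening for all
four cohorts — printing the summary table and writing the results JSON.

See `docs/methods.md` for model assumptions, parameter rationale, numerical
choices, and known limitations.
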