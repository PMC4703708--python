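"""Shared fixtures: the synthetic world and risk-scaled cohort parameters."""

import pytest

import pacscreen as pk
from pacscreen.outcomes import EvalContext
from pacscreen.screening import TestPerformance

# a domain class, not a test case
TestPerformance.__test__ = False

FIXTURE_SEED = 20210


@pytest.fixture(scope="session")
def bundle():
    return pk.default_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def mortality(bundle):
    return bundle.mortality_adjusted


@pytest.fixture(scope="session")
def cohort_params(bundle):
    """Natural-history parameters re-calibrated per relative-risk cohort."""
    return {
        label: pk.scale_to_relative_risk(
            bundle.truth_params, rr, bundle.targets, bundle.mortality_adjusted
        )
        for label, rr in bundle.cohorts.items()
    }


@pytest.fixture(scope="session")
def cohort_contexts(bundle, cohort_params):
    return {
        label: EvalContext(
            params, bundle.mortality_adjusted, bundle.test, bundle.policy, label=label
        )
        for label, params in cohort_params.items()
    }


@pytest.fixture(scope="session")
def base_context(bundle):
    """Truth-parameter (general-population-risk) evaluation context."""
    return EvalContext(
        bundle.truth_params, bundle.mortality_adjusted, bundle.test, bundle.policy
    )
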