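"""Shared fixtures: toy models, their knockout strains, and pre-computed
monoculture/co-culture results reused across test modules (batch simulations
are the expensive part, so they are session-scoped)."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from crossfeed.batch_dynamics import simulate_monoculture
from crossfeed.fixtures import (
    chain_condition,
    chain_strains,
    crossfeed_condition,
    crossfeed_strains,
    make_chain_model,
    make_crossfeed_model,
)
from crossfeed.model_io import apply_knockout
from crossfeed.workflows import sweep_knockouts

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


# --------------------------------------------------------------------------- #
# overflow cross-feeding model
# --------------------------------------------------------------------------- #

@pytest.fixture(scope="session")
def crossfeed_model():
    return make_crossfeed_model()


@pytest.fixture(scope="session")
def crossfeed_cond():
    return crossfeed_condition()


@pytest.fixture(scope="session")
def crossfeed_specs():
    return crossfeed_strains()


@pytest.fixture(scope="session")
def crossfeed_mutants(crossfeed_model, crossfeed_specs):
    return {
        name: apply_knockout(crossfeed_model, spec)
        for name, spec in crossfeed_specs.items()
    }


@pytest.fixture(scope="session")
def crossfeed_sweep(crossfeed_model, crossfeed_specs, crossfeed_cond):
    """(table, profiles, endpoints) over the standard strain set."""
    return sweep_knockouts(
        crossfeed_model, list(crossfeed_specs.values()), crossfeed_cond
    )


@pytest.fixture(scope="session")
def provider_trajectory(crossfeed_mutants, crossfeed_cond):
    return simulate_monoculture(
        crossfeed_mutants["provider"], crossfeed_cond, "provider"
    )


@pytest.fixture(scope="session")
def wildtype_trajectory(crossfeed_mutants, crossfeed_cond):
    return simulate_monoculture(
        crossfeed_mutants["wild_type"], crossfeed_cond, "wild_type"
    )


# --------------------------------------------------------------------------- #
# three-strain conversion chain
# --------------------------------------------------------------------------- #

@pytest.fixture(scope="session")
def chain_model():
    return make_chain_model()


@pytest.fixture(scope="session")
def chain_cond():
    return chain_condition()


@pytest.fixture(scope="session")
def chain_specs():
    return chain_strains()


@pytest.fixture(scope="session")
def chain_mutants(chain_model, chain_specs):
    return {
        name: apply_knockout(chain_model, spec)
        for name, spec in chain_specs.items()
    }


@pytest.fixture(scope="session")
def chain_monos(chain_mutants, chain_cond):
    """Monoculture endpoint biomass per chain strain."""
    return {
        name: simulate_monoculture(model, chain_cond, name).endpoint_biomass
        for name, model in chain_mutants.items()
    }
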