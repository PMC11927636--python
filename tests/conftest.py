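import numpy as np
import pytest

import midflux as mf


@pytest.fixture(scope="session")
def model():
    """The shipped fixture network with fixed exchange-rate constraints."""
    return mf.fixture_model()


@pytest.fixture(scope="session")
def tracer():
    return mf.fixture_tracer()


@pytest.fixture(scope="session")
def regimes(model):
    return mf.make_regimes(model)


@pytest.fixture(scope="session")
def vehicle_zero_noise(model, regimes, tracer):
    vehicle, _ = regimes
    return mf.simulate_dataset(model, vehicle, tracer, n_replicates=3, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def vehicle_fit(model, vehicle_zero_noise, tracer):
    """A modest multi-start fit of the zero-noise vehicle dataset (shared)."""
    return mf.fit_fluxes(
        model, vehicle_zero_noise.measurements, tracer, n_starts=40, n_keep=10, seed=3
    )


def simple_chain():
    """S -> A -> P with one balanced intermediate, for bookkeeping tests."""
    mets = [
        mf.Metabolite("S", 1, "substrate"),
        mf.Metabolite("A", 1, "balanced"),
        mf.Metabolite("P", 1, "sink"),
    ]
    rxns = [
        mf.Reaction("r_in", (("S", 1.0),), (("A", 1.0),), (((0, 0),),), lb=0, ub=10),
        mf.Reaction("r_out", (("A", 1.0),), (("P", 1.0),), (((0, 0),),), lb=0, ub=10),
    ]
    return mets, rxns
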