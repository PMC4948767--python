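import pytest

from lineagecalc import build_model
from lineagecalc.airway import (airway_full_model, airway_reduced_model,
                                fig3_params, fig4_params,
                                two_compartment_model)


@pytest.fixture(scope="session")
def immigration_death():
    """One compartment with constant influx and linear removal.

    Equilibrium mean 100; the exact stationary law is Poisson, so the
    stationary variance equals the mean — a closed-form oracle for the
    covariance machinery and the simulator.
    """
    return build_model({
        "compartments": [{"name": "cell", "equilibrium": 100}],
        "processes": [
            {"name": "in", "increments": [1], "rate": 10.0},
            {"name": "out", "increments": [-1], "rate": 10.0,
             "controls": {"cell": 0.1}, "control_signs": {"cell": "+"}},
        ],
    })


@pytest.fixture(scope="session")
def reduced_model():
    """Reduced airway preset with the recovery-dynamics controls."""
    return airway_reduced_model(fig4_params())


@pytest.fixture(scope="session")
def reduced_fig3_model():
    return airway_reduced_model(fig3_params())


@pytest.fixture(scope="session")
def full_model():
    return airway_full_model()


@pytest.fixture(scope="session")
def two_comp():
    return two_compartment_model()
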