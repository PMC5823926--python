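import warnings

import pytest

from hslpattern.circuitsim import (C6_LEVELS, C12_LEVELS, Condition,
                                   parameter_set, simulate_plate)

warnings.filterwarnings("ignore", message="Covariance of the parameters")


@pytest.fixture(scope="session")
def and_params_250():
    return parameter_set("and_rbs250")


@pytest.fixture(scope="session")
def and_params_500():
    return parameter_set("and_rbs500")


@pytest.fixture(scope="session")
def reporter_params():
    return parameter_set("reporter_best")


def and_layout():
    return [(Condition(c6=a, c12=b), "and_full")
            for a in C6_LEVELS for b in C12_LEVELS]


@pytest.fixture(scope="session")
def noisefree_and_grid(and_params_250):
    """Noise-free full 2D titration plate of the optimized AND circuit."""
    from hslpattern import gatecheck
    ts = simulate_plate(and_params_250, and_layout(), replicates=1, noise=False)
    return gatecheck.grid_from_plate(ts)


@pytest.fixture(scope="session")
def noisy_and_grid(and_params_250):
    from hslpattern import gatecheck
    ts = simulate_plate(and_params_250, and_layout(), replicates=3, seed=42)
    return gatecheck.grid_from_plate(ts)
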