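import pytest
from hypothesis import settings

from irmsim import (
    CrossResistance,
    InsecticideProfile,
    Scenario,
    build_equal_design,
    build_unique_design,
    run_design,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig_profile():
    """The printed worked-example insecticide (both products identical)."""
    return InsecticideProfile(
        h2=0.2028686, psi=0.1730878, x=0.8645515, m=0.2500806, z0=0.0
    )


@pytest.fixture(scope="session")
def fig_scenario():
    """The printed worked-example landscape and schedule."""
    return Scenario(
        coverage=0.6885651, dispersal=0.8844445, beta=10.0, deploy_interval=10
    )


@pytest.fixture(scope="session")
def no_cross():
    return CrossResistance.symmetric(0.0)


@pytest.fixture(scope="session")
def equal_outcomes():
    """Reduced equal-properties design run under all three strategies.

    150 LHS rows crossed with the 11-point cross-resistance grid, two
    starting-resistance levels and two deployment intervals (6600
    simulations per strategy).
    """
    design = build_equal_design(150, seed=5)
    return run_design(design, ("sequence", "rotation", "mixture"))


@pytest.fixture(scope="session")
def unique_outcomes():
    """Reduced unique-properties design run under all four strategies."""
    design = build_unique_design(800, seed=7)
    return run_design(
        design, ("sequence", "rotation", "adaptive_rotation", "mixture")
    )
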