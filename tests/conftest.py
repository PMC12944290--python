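"""Shared fixtures: the efficient-system reference conditions and the
expensive fitted objects, computed once per session."""

import numpy as np
import pytest

from kokwave import (
    DARK_ADAPTED_INIT,
    EFFICIENT_SYSTEM_PARAMS,
    KokParameters,
    SStateDistribution,
    fit_vzad,
    run_recovery_experiment,
    simulate_yields,
)


@pytest.fixture(scope="session")
def reference_params() -> KokParameters:
    """The efficient-system parameter set (α=0.100, β=0.050, γ=0.820,
    δ=0.020, ε=0.010)."""
    return EFFICIENT_SYSTEM_PARAMS


@pytest.fixture(scope="session")
def dark_init() -> SStateDistribution:
    """Canonical dark-adapted start: 75% S1, 25% S0."""
    return DARK_ADAPTED_INIT


@pytest.fixture(scope="session")
def reference_sequence(reference_params, dark_init):
    """Noise-free 20-flash simulation at the reference conditions."""
    return simulate_yields(reference_params, dark_init, 20)


@pytest.fixture(scope="session")
def reference_fit(reference_sequence):
    """Round-trip fit of the noise-free reference simulation."""
    return fit_vzad(reference_sequence)


@pytest.fixture(scope="session")
def recovery_result():
    """Default combined-signal recovery experiment (raw vs EWT fit)."""
    return run_recovery_experiment(seed=1)
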