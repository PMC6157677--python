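import pytest

from clutchsim import HazardModel, validate_params


@pytest.fixture(scope="session")
def defaults():
    """Documented default parameter set (c=1)."""
    return validate_params({})


@pytest.fixture(scope="session")
def no_hazard():
    """Degenerate hazard h = 0: every attempt succeeds."""
    return HazardModel.constant(0.0)


@pytest.fixture(scope="session", autouse=True)
def _warm_kernel():
    """Compile the season kernel once, up front, so timings are per-test."""
    from clutchsim import run_replicates

    run_replicates(validate_params({"T": 30, "t_r": 2, "E_i": 1.0}), n=1, seed=0)
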