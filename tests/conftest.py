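import pytest

from ulvafarm import (
    FarmConfig,
    GrowthParameters,
    PumpSetting,
    ReactorGeometry,
    generate_synthetic_forcing,
    seasonal_spec,
)


@pytest.fixture(scope="session")
def params():
    """Calibrated/default kinetic parameter set."""
    return GrowthParameters()


@pytest.fixture(scope="session")
def geometry():
    return ReactorGeometry()


@pytest.fixture(scope="session")
def pump():
    return PumpSetting()


@pytest.fixture(scope="session")
def spring_forcing():
    """One 14-day spring cycle of synthetic forcing (250 μM upstream N)."""
    start, spec = seasonal_spec("spring")
    return generate_synthetic_forcing(spec, start=start, days=14)


@pytest.fixture(scope="session")
def spring_cfg():
    _, spec = seasonal_spec("spring")
    return FarmConfig(n_reactors=5, N_env0=spec.N_up, N_ext0=None)
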