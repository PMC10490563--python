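import pytest
from hypothesis import HealthCheck, settings

from eisr import AntennaRing, ImagingDomain, PhysicalConfig

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cfg() -> PhysicalConfig:
    """300 MHz free-space configuration (λ = 1 m exactly)."""
    return PhysicalConfig(frequency=300e6)


@pytest.fixture(scope="session")
def small_domain() -> ImagingDomain:
    """Compact grid (0.4 m square, λ/100 cells) for forward-solver tests."""
    return ImagingDomain(extent=(-0.2, 0.2, -0.2, 0.2), cell_size=0.01)


@pytest.fixture(scope="session")
def ring() -> AntennaRing:
    return AntennaRing(radius=10.0, n_transmitters=36, n_receivers=36)
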