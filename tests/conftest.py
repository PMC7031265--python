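import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from phagestats import AliquotSeries


@pytest.fixture
def series_25ul() -> AliquotSeries:
    """The 25 µL presence/absence series: 13 of 18 vessels positive."""
    return AliquotSeries(label="Bluephage", volume=25.0, n_vessels=18, n_positive=13)


@pytest.fixture
def series_10ul_blue() -> AliquotSeries:
    """The 10 µL candidate-method series: 16 of 42 vessels positive."""
    return AliquotSeries(label="Bluephage", volume=10.0, n_vessels=42, n_positive=16)


@pytest.fixture
def series_10ul_iso() -> AliquotSeries:
    """The 10 µL reference-titration series: 17 of 42 vessels positive."""
    return AliquotSeries(label="ISO-DAL", volume=10.0, n_vessels=42, n_positive=17)
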