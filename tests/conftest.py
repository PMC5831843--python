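import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def demo_design():
    """Full-size 7-module, two-donor design on a 300-codon toy CDS."""
    from ggshuffle import synthdata

    return synthdata.make_demo_design(seed=1)


@pytest.fixture(scope="session")
def small_design():
    """Fast 2-module design for unit-level assembly checks."""
    from ggshuffle import synthdata

    return synthdata.make_demo_design(
        seed=7, length_codons=100, k_sites=2, adjacent_pair=False
    )
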