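import pytest

from alertconfide import (
    Tier,
    default_weighting_scheme,
    load_default_registry,
    profile_from_levels,
    uniform_profile,
)


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def scheme(registry):
    return default_weighting_scheme(registry)


@pytest.fixture
def all_high(registry):
    return uniform_profile("high", alert_id="all_high", registry=registry)


@pytest.fixture
def all_low(registry):
    return uniform_profile("low", alert_id="all_low", registry=registry)


@pytest.fixture
def tiered_profile(registry):
    """Essential criteria HIGH, desirable MODERATE, optional LOW."""
    level_by_tier = {Tier.ESSENTIAL: "high", Tier.DESIRABLE: "moderate", Tier.OPTIONAL: "low"}
    return profile_from_levels(
        "tiered", {c.id: level_by_tier[c.tier] for c in registry}
    )
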