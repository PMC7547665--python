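import pytest

from friendlyrivals import PayoffMatrix, capri, enumeration


@pytest.fixture(scope="session")
def m2_report():
    """Full memory-two scan, shared across the session (the module caches
    it, so named-strategy lookups that need the search reuse it too)."""
    return enumeration.scan_memory_two()


@pytest.fixture(scope="session")
def pd_payoffs():
    """The (R, T, S, P) = (3, 4, 0, 1) prisoner's dilemma used for the
    payoff-sampling experiments."""
    return PayoffMatrix(R=3, T=4, S=0, P=1)


@pytest.fixture(scope="session")
def capri_strategy():
    return capri()
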