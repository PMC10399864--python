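import pytest
from hypothesis import HealthCheck, settings

# Property tests must be reproducible run-to-run.
settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def monopartite_candidate():
    from birkit import fixtures

    return fixtures.get("nls_monopartite_candidate")
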