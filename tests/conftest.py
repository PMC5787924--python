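import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundled():
    from ivmr import load_bundled_data

    instruments, panels = load_bundled_data()
    return {s.exposure_name: s for s in instruments}, {p.outcome_name: p for p in panels}


@pytest.fixture(scope="session")
def bundled_report():
    """One shared full-pipeline run on the bundled study data."""
    from ivmr import RunConfig, run_analysis

    return run_analysis(RunConfig())
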