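import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cerna_fixture():
    """Masked implant fixture: 5 strong partners among 236 decoys."""
    from cernet.simulate import build_cerna_fixture

    return build_cerna_fixture(rng_seed=7)


@pytest.fixture(scope="session")
def cerna_targetmap(cerna_fixture):
    from cernet.targets import predict_targets

    return predict_targets(
        cerna_fixture.mirnas, cerna_fixture.transcripts, min_site_type="8mer"
    )


@pytest.fixture(scope="session")
def pipeline_result():
    """One seeded end-to-end run shared by integration checks."""
    from cernet.pipeline import run_pipeline

    return run_pipeline(seed=11)
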