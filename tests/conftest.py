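import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from famvar import SyntheticConfig, generate_callsets  # noqa: E402


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small, fast cohort used by most integration tests.  Depth is
    effectively constant (huge NB dispersion) so the quality gate is a
    no-op and cascade logic can be asserted exactly."""
    return SyntheticConfig(
        n_families=2,
        n_probands=4,
        n_common=120,
        n_family_private_benign=8,
        n_sporadic_deleterious=3,
        n_synonymous_novel=4,
        n_proband_recurrent=6,
        depth_mean=63.0,
        depth_dispersion=1e9,
        seed=20240626,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    return generate_callsets(tiny_cfg)
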