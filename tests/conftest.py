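import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def demo_variants():
    from cardiosplice.demo import rna_confirmed_variants

    return rna_confirmed_variants()


@pytest.fixture(scope="session")
def gene_meta():
    from cardiosplice.simulate import default_gene_meta

    return default_gene_meta()


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared across read-only tests."""
    from cardiosplice.models import Disease
    from cardiosplice.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        seed=42,
        group_sizes={Disease.HCM: 200, Disease.DCM: 60, Disease.ACM: 34,
                     Disease.LQTS: 30},
    )
    return simulate_cohort(cfg)
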