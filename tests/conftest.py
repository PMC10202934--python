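import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_tma_cells():
    """A small TMA cohort (30 cores, 100 cells each) with planted outliers."""
    from oncomir.syndata import SimConfig, gen_tma_cohort

    cfg = SimConfig(
        seed=11,
        n_patients=10,
        cores_per_patient=3,
        cells_per_core_range=(100, 100),
        outlier_fraction=0.03,
    )
    return gen_tma_cohort(cfg)
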