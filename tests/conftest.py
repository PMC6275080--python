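import pytest

from methclass import synthetic_cohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort for fast stage-level tests."""
    cfg = sc.SimulationConfig(
        n_samples_per_class=(10, 20, 20), n_probes=3000, n_genes=400,
        immune_module_size=40, seed=7,
    )
    return sc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the generator's default geometry (50/120/130, 20k probes)."""
    return sc.generate_cohort(sc.SimulationConfig(seed=7))
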