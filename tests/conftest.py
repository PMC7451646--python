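import pytest

from stepsvm.datagen import HierarchyConfig, default_effects, generate_hierarchy


@pytest.fixture(scope="session")
def small_hierarchy():
    """One reduced-scale hierarchical draw (10 hospitals) shared across tests."""
    cfg = HierarchyConfig(n_hospitals=10, doctors_per_hospital=(4, 6),
                          patients_per_doctor=(5, 15), seed=11)
    return generate_hierarchy(cfg, default_effects())


@pytest.fixture(scope="session")
def full_scale_hierarchy():
    """One default (35-hospital) draw; generation is cheap, fits are not."""
    return generate_hierarchy(HierarchyConfig(seed=5), default_effects())
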