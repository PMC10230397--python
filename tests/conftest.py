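import numpy as np
import pytest

from abdovar.synthetic import CohortSimConfig, PhantomSpec


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A child-torso phantom small enough for fast per-test voxel work."""
    return PhantomSpec(
        torso_semiaxes_mm=(60.0, 48.0, 70.0), spacing_mm=3.0, margin_mm=27.0
    )


@pytest.fixture(scope="session")
def tiny_sim_config() -> CohortSimConfig:
    """A 2-patient rendered cohort for pipeline-level tests."""
    return CohortSimConfig.reference_fixture(
        n_patients=2, n_weeks_min=2, n_weeks_max=2, seed=7
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
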