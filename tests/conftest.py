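import numpy as np
import pytest

from netmig import SynthConfig, build_default_atlas, generate_cohort


@pytest.fixture(scope="session")
def atlas():
    return build_default_atlas()


@pytest.fixture(scope="session")
def small_cohort(atlas):
    """A quick null cohort for unit tests (no planted effects)."""
    cfg = SynthConfig(
        n_patients=8, n_controls=6, n_timepoints=60, include_structural=True, seed=123
    )
    return generate_cohort(cfg, atlas)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
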