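import numpy as np
import pytest

from neurofuse import EffectSpec, VolumeTimeSeries, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_volume(rng):
    """A small random 4D volume with a full mask (6x6x6, T=48)."""
    data = rng.standard_normal((6, 6, 6, 48))
    return VolumeTimeSeries(data, tr_seconds=2.0, mask=np.ones((6, 6, 6), bool))


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-effect cohort shared by pipeline-level tests."""
    effect = EffectSpec(
        target_rois={3, 5}, effect_axes=("pet_mean",), effect_size=3.0
    )
    return generate_cohort(
        8, 8, grid_dims=(10, 10, 8), n_rois=8, n_timepoints=60, effect=effect, seed=7
    )
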