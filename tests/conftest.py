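import numpy as np
import pytest

import acetowhite as aw
from acetowhite.datasets import TissueClass


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_kinetics():
    """Default class kinetics with lighting noise and drift switched off."""
    return {
        c: aw.ClassKinetics(theta=k.theta, noise_sd=0.0, drift_amplitude=0.0)
        for c, k in aw.DEFAULT_KINETICS.items()
    }


@pytest.fixture(scope="session")
def default_series():
    """The default 200-case simulated cohort (seed 7), shared across tests."""
    return aw.generate_series(aw.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_binary_pla():
    """PLA-encoded binary dataset from the default cohort (seed 7)."""
    series = aw.generate_series(aw.GeneratorConfig(seed=7))
    raw = aw.series_to_dataset(series)
    from acetowhite.representations import standardize_dataset

    std = standardize_dataset(raw, 10)
    scheme = aw.calibrate_scheme(std.features, aw.uniform_boundaries(180, 12), 5)
    reps = aw.build_representations(raw, 10, scheme)
    return reps["pla"].binarized()


@pytest.fixture
def small_image_config():
    def make(seed=3, jitter_sd=1.5, n_post=40, cls=TissueClass.HSIL):
        return aw.GeneratorConfig(
            class_counts={cls: 1},
            frame_shape=(80, 100),
            jitter_sd=jitter_sd,
            seed=seed,
            n_post=n_post,
        )

    return make
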