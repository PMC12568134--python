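import numpy as np
import pytest

from fallwin import SyntheticConfig, TriaxialTrace, WindowScheme, gen_event_dataset


@pytest.fixture(scope="session")
def default_scheme():
    return WindowScheme()


@pytest.fixture(scope="session")
def small_cfg():
    """A small but class-imbalanced synthetic dataset configuration."""
    return SyntheticConfig(n_subjects=4, falls_per_subject=6,
                           adls_per_subject=24, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return gen_event_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return small_dataset.to_labeled_features()


def random_trace(rng, n=150, rate=50.0, range_g=2.0, subject="S01"):
    samples = np.clip(rng.normal(0, 0.5, size=(n, 3)), -range_g, range_g)
    return TriaxialTrace(samples=samples, rate=rate, range_g=range_g,
                         subject_id=subject)
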