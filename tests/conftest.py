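import numpy as np
import pytest

from mpar import (
    CohortSpec,
    WindowingConfig,
    extract_feature_table,
    generate_cohort,
    segment,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def small_cohort():
    """Six subjects, all ten activities, short bouts — fast but complete."""
    spec = CohortSpec(
        n_subjects=6, activities_per_subject=10, seed=7, duration_range=(10.0, 14.0)
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    cfg = WindowingConfig(window_seconds=1, overlapped=False)
    windows = [w for rec in small_cohort for w in segment(rec, cfg)]
    return extract_feature_table(windows)


def random_window_samples(rng, n=50, scale=1.0):
    """A plausible random signal window: offset + tone + noise."""
    t = np.arange(n) / 50.0
    return (
        rng.normal(0.0, 0.5)
        + rng.uniform(0.1, 1.0) * scale * np.sin(2 * np.pi * rng.uniform(0.5, 20.0) * t)
        + rng.normal(0.0, 0.2 * scale, n)
    )
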