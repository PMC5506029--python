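import numpy as np
import pytest

from leida import ParcelTimeSeries, SyntheticSpec, simulate_cohort


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def inband_ts(rng):
    """Small band-limited multichannel recording (sum of in-band sinusoids)."""
    n, t, tr = 6, 60, 2.0
    time = np.arange(t) * tr
    freqs = rng.uniform(0.02, 0.06, size=n)
    phases = rng.uniform(0, 2 * np.pi, size=n)
    data = np.cos(2 * np.pi * freqs[:, None] * time[None, :] + phases[:, None])
    data += 0.05 * rng.normal(size=(n, t))
    return ParcelTimeSeries("inband", "g", data, tr)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small two-group switching cohort shared by fast integration tests."""
    spec = SyntheticSpec(seed=99, n_subjects_per_group=2, n_frames=120)
    subjects, truth = simulate_cohort(spec)
    return spec, subjects, truth
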