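import numpy as np
import pytest

from eegisc.containers import MONTAGE_10_20_19, MultiSubjectEEG
from eegisc.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort, two videos, short but long enough for filtering."""
    spec = CohortSpec(
        n_healthy=6, n_patient=5, duration=12.0, n_videos=2,
        gain_healthy=1.0, gain_patient=0.4, seed=101,
    )
    videos, truth = generate_cohort(spec)
    return spec, videos, truth


def make_eeg(data, fs=500.0, groups=None, video_id=1):
    """Wrap a raw (N, D, T) array with default metadata."""
    data = np.asarray(data, dtype=float)
    n, d, _ = data.shape
    labels = list(MONTAGE_10_20_19[:d]) if d <= 19 else [f"CH{i}" for i in range(d)]
    return MultiSubjectEEG(
        data=data,
        fs=fs,
        channel_labels=labels,
        subject_ids=[f"S{i}" for i in range(n)],
        groups=groups or ["healthy"] * n,
        video_id=video_id,
    )
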