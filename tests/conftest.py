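import numpy as np
import pytest

from tremorsdh import simulate


@pytest.fixture(scope="session")
def default_cohort():
    """The default 39-recording synthetic cohort (fixed master seed)."""
    manifest, recordings = simulate.simulate_cohort(seed=1)
    return manifest, recordings


@pytest.fixture(scope="session")
def small_recordings():
    """Two recordings per level — cheap input for pipeline-shape tests."""
    recs = []
    for level in (0, 1, 2):
        for i, hand in enumerate(("left", "right")):
            recs.append(
                simulate.simulate_recording(
                    level, hand, seed=100 * level + i, patient_id=f"T{level}{i}"
                )
            )
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
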