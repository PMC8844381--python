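import numpy as np
import pytest

from polarcall.synthetic_embryo import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def small_recording():
    """One small synthetic recording shared by read-only tests."""
    cfg = SynthConfig(size=48, n_z=5, n_frames=12, compaction_frame=4,
                      polarization_frame=6, blastomere_radius=8.0, seed=11)
    return generate_recording(cfg, recording_id="fix_embryo")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
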