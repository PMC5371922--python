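import numpy as np
import pytest

from pcgkit import SynthConfig, denoise, generate_recording, segment_recording


@pytest.fixture(scope="session")
def clean_recording():
    """A noise-free synthetic PCG with its ground truth."""
    cfg = SynthConfig(seed=3, noise_snr_db=np.inf, hr_jitter_pct=0.0)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def segmented(clean_recording):
    """(recording, truth, events, cycles) for a denoised clean recording."""
    rec, truth = clean_recording
    events, cycles = segment_recording(denoise(rec))
    return rec, truth, events, cycles
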