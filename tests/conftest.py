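import numpy as np
import pytest

from eegannot.io import AnnotationInterval, Recording
from eegannot.montage import STANDARD_19


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """2-s, 19-channel random recording at 256 Hz with two annotations."""
    sr = 256.0
    signal = rng.standard_normal((19, int(2 * sr))) * 20e-6
    return Recording(
        subject_id="S000",
        recording_id="S000R00",
        sr=sr,
        channel_names=list(STANDARD_19),
        signal=signal,
        annotations=[
            AnnotationInterval(0.25, 0.3, "artifact"),
            AnnotationInterval(1.5, 0.4, "artifact"),
        ],
    )
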