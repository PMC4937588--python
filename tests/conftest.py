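import numpy as np
import pytest

from pwvkit import WaveformParams, generate_waveform


@pytest.fixture(scope="session")
def default_params():
    """Normal-subject-like waveform: 60 bpm, 400 ml/s peak, foot at 80 ms."""
    return WaveformParams()


@pytest.fixture(scope="session")
def dense_curve(default_params):
    """Default waveform on the dense 0.1 ms grid."""
    return generate_waveform(default_params, 10_000)
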