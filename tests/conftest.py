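import numpy as np
import pytest

from lexstress.aligner import MonophoneAligner
from lexstress.core_io import Waveform
from lexstress.synthgen import generate_corpus


@pytest.fixture(scope="session")
def train_corpus():
    """Labelled training corpus: 150 tokens over a 12-word SW/WS lexicon."""
    return generate_corpus(150, pattern_mix={"SW": 6, "WS": 6}, seed=3)


@pytest.fixture(scope="session")
def trained_aligner(train_corpus):
    X = [t.waveform for t in train_corpus.tokens]
    y = [t.alignment for t in train_corpus.tokens]
    return MonophoneAligner(n_iter=5).fit(X, y)


@pytest.fixture()
def sine_wave():
    def make(freq: float, duration: float = 0.2, rate: int = 16000,
             amplitude: float = 0.5) -> Waveform:
        t = np.arange(int(duration * rate)) / rate
        return Waveform(amplitude * np.sin(2 * np.pi * freq * t), rate)

    return make
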