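import numpy as np
import pandas as pd
import pytest

from ppa_speech.signal_core import Waveform, write_wav
from ppa_speech.synthetic_data import synth_word

RATE = 16000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_words_fixture(tmp_path, word_specs, rate=RATE, name="words"):
    """Concatenate synthetic word tokens into one WAV + annotation CSV.

    ``word_specs``: list of (word, pattern, d1_ms, d2_ms) tuples.
    Returns (wav_path, csv_path).
    """
    pieces, rows = [], []
    offset = 0.0
    for i, (word, pattern, d1, d2) in enumerate(word_specs):
        w, tok = synth_word(d1, d2, seed=100 + i, rate=rate, word=word, pattern=pattern)
        pieces.append(w.samples)
        rows.append(
            {
                "word": word,
                "pattern": pattern,
                "v1_on_s": offset + tok.v1.start,
                "v1_off_s": offset + tok.v1.end,
                "v2_on_s": offset + tok.v2.start,
                "v2_off_s": offset + tok.v2.end,
            }
        )
        offset += w.duration
    wav_path = tmp_path / f"{name}.wav"
    csv_path = tmp_path / f"{name}.csv"
    write_wav(wav_path, Waveform(np.concatenate(pieces), rate))
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return wav_path, csv_path
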