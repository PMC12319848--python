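import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from readrsa.lexicon import Lexicon, PhonemeFeatureTable, WordEntry, load_phoneme_features


@pytest.fixture(scope="session")
def feature_table() -> PhonemeFeatureTable:
    return load_phoneme_features()


@pytest.fixture(scope="session")
def toy_feature_table() -> PhonemeFeatureTable:
    """Four phonemes with 4 binary features each, for exhaustive oracles."""
    return PhonemeFeatureTable(
        {
            "p": np.array([0, 0, 0, 0]),
            "b": np.array([1, 0, 0, 0]),
            "a": np.array([1, 1, 1, 0]),
            "i": np.array([1, 1, 1, 1]),
        }
    )


@pytest.fixture(scope="session")
def toy_lexicon() -> Lexicon:
    """Three words with hand-set transcriptions, embeddings and MFCC tracks."""
    rng = np.random.default_rng(42)

    def mfcc(n_frames: int) -> np.ndarray:
        return rng.standard_normal((n_frames, 3))

    entries = []
    for word, tr in [
        ("salt", ("s", "a", "l", "t")),
        ("banana", ("b", "a", "n", "a", "n", "a")),
        ("record", ("r", "e", "k", "o", "r", "d")),
    ]:
        entries.append(
            WordEntry(
                text=word,
                transcription=tr,
                embedding=rng.standard_normal(8),
                mfcc_by_speaker={"s1": mfcc(24), "s2": mfcc(30)},
            )
        )
    return Lexicon(entries)
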