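"""Word stimuli: lexicon entries, phoneme feature tables, and their file formats.

A lexicon holds the word stimuli of one study: the orthographic form, a
phonemic transcription, a semantic embedding vector, per-speaker MFCC frame
sequences, and the reading condition ("aloud" / "silent") the word was
assigned to for a given participant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("aloud", "silent")

__all__ = [
    "CONDITIONS",
    "WordEntry",
    "Lexicon",
    "PhonemeFeatureTable",
    "load_phoneme_features",
]


@dataclass(frozen=True)
class WordEntry:
    """One word stimulus.

    Parameters
    ----------
    text : str
        Lowercase alphabetic word form, 6-10 letters in the default design.
    transcription : tuple of str
        Phoneme sequence (symbols must appear in the study's feature table).
    embedding : ndarray or None
        Semantic embedding vector; all entries of a lexicon share one dimension.
    mfcc_by_speaker : dict
        speaker id -> (n_frames, n_coeff) array of MFCC frames.
    condition : str
        "aloud", "silent" or "unassigned".
    """

    text: str
    transcription: tuple[str, ...] = ()
    embedding: np.ndarray | None = None
    mfcc_by_speaker: dict[str, np.ndarray] = field(default_factory=dict)
    condition: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.text or not self.text.isalpha():
            raise ValueError(f"word text must be non-empty alphabetic, got {self.text!r}")
        if self.condition not in CONDITIONS + ("unassigned",):
            raise ValueError(f"unknown condition {self.condition!r}")


class Lexicon:
    """Ordered collection of :class:`WordEntry`, indexable by word."""

    def __init__(self, entries: list[WordEntry]):
        words = [e.text for e in entries]
        if len(set(words)) != len(words):
            raise ValueError("duplicate words in lexicon")
        dims = {e.embedding.shape[0] for e in entries if e.embedding is not None}
        if len(dims) > 1:
            raise ValueError(f"embeddings must share one dimension, found {sorted(dims)}")
        self.entries = list(entries)
        self._by_word = {e.text: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, word: str) -> WordEntry:
        return self._by_word[word]

    @property
    def words(self) -> list[str]:
        return [e.text for e in self.entries]

    def subset(self, condition: str) -> "Lexicon":
        """Entries assigned to one reading condition, in lexicon order."""
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return Lexicon([e for e in self.entries if e.condition == condition])

    def with_conditions(self, mapping: dict[str, str]) -> "Lexicon":
        """Return a copy with condition labels taken from ``mapping``."""
        return Lexicon(
            [replace(e, condition=mapping.get(e.text, e.condition)) for e in self.entries]
        )

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "word": self.words,
                "transcription": [" ".join(e.transcription) for e in self.entries],
                "condition": [e.condition for e in self.entries],
            }
        )

    def save(self, directory: str | Path) -> None:
        """Write word table (TSV), embeddings (TSV) and MFCCs (JSON)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "lexicon.tsv", sep="\t", index=False)
        if self.entries and self.entries[0].embedding is not None:
            emb = pd.DataFrame(
                np.stack([e.embedding for e in self.entries]), index=self.words
            )
            emb.to_csv(directory / "embeddings.tsv", sep="\t", header=False)
        mfcc = {
            spk: {e.text: np.asarray(e.mfcc_by_speaker[spk]).tolist() for e in self.entries}
            for spk in (self.entries[0].mfcc_by_speaker if self.entries else {})
        }
        if mfcc:
            (directory / "mfcc.json").write_text(json.dumps(mfcc))

    @classmethod
    def load(cls, directory: str | Path) -> "Lexicon":
        directory = Path(directory)
        table = pd.read_csv(directory / "lexicon.tsv", sep="\t")
        emb_path = directory / "embeddings.tsv"
        embeddings: dict[str, np.ndarray] = {}
        if emb_path.exists():
            emb = pd.read_csv(emb_path, sep="\t", header=None, index_col=0)
            embeddings = {w: emb.loc[w].to_numpy(float) for w in emb.index}
        mfcc_path = directory / "mfcc.json"
        mfcc: dict[str, dict[str, np.ndarray]] = {}
        if mfcc_path.exists():
            raw = json.loads(mfcc_path.read_text())
            mfcc = {spk: {w: np.asarray(v, float) for w, v in d.items()} for spk, d in raw.items()}
        entries = []
        for row in table.itertuples(index=False):
            entries.append(
                WordEntry(
                    text=row.word,
                    transcription=tuple(str(row.transcription).split()),
                    embedding=embeddings.get(row.word),
                    mfcc_by_speaker={spk: mfcc[spk][row.word] for spk in mfcc},
                    condition=getattr(row, "condition", "unassigned"),
                )
            )
        return cls(entries)


class PhonemeFeatureTable:
    """Binary articulatory feature vectors, one per phoneme.

    Substitution cost in the feature-weighted edit distance is the Hamming
    distance between two phonemes' vectors divided by the feature count.
    """

    def __init__(self, table: dict[str, np.ndarray], feature_names: list[str] | None = None):
        lengths = {len(v) for v in table.values()}
        if len(lengths) != 1:
            raise ValueError("all feature vectors must share one length")
        self.table = {p: np.asarray(v, dtype=float) for p, v in table.items()}
        self.n_features = lengths.pop()
        self.feature_names = feature_names or [f"f{i}" for i in range(self.n_features)]

    def __contains__(self, phoneme: str) -> bool:
        return phoneme in self.table

    def vector(self, phoneme: str) -> np.ndarray:
        try:
            return self.table[phoneme]
        except KeyError:
            raise KeyError(f"phoneme {phoneme!r} not in feature table") from None

    def substitution_cost(self, a: str, b: str) -> float:
        """Fraction of mismatched features between phonemes ``a`` and ``b``."""
        return float(np.sum(self.vector(a) != self.vector(b))) / self.n_features

    def validate(self, lexicon: Lexicon) -> None:
        missing = {
            ph for e in lexicon for ph in e.transcription if ph not in self.table
        }
        if missing:
            raise KeyError(f"phonemes missing from feature table: {sorted(missing)}")


def load_phoneme_features() -> PhonemeFeatureTable:
    """Load the bundled toy articulatory feature inventory (23 phonemes x 10 features)."""
    raw = json.loads(
        resources.files("readrsa.data").joinpath("phoneme_features.json").read_text()
    )
    names = raw.pop("_features")
    return PhonemeFeatureTable({p: np.asarray(v) for p, v in raw.items()}, names)
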