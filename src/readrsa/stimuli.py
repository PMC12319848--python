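"""The five hypothesis dissimilarity models over word stimuli.

Each builder returns a :class:`~readrsa.rdm.ModelRDM` over the input word
list:

* ``visual_rdm`` — correlation distance between vectorised binary silhouette
  images of the rendered words.
* ``orthographic_rdm`` — correlation distance between unconstrained
  open-bigram count vectors.
* ``phonological_rdm`` — MFCC-based acoustic distance (segment-mean Euclidean),
  averaged across speakers; distances are computed within speaker only.
* ``semantic_rdm`` — cosine distance between word embedding vectors.
* ``articulatory_rdm`` — feature-weighted phonological edit distance,
  normalised for word length.

``model_independence_report`` screens a set of models for mutual independence
by correlating their vectorised forms and attaching a default-prior Bayes
factor to each pairwise correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw, ImageFont

from .bayes import correlation_bf
from .lexicon import Lexicon, PhonemeFeatureTable, WordEntry
from .rdm import ModelRDM, rdm_vectorize

__all__ = [
    "RenderConfig",
    "render_silhouette",
    "visual_rdm",
    "open_bigrams",
    "open_bigram_vector",
    "orthographic_rdm",
    "acoustic_word_distance",
    "phonological_rdm",
    "semantic_rdm",
    "weighted_edit_distance",
    "articulatory_rdm",
    "build_model_rdms",
    "model_independence_report",
]


def _default_font_path() -> str:
    # DejaVu Sans ships with matplotlib; a metrically ordinary sans-serif
    # stand-in for the presentation font, resolved once per process.
    from matplotlib import font_manager

    return font_manager.findfont("DejaVu Sans", fallback_to_default=True)


@dataclass(frozen=True)
class RenderConfig:
    """How words are rasterised into binary silhouettes.

    ``canvas`` must be wide enough for the longest word at ``font_size``;
    rendering centers the word on the canvas and binarises normalised
    intensity at ``threshold``.
    """

    font_path: str | None = None
    font_size: int = 28
    canvas: tuple[int, int] = (240, 48)
    threshold: float = 0.5
    lowercase: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly inside (0, 1)")

    def font(self) -> ImageFont.FreeTypeFont:
        path = self.font_path or _default_font_path()
        return ImageFont.truetype(path, self.font_size)


def render_silhouette(word: str, cfg: RenderConfig = RenderConfig()) -> np.ndarray:
    """Rasterise ``word`` to a flat {0,1} vector of length width*height."""
    if not word or not word.isalpha():
        raise ValueError(f"word must be non-empty alphabetic, got {word!r}")
    if cfg.lowercase:
        word = word.lower()
    font = cfg.font()
    for ch in word:
        if font.getmask(ch).getbbox() is None:
            raise ValueError(f"font has no visible glyph for character {ch!r}")
    w, h = cfg.canvas
    img = Image.new("L", (w, h), color=0)
    draw = ImageDraw.Draw(img)
    x0, y0, x1, y1 = draw.textbbox((0, 0), word, font=font)
    if x1 - x0 > w or y1 - y0 > h:
        raise ValueError(
            f"canvas {cfg.canvas} too small for {word!r} at font size {cfg.font_size}"
        )
    origin = ((w - (x1 - x0)) / 2 - x0, (h - (y1 - y0)) / 2 - y0)
    draw.text(origin, word, fill=255, font=font)
    arr = np.asarray(img, dtype=float) / 255.0
    return (arr >= cfg.threshold).astype(np.uint8).ravel()


def _pearson_distance_matrix(vectors: np.ndarray, what: str) -> np.ndarray:
    """1 - Pearson over rows; errors on any zero-variance row."""
    v = np.asarray(vectors, dtype=float)
    sd = v.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"{what} #{bad} is constant; Pearson distance undefined")
    d = 1.0 - np.corrcoef(v)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def visual_rdm(words: list[str], cfg: RenderConfig = RenderConfig()) -> ModelRDM:
    """Correlation distance between vectorised binary silhouette images."""
    if len(words) < 2:
        raise ValueError("need at least two words")
    sil = np.stack([render_silhouette(w, cfg) for w in words]).astype(float)
    return ModelRDM(tuple(words), _pearson_distance_matrix(sil, "silhouette"), "visual")


# --------------------------------------------------------------- orthographic


def open_bigrams(word: str) -> list[str]:
    """All ordered letter pairs of ``word`` with any positional gap (with
    multiplicity): L(L-1)/2 bigram tokens for a word of length L."""
    if len(word) < 2:
        raise ValueError(f"word must have length >= 2, got {word!r}")
    return [word[i] + word[j] for i, j in itertools.combinations(range(len(word)), 2)]


def open_bigram_vector(word: str, vocabulary: list[str]) -> np.ndarray:
    """Count vector of the word's unconstrained open bigrams over ``vocabulary``."""
    grams = open_bigrams(word)
    index = {g: k for k, g in enumerate(vocabulary)}
    vec = np.zeros(len(vocabulary), dtype=float)
    for g in grams:
        if g not in index:
            raise ValueError(f"bigram {g!r} of {word!r} missing from vocabulary")
        vec[index[g]] += 1.0
    return vec


def bigram_vocabulary(words: list[str]) -> list[str]:
    """Sorted union of open bigrams across ``words``."""
    return sorted(set(itertools.chain.from_iterable(open_bigrams(w) for w in words)))


def orthographic_rdm(words: list[str]) -> ModelRDM:
    """Correlation distance between unconstrained open-bigram count vectors."""
    if len(words) < 2:
        raise ValueError("need at least two words")
    vocab = bigram_vocabulary(words)
    vecs = np.stack([open_bigram_vector(w, vocab) for w in words])
    return ModelRDM(
        tuple(words), _pearson_distance_matrix(vecs, "bigram vector"), "orthographic"
    )


# --------------------------------------------------------------- phonological


def acoustic_word_distance(
    seq_a: np.ndarray, seq_b: np.ndarray, k_segments: int = 10
) -> float:
    """Segment-mean MFCC distance between two spoken-word frame sequences.

    Each sequence is split into ``k_segments`` contiguous, equal-count frame
    segments; each segment is reduced to its mean frame; the distance is the
    mean Euclidean distance between corresponding segment means.  Splitting
    into a fixed number of segments makes the measure invariant to overall
    word duration.
    """
    a, b = np.atleast_2d(np.asarray(seq_a, float)), np.atleast_2d(np.asarray(seq_b, float))
    if k_segments < 1:
        raise ValueError("k_segments must be >= 1")
    if a.shape[0] < k_segments or b.shape[0] < k_segments:
        raise ValueError(
            f"sequences must have at least k_segments={k_segments} frames "
            f"(got {a.shape[0]} and {b.shape[0]})"
        )
    if a.shape[1] != b.shape[1]:
        raise ValueError("MFCC frames must share one dimension")
    means_a = np.stack([s.mean(axis=0) for s in np.array_split(a, k_segments)])
    means_b = np.stack([s.mean(axis=0) for s in np.array_split(b, k_segments)])
    return float(np.linalg.norm(means_a - means_b, axis=1).mean())


def phonological_rdm(
    lexicon: Lexicon | list[WordEntry],
    speakers: list[str] | None = None,
    k_segments: int = 10,
) -> ModelRDM:
    """Across-speaker mean of within-speaker acoustic word distances."""
    entries = list(lexicon)
    words = [e.text for e in entries]
    if speakers is None:
        speakers = sorted(entries[0].mfcc_by_speaker)
    if not speakers:
        raise ValueError("no speakers given and none found in the lexicon")
    for e in entries:
        for spk in speakers:
            if spk not in e.mfcc_by_speaker:
                raise KeyError(f"word {e.text!r} has no MFCC sample for speaker {spk!r}")
    n = len(words)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = np.mean(
            [
                acoustic_word_distance(
                    entries[i].mfcc_by_speaker[spk],
                    entries[j].mfcc_by_speaker[spk],
                    k_segments,
                )
                for spk in speakers
            ]
        )
        out[i, j] = out[j, i] = d
    return ModelRDM(tuple(words), out, "phonological")


# ------------------------------------------------------------------- semantic


def semantic_rdm(
    lexicon: Lexicon | list[WordEntry], embeddings: dict[str, np.ndarray] | None = None
) -> ModelRDM:
    """Cosine distance (1 - cosine similarity) between word embeddings."""
    entries = list(lexicon)
    words = [e.text for e in entries]
    if embeddings is None:
        embeddings = {e.text: e.embedding for e in entries}
    vecs = []
    for w in words:
        v = embeddings.get(w)
        if v is None:
            raise KeyError(f"no embedding for word {w!r}")
        v = np.asarray(v, float)
        if np.linalg.norm(v) == 0:
            raise ValueError(f"zero-norm embedding for word {w!r}")
        vecs.append(v / np.linalg.norm(v))
    v = np.stack(vecs)
    d = np.clip(1.0 - v @ v.T, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return ModelRDM(tuple(words), (d + d.T) / 2.0, "semantic")


# --------------------------------------------------------------- articulatory


def weighted_edit_distance(
    tr_a: tuple[str, ...],
    tr_b: tuple[str, ...],
    ft: PhonemeFeatureTable,
    indel_cost: float = 1.0,
) -> float:
    """Feature-weighted phonological edit distance, normalised for word length.

    Standard dynamic-programming edit distance where substituting phoneme a
    for b costs the fraction of mismatched articulatory features, and
    insertions/deletions cost ``indel_cost`` (1.0 = the maximum substitution
    cost, bounding the normalised result in [0, 1]).  The raw distance is
    divided by the longer transcription's length.
    """
    a, b = tuple(tr_a), tuple(tr_b)
    if not a or not b:
        raise ValueError("transcriptions must be non-empty")
    for ph in (*a, *b):
        ft.vector(ph)  # raises KeyError naming an unknown phoneme
    la, lb = len(a), len(b)
    dp = np.zeros((la + 1, lb + 1))
    dp[:, 0] = np.arange(la + 1) * indel_cost
    dp[0, :] = np.arange(lb + 1) * indel_cost
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = dp[i - 1, j - 1] + ft.substitution_cost(a[i - 1], b[j - 1])
            dp[i, j] = min(sub, dp[i - 1, j] + indel_cost, dp[i, j - 1] + indel_cost)
    return float(dp[la, lb]) / max(la, lb)


def articulatory_rdm(
    lexicon: Lexicon | list[WordEntry],
    ft: PhonemeFeatureTable,
    indel_cost: float = 1.0,
) -> ModelRDM:
    """Pairwise length-normalised feature-weighted edit distances."""
    entries = list(lexicon)
    words = [e.text for e in entries]
    n = len(words)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = weighted_edit_distance(
            entries[i].transcription, entries[j].transcription, ft, indel_cost
        )
    return ModelRDM(tuple(words), out, "articulatory")


# ------------------------------------------------------------------ ensembles


def build_model_rdms(
    lexicon: Lexicon,
    ft: PhonemeFeatureTable,
    cfg: RenderConfig = RenderConfig(),
    condition: str | None = None,
    k_segments: int = 10,
) -> dict[str, ModelRDM]:
    """All five hypothesis RDMs for one word set.

    With ``condition`` given, only that condition's words enter (the
    15-item models used per participant); otherwise all words do (the
    30-item exemplar models used for the independence screen).
    """
    lex = lexicon.subset(condition) if condition else lexicon
    words = lex.words
    return {
        "visual": visual_rdm(words, cfg),
        "orthographic": orthographic_rdm(words),
        "phonological": phonological_rdm(lex, k_segments=k_segments),
        "semantic": semantic_rdm(lex),
        "articulatory": articulatory_rdm(lex, ft),
    }


def model_independence_report(rdms: dict[str, ModelRDM] | list[ModelRDM]) -> pd.DataFrame:
    """Pairwise Pearson r and BF10 between vectorised models (upper triangle).

    The Bayes factor treats the n(n-1)/2 RDM cells as observations, so for
    30-item exemplar models each correlation is screened at n = 435 pairs.
    """
    if isinstance(rdms, dict):
        named = list(rdms.items())
    else:
        named = [(r.measure, r) for r in rdms]
    items = named[0][1].items
    for name, r in named:
        if r.items != items:
            raise ValueError(f"model {name!r} is over a different item list")
    vectors = {name: rdm_vectorize(r.matrix) for name, r in named}
    n_pairs = len(items) * (len(items) - 1) // 2
    rows = []
    for (na, _), (nb, _) in itertools.combinations(named, 2):
        r = float(np.corrcoef(vectors[na], vectors[nb])[0, 1])
        rows.append(
            {
                "model_a": na,
                "model_b": nb,
                "r": r,
                "bf10": correlation_bf(r, n_pairs),
                "n_pairs": n_pairs,
            }
        )
    return pd.DataFrame(rows)
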