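"""The five hypothesis dissimilarity models and the independence screen."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readrsa.lexicon import WordEntry
from readrsa.rdm import ModelRDM, rdm_vectorize
from readrsa.stimuli import (
    RenderConfig,
    acoustic_word_distance,
    articulatory_rdm,
    bigram_vocabulary,
    build_model_rdms,
    model_independence_report,
    open_bigram_vector,
    open_bigrams,
    orthographic_rdm,
    phonological_rdm,
    render_silhouette,
    semantic_rdm,
    visual_rdm,
    weighted_edit_distance,
)

# ----------------------------------------------------------------- rendering


class TestSilhouettes:
    def test_deterministic_and_binary(self):
        a = render_silhouette("window")
        b = render_silhouette("window")
        assert np.array_equal(a, b)
        assert set(np.unique(a)) <= {0, 1}

    def test_ink_pixel_count_matches_frozen_reference(self):
        # reference rasterization of "cat" (DejaVu Sans 28pt, 240x48 canvas,
        # threshold 0.5), frozen once
        v = render_silhouette("cat")
        assert v.size == 240 * 48
        assert int(v.sum()) == 234

    def test_rejects_non_alphabetic(self):
        with pytest.raises(ValueError):
            render_silhouette("no-hyphens")

    def test_canvas_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            render_silhouette("wwwwwwwwww", RenderConfig(canvas=(40, 12)))

    def test_visual_rdm_duplicate_word_is_zero(self):
        rdm = visual_rdm(["cat", "cat", "dog"])
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(rdm.matrix <= 2.0)

    def test_visual_rdm_matches_hand_computed_pearson(self):
        # bypass rendering: the distance computation is shared, so check it
        # on 6-pixel hand-set "silhouettes" against the direct formula
        from readrsa.stimuli import _pearson_distance_matrix

        sil = np.array(
            [[1, 0, 0, 1, 1, 0], [1, 1, 0, 0, 1, 0], [0, 1, 1, 0, 0, 1]], float
        )
        got = _pearson_distance_matrix(sil, "silhouette")
        for i, j in itertools.combinations(range(3), 2):
            x, y = sil[i], sil[j]
            r = np.sum((x - x.mean()) * (y - y.mean())) / (
                np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            )
            assert got[i, j] == pytest.approx(1 - r, abs=1e-12)


# -------------------------------------------------------------- open bigrams


class TestOpenBigrams:
    def test_two_letter_word(self):
        assert open_bigrams("at") == ["at"]

    def test_salt_enumeration(self):
        assert sorted(open_bigrams("salt")) == sorted(
            ["sa", "sl", "st", "al", "at", "lt"]
        )

    def test_banana_counts(self):
        vocab = bigram_vocabulary(["banana"])
        vec = open_bigram_vector("banana", vocab)
        assert vec[vocab.index("an")] == 3
        assert vec.sum() == 15  # 6*5/2

    def test_word_too_short(self):
        with pytest.raises(ValueError):
            open_bigrams("a")

    @given(st.text(alphabet="abcdef", min_size=2, max_size=10))
    @settings(deadline=None, max_examples=60)
    def test_counts_match_exhaustive_index_pairs(self, word):
        vocab = bigram_vocabulary([word])
        vec = open_bigram_vector(word, vocab)
        # oracle: enumerate all ordered index pairs directly
        counts = {}
        for i in range(len(word)):
            for j in range(i + 1, len(word)):
                counts[word[i] + word[j]] = counts.get(word[i] + word[j], 0) + 1
        assert vec.sum() == len(word) * (len(word) - 1) / 2
        for g, c in counts.items():
            assert vec[vocab.index(g)] == c

    def test_orthographic_rdm_identical_words(self):
        rdm = orthographic_rdm(["salt", "salt", "pepper"])
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_letter_words_anticorrelated(self):
        rdm = orthographic_rdm(["abab", "cdcd"])
        assert rdm.matrix[0, 1] > 1.0


# ------------------------------------------------------------- MFCC distance


class TestAcousticDistance:
    def test_identical_sequences(self):
        seq = np.random.default_rng(0).standard_normal((20, 5))
        assert acoustic_word_distance(seq, seq, 10) == 0.0

    def test_three_four_five(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[3.0, 4.0]])
        assert acoustic_word_distance(a, b, 1) == pytest.approx(5.0)

    def test_matches_segment_mean_oracle(self):
        a = np.array([[0, 0], [2, 0], [4, 4], [6, 4]], float)
        b = np.array([[1, 1], [1, 1], [5, 0], [5, 0]], float)
        # k=2 oracle: segment means a -> (1,0),(5,4); b -> (1,1),(5,0)
        expected = (np.hypot(0, 1) + np.hypot(0, 4)) / 2
        assert acoustic_word_distance(a, b, 2) == pytest.approx(expected)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            acoustic_word_distance(np.zeros((3, 2)), np.zeros((10, 2)), 5)

    def test_phonological_rdm_speaker_average(self, toy_lexicon):
        rdm = phonological_rdm(toy_lexicon, k_segments=4)
        entries = list(toy_lexicon)
        # brute-force oracle: per speaker then average
        for i, j in itertools.combinations(range(3), 2):
            per_spk = [
                acoustic_word_distance(
                    entries[i].mfcc_by_speaker[s], entries[j].mfcc_by_speaker[s], 4
                )
                for s in ("s1", "s2")
            ]
            assert rdm.matrix[i, j] == pytest.approx(np.mean(per_spk))

    def test_missing_speaker_errors_with_name(self, toy_lexicon):
        with pytest.raises(KeyError, match="spk-x"):
            phonological_rdm(toy_lexicon, speakers=["s1", "spk-x"])


# ------------------------------------------------------------------ semantic


class TestSemanticRDM:
    def test_cosine_extremes(self):
        e = {
            "same": np.array([1.0, 0.0]),
            "copy": np.array([2.0, 0.0]),
            "ortho": np.array([0.0, 1.0]),
            "anti": np.array([-3.0, 0.0]),
        }
        entries = [WordEntry(text=w, transcription=("a",)) for w in e]
        rdm = semantic_rdm(entries, embeddings=e)
        m = {w: i for i, w in enumerate(e)}
        assert rdm.matrix[m["same"], m["copy"]] == pytest.approx(0.0, abs=1e-12)
        assert rdm.matrix[m["same"], m["ortho"]] == pytest.approx(1.0)
        assert rdm.matrix[m["same"], m["anti"]] == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        entries = [
            WordEntry(text="aa", transcription=("a",)),
            WordEntry(text="bb", transcription=("b",)),
        ]
        with pytest.raises(ValueError, match="zero-norm"):
            semantic_rdm(entries, embeddings={"aa": np.zeros(3), "bb": np.ones(3)})


# ------------------------------------------------------------- edit distance


def exhaustive_edit_distance(a, b, ft, indel=1.0):
    """Oracle: plain recursion over all alignments (exponential)."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        opts = []
        if i < len(a):
            opts.append(indel + rec(i + 1, j))
        if j < len(b):
            opts.append(indel + rec(i, j + 1))
        if i < len(a) and j < len(b):
            opts.append(ft.substitution_cost(a[i], b[j]) + rec(i + 1, j + 1))
        return min(opts)

    return rec(0, 0) / max(len(a), len(b))


class TestWeightedEditDistance:
    def test_identical(self, toy_feature_table):
        assert weighted_edit_distance(("p", "a"), ("p", "a"), toy_feature_table) == 0.0

    def test_single_substitution(self, toy_feature_table):
        # p vs b mismatch in 1 of 4 features, length 3
        d = weighted_edit_distance(
            ("p", "a", "i"), ("b", "a", "i"), toy_feature_table
        )
        assert d == pytest.approx((1 / 4) / 3)

    def test_single_insertion(self, toy_feature_table):
        d = weighted_edit_distance(("a",), ("a", "p"), toy_feature_table)
        assert d == pytest.approx(1.0 / 2)

    def test_unknown_phoneme_named(self, toy_feature_table):
        with pytest.raises(KeyError, match="zz"):
            weighted_edit_distance(("zz",), ("a",), toy_feature_table)

    @given(
        st.lists(st.sampled_from(["p", "b", "a", "i"]), min_size=1, max_size=5),
        st.lists(st.sampled_from(["p", "b", "a", "i"]), min_size=1, max_size=5),
    )
    @settings(deadline=None, max_examples=80)
    def test_matches_exhaustive_alignment_oracle(self, a, b):
        from readrsa.lexicon import PhonemeFeatureTable

        ft = PhonemeFeatureTable(
            {
                "p": np.array([0, 0, 0, 0]),
                "b": np.array([1, 0, 0, 0]),
                "a": np.array([1, 1, 1, 0]),
                "i": np.array([1, 1, 1, 1]),
            }
        )
        got = weighted_edit_distance(tuple(a), tuple(b), ft)
        assert got == pytest.approx(exhaustive_edit_distance(tuple(a), tuple(b), ft))

    def test_articulatory_rdm_homophones_and_symmetry(self, feature_table):
        entries = [
            WordEntry(text="night", transcription=("n", "a", "i", "t")),
            WordEntry(text="knight", transcription=("n", "a", "i", "t")),
            WordEntry(text="day", transcription=("d", "e", "i")),
        ]
        rdm = articulatory_rdm(entries, feature_table)
        assert rdm.matrix[0, 1] == 0.0
        assert np.array_equal(rdm.matrix, rdm.matrix.T)


# -------------------------------------------------------- ensemble behaviour


class TestModelEnsemble:
    def test_all_builders_valid_and_equivariant(self, toy_lexicon, feature_table):
        """Symmetry/diagonal/bounds plus item-permutation equivariance."""
        rdms = build_model_rdms(toy_lexicon, feature_table, k_segments=4)
        perm = [2, 0, 1]
        from readrsa.lexicon import Lexicon

        permuted = Lexicon([list(toy_lexicon)[i] for i in perm])
        rdms_p = build_model_rdms(permuted, feature_table, k_segments=4)
        for measure, rdm in rdms.items():
            m = rdm.matrix
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 0)
            assert np.all(m >= 0)
            if measure in ("visual", "orthographic", "semantic"):
                assert np.all(m <= 2.0)
            expected = m[np.ix_(perm, perm)]
            # orthographic vocabulary is permutation-invariant, so this holds
            # exactly for every measure
            assert np.allclose(rdms_p[measure].matrix, expected, atol=1e-12)

    def test_independence_report_shape_and_n(self, feature_table):
        from readrsa.simulate import generate_lexicon

        lex = generate_lexicon(6, seed=2)
        rdms = build_model_rdms(lex, feature_table, k_segments=4)
        report = model_independence_report(rdms)
        assert len(report) == 10  # C(5,2)
        assert (report["n_pairs"] == 15).all()  # C(6,2)

    def test_independence_report_random_rdms_weak_evidence(self):
        rng = np.random.default_rng(7)
        items = tuple(f"w{i}" for i in range(30))

        def random_rdm(tag):
            a = rng.standard_normal((30, 30))
            d = np.abs(a - a.T)
            np.fill_diagonal(d, 0)
            return ModelRDM(items, d, tag)

        report = model_independence_report([random_rdm("m1"), random_rdm("m2")])
        assert abs(report.loc[0, "r"]) < 0.15
        assert report.loc[0, "bf10"] < 3.0
        assert report.loc[0, "n_pairs"] == 435

    def test_mismatched_item_lists_rejected(self):
        a = ModelRDM(("x", "y"), np.array([[0, 1.0], [1.0, 0]]), "m1")
        b = ModelRDM(("x", "z"), np.array([[0, 1.0], [1.0, 0]]), "m2")
        with pytest.raises(ValueError):
            model_independence_report([a, b])
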