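import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import protrep as pr
from protrep.alphabets import SDM12, AlphabetGrouping, TrigramVocabulary
from protrep.io import ValidationError

sequences = st.text(alphabet=pr.STANDARD_AA, min_size=3, max_size=60)


class TestExtractTrigrams:
    def test_overlapping_windows(self):
        assert pr.extract_trigrams("MKVL") == ["MKV", "KVL"]
        assert pr.extract_trigrams("ACD") == ["ACD"]

    def test_too_short(self):
        with pytest.raises(ValidationError):
            pr.extract_trigrams("MK")


class TestHistogram:
    def test_repeated_trigram(self, vocab):
        h = pr.histogram("AAAA", vocab)
        assert h[vocab.index("AAA")] == 2
        assert h.sum() == 2

    def test_enumerated_counts(self, vocab):
        h = pr.histogram("ACDACD", vocab)
        expected = {"ACD": 2, "CDA": 1, "DAC": 1}
        for tri, count in expected.items():
            assert h[vocab.index(tri)] == count
        assert h.sum() == sum(expected.values())

    @settings(derandomize=True, deadline=None)
    @given(sequences)
    def test_conservation(self, seq):
        vocab = pr.standard_vocabulary()
        assert pr.histogram(seq, vocab).sum() == len(seq) - 2

    def test_normalized_sums_to_one(self, vocab):
        assert pr.histogram("ACDACD", vocab, normalize=True).sum() == pytest.approx(1.0)


class TestReducedAlphabet:
    def test_sdm12_recoding(self):
        # L, I, V, M share one SDM12 group
        reduced = pr.reduce_sequence("LIVM", SDM12)
        assert len(set(reduced)) == 1 and len(reduced) == 4

    def test_identity_partition(self):
        identity = AlphabetGrouping({c: c for c in pr.STANDARD_AA}, name="identity")
        assert pr.reduce_sequence("MKVLW", identity) == "MKVLW"

    def test_unmapped_residue(self):
        with pytest.raises(ValueError):
            pr.reduce_sequence("MXV", SDM12)

    def test_sdm12_vector_length(self):
        assert len(pr.histogram_reduced("MKVLW", SDM12)) == 1728

    def test_cogrouped_counts(self):
        h = pr.histogram_reduced("LIVM", SDM12)
        g = SDM12.residue_map()["L"]
        reduced_vocab = pr.reduced_vocabulary(SDM12)
        assert h[reduced_vocab.index(g * 3)] == 2
        assert h.sum() == 2

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(sequences, st.integers(0, 2**31 - 1))
    def test_projection_of_full_histogram(self, seq, grouping_seed):
        """Summing full-histogram counts over trigrams mapping to one reduced
        trigram must reproduce the reduced histogram, for random groupings."""
        rng = np.random.default_rng(grouping_seed)
        n_groups = int(rng.integers(2, 6))
        symbols = "abcdef"[:n_groups]
        assignment = rng.integers(0, n_groups, size=20)
        while len(set(assignment)) < n_groups:  # every group non-empty
            assignment = rng.integers(0, n_groups, size=20)
        grouping = AlphabetGrouping(
            {
                symbols[g]: "".join(pr.STANDARD_AA[i] for i in np.flatnonzero(assignment == g))
                for g in range(n_groups)
            },
            name="random",
        )
        full = pr.histogram(seq, pr.standard_vocabulary())
        reduced = pr.histogram_reduced(seq, grouping)
        # brute-force projection
        table = grouping.residue_map()
        reduced_vocab = pr.reduced_vocabulary(grouping)
        projected = np.zeros(reduced_vocab.size)
        for i, tri in enumerate(pr.standard_vocabulary().trigrams):
            image = "".join(table[c] for c in tri)
            projected[reduced_vocab.index(image)] += full[i]
        assert np.array_equal(projected, reduced)


class TestEmbeddingRepresentations:
    def _ones_table(self, dim=5):
        vocab = pr.standard_vocabulary()
        return pr.EmbeddingTable(dim, {t: np.ones(dim) for t in vocab.trigrams})

    def test_all_ones_table(self):
        vec = pr.sum_of_trigram_embeddings("ACDEFGH", self._ones_table())
        assert np.array_equal(vec, np.full(5, 5.0))  # 5 windows x 1

    def test_single_window_identity(self):
        table = pr.EmbeddingTable(3, {"ACD": np.array([1.0, -2.0, 0.5])})
        assert np.array_equal(pr.sum_of_trigram_embeddings("ACD", table), [1.0, -2.0, 0.5])

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(sequences, st.integers(0, 2**31 - 1))
    def test_equals_histogram_matrix_product(self, seq, seed):
        rng = np.random.default_rng(seed)
        vocab = pr.standard_vocabulary()
        emb = rng.standard_normal((vocab.size, 8))
        table = pr.EmbeddingTable(8, {t: emb[i] for i, t in enumerate(vocab.trigrams)})
        direct = pr.sum_of_trigram_embeddings(seq, table)
        product = pr.histogram(seq, vocab) @ emb
        assert np.allclose(direct, product, atol=1e-9)

    def test_missing_trigram_policies(self):
        table = pr.EmbeddingTable(2, {"ACD": np.ones(2)})
        with pytest.raises(ValidationError):
            pr.sum_of_trigram_embeddings("ACDE", table)
        assert np.array_equal(
            pr.sum_of_trigram_embeddings("ACDE", table, missing="skip"), [1.0, 1.0]
        )

    def test_mean_pool(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(pr.mean_pool_residue_embeddings(np.vstack([v, v, v])), v)
        assert np.array_equal(pr.mean_pool_residue_embeddings(np.vstack([0 * v, 2 * v])), v)
        assert np.array_equal(pr.mean_pool_residue_embeddings(v[None, :]), v)

    def test_mean_pool_empty(self):
        with pytest.raises(ValidationError):
            pr.mean_pool_residue_embeddings(np.empty((0, 3)))


class TestRegionRestriction:
    def test_centre_residue_rule(self, vocab):
        # length 10, domain [0,5): windows 0..7 have centres 1..8; centres
        # 1-4 fall in the domain -> windows 0-3 are domain windows
        rec = pr.ProteinRecord("p", "ACDEFGHIKL", domains=[(0, 5)])
        dom = pr.region_restricted_histogram(rec, "domain", vocab)
        non = pr.region_restricted_histogram(rec, "nondomain", vocab)
        assert dom.sum() == 4
        assert non.sum() == 4
        for i in range(4):
            assert dom[vocab.index(rec.sequence[i : i + 3])] >= 1

    def test_near_total_domain(self, vocab):
        rec = pr.ProteinRecord("p", "ACDEFGHIKL", domains=[(0, 9)])
        non = pr.region_restricted_histogram(rec, "nondomain", vocab)
        assert non.sum() <= 1

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_conservation(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(6, 60))
        seq = "".join(rng.choice(list(pr.STANDARD_AA), size=length))
        start = int(rng.integers(0, length - 1))
        end = int(rng.integers(start + 1, length + 1))
        if (end - start) == length:  # keep one non-domain residue
            end -= 1
            if end <= start:
                start, end = 0, length - 1
        rec = pr.ProteinRecord("p", seq, domains=[(start, end)])
        vocab = pr.standard_vocabulary()
        dom = pr.region_restricted_histogram(rec, "domain", vocab)
        non = pr.region_restricted_histogram(rec, "nondomain", vocab)
        assert np.array_equal(dom + non, pr.histogram(seq, vocab))

    def test_requires_both_regions(self, vocab):
        with pytest.raises(ValidationError):
            pr.region_restricted_histogram(pr.ProteinRecord("p", "ACDEF"), "domain", vocab)


class TestSubsetFeatures:
    def _matrix(self):
        return pr.FeatureMatrix(["a", "b"], np.arange(8.0).reshape(2, 4), ["f0", "f1", "f2", "f3"])

    def test_identity(self):
        fm = self._matrix()
        out = pr.subset_features(fm, [0, 1, 2, 3])
        assert np.array_equal(out.values, fm.values)
        assert out.feature_names == fm.feature_names

    def test_single_column(self):
        out = pr.subset_features(self._matrix(), [2])
        assert np.array_equal(out.values, [[2.0], [6.0]])
        assert out.feature_names == ["f2"]

    @pytest.mark.parametrize("bad", [[], [0, 0], [4], [-1]])
    def test_invalid_indices(self, bad):
        with pytest.raises(ValueError):
            pr.subset_features(self._matrix(), bad)


class TestVocabulary:
    def test_sizes(self):
        assert pr.standard_vocabulary().size == 8000
        assert pr.reduced_vocabulary(SDM12).size == 1728

    def test_lexicographic_order(self):
        vocab = TrigramVocabulary("AB")
        assert vocab.trigrams == ["".join(t) for t in itertools.product("AB", repeat=3)]
        assert vocab.index("ABA") == 2

    def test_sdm12_partitions_standard_alphabet(self):
        members = "".join(SDM12.groups.values())
        assert sorted(members) == sorted(pr.STANDARD_AA)
        assert SDM12.n_groups == 12
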