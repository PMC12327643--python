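from functools import lru_cache

import numpy as np
import pytest

import protrep as pr
from protrep.representations import histogram


def brute_force_nw(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Independent oracle: recursive maximisation over all global alignments
    with gap-run scoring (first gap symbol costs gap_open, each further
    symbol of the same run costs gap_extend)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        # state: which move produced column (i, j) — 'm' match, 'a' gap in b
        # (a consumed), 'b' gap in a (b consumed), 's' start
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(sub[(a[i], b[j])] + best(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_extend if state == "a" else gap_open
            options.append(cost + best(i + 1, j, "a"))
        if j < len(b):
            cost = gap_extend if state == "b" else gap_open
            options.append(cost + best(i, j + 1, "b"))
        return max(options)

    return best(0, 0, "s")


def random_scheme(rng):
    """A random symmetric integer substitution map over a 4-letter alphabet."""
    alphabet = "ACDE"
    sub = {}
    for i, x in enumerate(alphabet):
        for y in alphabet[i:]:
            s = float(rng.integers(-3, 6))
            sub[(x, y)] = s
            sub[(y, x)] = s
    return alphabet, sub


class TestNWScore:
    def test_identical_sequences_linear(self):
        scheme = pr.ScoringScheme.toy(match=1, mismatch=-1, gap=-1)
        assert pr.nw_score("MKVLW", "MKVLW", scheme) == 5.0

    def test_one_match_one_gap(self):
        scheme = pr.ScoringScheme.toy(match=1, mismatch=-1, gap=-1)
        assert pr.nw_score("AW", "W", scheme) == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pr.nw_score("", "A")

    @pytest.mark.parametrize("mode", ["linear", "affine"])
    def test_matches_enumeration_oracle(self, mode):
        """Exact agreement with the exhaustive alignment oracle on 100
        random pairs per gap mode (lengths 1-8)."""
        rng = np.random.default_rng(17 if mode == "linear" else 23)
        for _ in range(100):
            alphabet, sub = random_scheme(rng)
            la, lb = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            a = "".join(rng.choice(list(alphabet), size=la))
            b = "".join(rng.choice(list(alphabet), size=lb))
            if mode == "linear":
                gap_open = gap_extend = float(-rng.integers(1, 4))
                scheme = pr.ScoringScheme(substitution=sub, gap_open=gap_open,
                                          gap_extend=gap_open, mode="linear")
            else:
                gap_open = float(-rng.integers(3, 7))
                gap_extend = float(-rng.integers(1, 3))
                scheme = pr.ScoringScheme(substitution=sub, gap_open=gap_open,
                                          gap_extend=gap_extend, mode="affine")
            expected = brute_force_nw(a, b, sub, gap_open, gap_extend)
            assert pr.nw_score(a, b, scheme) == pytest.approx(expected), (a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        scheme = pr.ScoringScheme()
        for _ in range(20):
            a = "".join(rng.choice(list(pr.STANDARD_AA), size=int(rng.integers(3, 30))))
            b = "".join(rng.choice(list(pr.STANDARD_AA), size=int(rng.integers(3, 30))))
            assert pr.nw_score(a, b, scheme) == pr.nw_score(b, a, scheme)

    def test_self_score_dominates(self):
        rng = np.random.default_rng(6)
        scheme = pr.ScoringScheme.toy(match=2, mismatch=-1, gap=-2)
        a = "".join(rng.choice(list(pr.STANDARD_AA), size=20))
        for _ in range(10):
            b = "".join(rng.choice(list(pr.STANDARD_AA), size=int(rng.integers(5, 30))))
            assert pr.nw_score(a, a, scheme) >= pr.nw_score(a, b, scheme)

    def test_invalid_gap_signs(self):
        with pytest.raises(ValueError):
            pr.ScoringScheme(gap_open=1.0)


class TestCosineSimilarity:
    def test_identity(self):
        v = np.array([1.0, 2.0, -1.0])
        assert pr.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert pr.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_antiparallel(self):
        v = np.array([3.0, -1.0])
        assert pr.cosine_similarity(v, -v) == pytest.approx(-1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            pr.cosine_similarity([0, 0], [1, 1])


def brute_force_spearman(x, y):
    """Direct mid-rank formula: Pearson correlation of average ranks."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


class TestSpearman:
    def test_monotone_cases(self):
        assert pr.spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert pr.spearman_rho([1, 2, 3], [5, 0, -5]) == pytest.approx(-1.0)

    def test_known_example(self):
        assert pr.spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_nan(self):
        assert np.isnan(pr.spearman_rho([1, 1, 1], [1, 2, 3]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_midrank_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        x = rng.integers(0, 10, size=n).astype(float)  # ties likely
        y = rng.integers(0, 10, size=n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert pr.spearman_rho(x, y) == pytest.approx(brute_force_spearman(x, y), abs=1e-10)


class TestSimilarityStudy:
    def _ladder_pool(self, seed=3):
        _, ladder = pr.generate_homolog_ladder(parent_length=100, n_per_rate=10, seed=seed)
        return [rec for group in ladder.values() for rec in group]

    def test_determinism(self):
        pool = self._ladder_pool()
        vocab = pr.standard_vocabulary()
        rep = lambda rec: histogram(rec.sequence, vocab)
        a = pr.similarity_study(pool, rep, n_sets=2, set_size=15, seed=8)
        b = pr.similarity_study(pool, rep, n_sets=2, set_size=15, seed=8)
        assert a.per_set_rho == b.per_set_rho

    def test_histogram_concordant_on_homologs(self):
        """On a mutation ladder, histogram cosine tracks alignment score."""
        pool = self._ladder_pool()
        vocab = pr.standard_vocabulary()
        res = pr.similarity_study(
            pool, lambda rec: histogram(rec.sequence, vocab),
            n_sets=2, set_size=25, seed=1,
        )
        assert res.mean > 0.5

    def test_random_vectors_discordant(self):
        """Representation vectors independent of sequence carry no
        alignment information: rho stays inside the permutation null."""
        pool = self._ladder_pool()
        rng = np.random.default_rng(2)
        vectors = {rec.id: rng.standard_normal(30) for rec in pool}
        res = pr.similarity_study(
            pool, lambda rec: vectors[rec.id], n_sets=1, set_size=25, seed=4,
        )
        nw, cos, rho = pr.pairwise_concordance(
            pool[:25], np.vstack([vectors[r.id] for r in pool[:25]])
        )
        null = [
            pr.spearman_rho(nw, rng.permutation(cos)) for _ in range(200)
        ]
        assert abs(res.per_set_rho[0]) <= np.quantile(np.abs(null), 0.995) + 0.05

    def test_set_size_lowered_with_warning(self, caplog):
        pool = self._ladder_pool()[:10]
        vocab = pr.standard_vocabulary()
        res = pr.similarity_study(
            pool, lambda rec: histogram(rec.sequence, vocab),
            n_sets=1, set_size=1000, seed=0,
        )
        assert res.set_size == 10

    def test_representation_failure_names_record(self):
        pool = self._ladder_pool()[:5]

        def broken(rec):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match=pool[0].id[:4]):
            pr.similarity_study(pool, broken, n_sets=1, set_size=5, seed=0)
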