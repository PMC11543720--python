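import itertools

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudovalence.form_features import CleanLexicon
from pseudovalence.neighbors import (
    hub_report,
    nearest_orthographic,
    nearest_semantic,
    neighbor_table,
    osa_distance,
)


def osa_oracle(s1: str, s2: str) -> int:
    """Exhaustive edit-sequence search for the optimal string alignment
    distance: explores every interleaving of insert/delete/substitute and
    adjacent-transposition steps over the two strings, never revisiting a
    transposed pair.  Independent of the dynamic program under test."""

    def go(i: int, j: int) -> int:
        if i == len(s1):
            return len(s2) - j
        if j == len(s2):
            return len(s1) - i
        best = go(i + 1, j + 1) + (0 if s1[i] == s2[j] else 1)
        best = min(best, go(i + 1, j) + 1)      # delete s1[i]
        best = min(best, go(i, j + 1) + 1)      # insert s2[j]
        if (
            i + 1 < len(s1)
            and j + 1 < len(s2)
            and s1[i] == s2[j + 1]
            and s1[i + 1] == s2[j]
        ):
            best = min(best, go(i + 2, j + 2) + 1)
        return best

    return go(0, 0)


class TestOsaDistance:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ("abc", "abc", 0),
            ("ab", "ba", 1),
            ("ca", "abc", 3),  # unrestricted Damerau-Levenshtein would give 2
            ("", "abc", 3),
            ("kitten", "sitting", 3),
        ],
    )
    def test_known_distances(self, s1, s2, expected):
        assert osa_distance(s1, s2) == expected

    def test_exhaustive_oracle_all_short_strings(self):
        """Full enumeration: all pairs of strings of length <= 4 over
        {a, b, c} agree with the exhaustive edit-sequence oracle."""
        strings = [""] + [
            "".join(t)
            for n in range(1, 5)
            for t in itertools.product("abc", repeat=n)
        ]
        for i, s1 in enumerate(strings):
            for s2 in strings[i:]:
                d = osa_distance(s1, s2)
                assert d == osa_oracle(s1, s2), (s1, s2)
                assert d == osa_distance(s2, s1)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.text(alphabet="abcde", max_size=8),
        st.text(alphabet="abcde", max_size=8),
    )
    def test_bounded_by_levenshtein(self, s1, s2):
        """OSA never exceeds plain Levenshtein (edlib as external oracle)
        and equals it when no adjacent transposition is beneficial."""
        d = osa_distance(s1, s2)
        if s1 and s2:
            lev = edlib.align(s1, s2)["editDistance"]
            assert d <= lev
            if d < lev:
                assert lev - d >= 1  # each transposition saves exactly one edit
        assert d == osa_distance(s2, s1)


class TestNearestOrthographic:
    def test_exact_match(self, tiny_lexicon):
        res = nearest_orthographic("bus", tiny_lexicon)
        assert res.distance == 0 and res.neighbors == ("bus",)
        assert res.neighbor_valence == 5.0

    def test_tied_neighbors_mean_valence(self, tiny_lexicon):
        res = nearest_orthographic("bux", tiny_lexicon)
        assert set(res.neighbors) == {"bus", "bug"}
        assert res.distance == 1
        assert res.neighbor_valence == pytest.approx(4.0)

    def test_matches_bruteforce_scan(self):
        """Neighbor sets agree with an independent full scan on random
        50-word lexicons."""
        rng = np.random.default_rng(0)
        letters = np.array(list("abcdef"))
        words = []
        while len(words) < 50:
            w = "".join(rng.choice(letters, size=rng.integers(2, 7)))
            if w not in words:
                words.append(w)
        lex = CleanLexicon(tuple(words), tuple(rng.uniform(1, 9, 50)))
        for _ in range(20):
            q = "".join(rng.choice(letters, size=rng.integers(2, 7)))
            res = nearest_orthographic(q, lex)
            dists = {w: osa_oracle(q, w) for w in words}
            dmin = min(dists.values())
            assert res.distance == dmin
            assert set(res.neighbors) == {w for w, d in dists.items() if d == dmin}

    def test_distance_never_increases_with_lexicon_growth(self, tiny_lexicon):
        small = CleanLexicon(tiny_lexicon.words[:2], tiny_lexicon.valences[:2])
        d_small = nearest_orthographic("vacatio", small).distance
        d_big = nearest_orthographic("vacatio", tiny_lexicon).distance
        assert d_big <= d_small


class TestNearestSemantic:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.vecs = {w: rng.normal(size=8) for w in ["alpha", "beta", "gamma", "delta"]}
        self.vals = {"alpha": 2.0, "beta": 4.0, "gamma": 6.0, "delta": 8.0}

    def test_identical_vector_wins(self):
        res = nearest_semantic("query", self.vecs, self.vecs["beta"].copy(), self.vals)
        assert res.neighbors == ("beta",)
        assert res.distance == pytest.approx(0.0, abs=1e-12)
        assert res.neighbor_valence == 4.0

    def test_excluded_hub_gives_runner_up(self):
        res = nearest_semantic("query", self.vecs, self.vecs["beta"].copy(), self.vals,
                               exclusion_list=["beta"])
        assert "beta" not in res.neighbors

    def test_exclusion_empties_lexicon(self):
        with pytest.raises(ValueError, match="empties"):
            nearest_semantic("q", {"a": np.ones(2)}, np.ones(2), {"a": 5.0},
                             exclusion_list=["a"])

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(2)
        from pseudovalence.embeddings import cosine_distance

        for _ in range(10):
            q = rng.normal(size=8)
            res = nearest_semantic("q", self.vecs, q, self.vals)
            dists = {w: cosine_distance(q, v) for w, v in self.vecs.items()}
            assert res.neighbors[0] == min(dists, key=dists.get)
            assert res.distance == pytest.approx(min(dists.values()))


class TestHubReport:
    def test_planted_hub_flagged(self):
        """A lexicon word whose vector points along the dominant direction of
        mean-offset queries becomes everyone's nearest neighbor."""
        rng = np.random.default_rng(3)
        d = 10
        hub_dir = np.ones(d) / np.sqrt(d)
        lex_vecs = {f"w{i}": rng.normal(size=d) for i in range(30)}
        lex_vecs["hubword"] = hub_dir * 0.1
        queries = {f"q{i}": hub_dir * 5 + rng.normal(0, 0.1, size=d) for i in range(40)}
        report = hub_report(list(queries), lex_vecs, queries, share_threshold=0.05)
        top = report.iloc[0]
        assert top["word"] == "hubword" and top["is_hub_candidate"]

    def test_uniform_vectors_no_hub(self):
        rng = np.random.default_rng(4)
        lex_vecs = {f"w{i}": rng.normal(size=30) for i in range(200)}
        queries = {f"q{i}": rng.normal(size=30) for i in range(100)}
        report = hub_report(list(queries), lex_vecs, queries, share_threshold=0.10)
        assert not report["is_hub_candidate"].any()

    def test_single_query(self):
        rng = np.random.default_rng(5)
        lex_vecs = {f"w{i}": rng.normal(size=4) for i in range(5)}
        report = hub_report(["q"], lex_vecs, {"q": rng.normal(size=4)})
        assert report["times_nearest"].sum() == 1 and len(report) == 1


class TestNeighborTable:
    def test_csv_layout(self, tiny_lexicon):
        results = [nearest_orthographic(q, tiny_lexicon) for q in ["bux", "graw"]]
        df = neighbor_table(results)
        assert list(df.columns) == ["query", "neighbors", "distance", "neighbor_valence"]
        assert ";" in df.loc[0, "neighbors"]
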