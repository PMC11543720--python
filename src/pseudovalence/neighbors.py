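"""Orthographic and semantic nearest neighbors of pseudowords in a lexicon.

Orthographic distance is the optimal string alignment (OSA) distance, the
restricted Damerau-Levenshtein edit distance: insertions, deletions,
substitutions and adjacent transpositions, with the restriction that a
transposed substring is never edited again.  All unit edit costs.  Because
OSA is integer-valued, a query typically ties with several words at the
minimal distance; the neighbor-valence predictor averages their norm values.

Semantic distance is cosine distance between the query's composed subword
vector and stored word vectors.  Lexicon words that sit near the fringe of
the embedding space can become the nearest neighbor of a disproportionate
share of queries (hubs) and ruin the predictor; ``hub_report`` flags such
words so they can be placed on an explicit exclusion list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .embeddings import cosine_distance
from .form_features import CleanLexicon


@dataclass(frozen=True)
class NeighborResult:
    query: str
    neighbors: tuple[str, ...]
    distance: float
    neighbor_valence: float

    def __post_init__(self) -> None:
        if not self.neighbors:
            raise ValueError("a neighbor result must name at least one neighbor")


def osa_distance(s1: str, s2: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance."""
    n1, n2 = len(s1), len(s2)
    if n1 == 0:
        return n2
    if n2 == 0:
        return n1
    prev2: list[int] | None = None
    prev = list(range(n2 + 1))
    for i in range(1, n1 + 1):
        cur = [i] + [0] * n2
        c1 = s1[i - 1]
        for j in range(1, n2 + 1):
            cost = 0 if c1 == s2[j - 1] else 1
            best = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and c1 == s2[j - 2]
                and s1[i - 2] == s2[j - 1]
            ):
                assert prev2 is not None
                best = min(best, prev2[j - 2] + 1)
            cur[j] = best
        prev2, prev = prev, cur
    return prev[n2]


def nearest_orthographic(query: str, lexicon: CleanLexicon) -> NeighborResult:
    """All lexicon words at minimal OSA distance; mean valence over ties."""
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    best_d = None
    ties: list[int] = []
    for idx, word in enumerate(lexicon.words):
        d = osa_distance(query, word)
        if best_d is None or d < best_d:
            best_d = d
            ties = [idx]
        elif d == best_d:
            ties.append(idx)
    valences = [lexicon.valences[i] for i in ties]
    return NeighborResult(
        query=query,
        neighbors=tuple(lexicon.words[i] for i in ties),
        distance=float(best_d),
        neighbor_valence=float(np.mean(valences)),
    )


def nearest_semantic(
    query: str,
    lexicon_vectors: Mapping[str, np.ndarray],
    query_vector: np.ndarray,
    valences: Mapping[str, float],
    exclusion_list: Sequence[str] = (),
    tie_tol: float = 1e-12,
) -> NeighborResult:
    """Nearest lexicon word by cosine distance to the composed query vector.

    Words on the exclusion list (configured hubs) are skipped.  Exact ties
    (within ``tie_tol``) are all returned with their mean valence, though
    with real-valued vectors a unique winner is the norm.
    """
    excluded = set(exclusion_list)
    words = [w for w in lexicon_vectors if w not in excluded]
    if not words:
        raise ValueError("exclusion list empties the lexicon")
    dists = np.array([cosine_distance(query_vector, lexicon_vectors[w]) for w in words])
    best = dists.min()
    ties = [w for w, d in zip(words, dists) if d <= best + tie_tol]
    vals = [valences[w] for w in ties]
    return NeighborResult(
        query=query,
        neighbors=tuple(ties),
        distance=float(best),
        neighbor_valence=float(np.mean(vals)),
    )


def hub_report(
    queries: Sequence[str],
    lexicon_vectors: Mapping[str, np.ndarray],
    query_vectors: Mapping[str, np.ndarray],
    share_threshold: float = 0.05,
) -> pd.DataFrame:
    """How often each lexicon word is a query's single nearest semantic neighbor.

    Returns a table (word, times_nearest, share, is_hub_candidate) sorted by
    share.  Flagged words are candidates for the semantic exclusion list;
    exclusion itself stays a configuration decision.
    """
    if not queries:
        raise ValueError("need at least one query")
    words = list(lexicon_vectors)
    mat = np.stack([lexicon_vectors[w] for w in words]).astype(np.float64)
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        raise ValueError("lexicon contains a zero vector")
    counts: dict[str, int] = {}
    for q in queries:
        qv = np.asarray(query_vectors[q], dtype=np.float64)
        qn = np.linalg.norm(qv)
        if qn == 0:
            raise ValueError(f"zero query vector for {q!r}")
        sims = mat @ qv / (norms * qn)
        w = words[int(np.argmax(sims))]
        counts[w] = counts.get(w, 0) + 1
    rows = [
        {
            "word": w,
            "times_nearest": c,
            "share": c / len(queries),
            "is_hub_candidate": c / len(queries) > share_threshold,
        }
        for w, c in counts.items()
    ]
    return pd.DataFrame(rows).sort_values("share", ascending=False).reset_index(drop=True)


def neighbor_table(results: Sequence[NeighborResult]) -> pd.DataFrame:
    """CSV-ready table: query, semicolon-joined neighbors, distance, valence."""
    return pd.DataFrame(
        {
            "query": [r.query for r in results],
            "neighbors": [";".join(r.neighbors) for r in results],
            "distance": [r.distance for r in results],
            "neighbor_valence": [r.neighbor_valence for r in results],
        }
    )
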