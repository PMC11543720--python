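"""Subword n-gram embedding tables and vector composition.

Any letter string receives a semantic vector by wrapping it in boundary
markers ('<' ... '>'), extracting every contiguous character 4-gram of the
wrapped string, and summing the vectors stored for those 4-grams.  This is
the standard subword-composition scheme that lets a distributional model
assign meaning representations to out-of-vocabulary strings such as
pseudowords.  Tables may additionally carry whole-word vectors; whether a
whole-word vector exists for a string is itself informative (a pseudoword
with one likely occurred in the training corpus by typo) and is exposed for
candidate filtering.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

logger = logging.getLogger(__name__)

BOUNDARY_START = "<"
BOUNDARY_END = ">"


def extract_ngrams(string: str, n: int = 4) -> list[str]:
    """All contiguous ``n``-grams of ``<string>`` (boundary-wrapped), in order.

    Duplicates are retained.  If the wrapped string is shorter than ``n`` the
    whole wrapped string is returned as the single gram.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not string:
        raise ValueError("string must be non-empty")
    wrapped = BOUNDARY_START + string + BOUNDARY_END
    if len(wrapped) <= n:
        return [wrapped]
    return [wrapped[i : i + n] for i in range(len(wrapped) - n + 1)]


@dataclass
class EmbeddingTable:
    """Fixed-dimension vectors for character n-grams and (optionally) words."""

    dimension: int
    ngram_vectors: dict[str, np.ndarray] = field(default_factory=dict)
    word_vectors: dict[str, np.ndarray] = field(default_factory=dict)
    n: int = 4

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be positive")
        for key, vec in list(self.ngram_vectors.items()) + list(self.word_vectors.items()):
            if len(vec) != self.dimension:
                raise ValueError(f"vector for {key!r} has length {len(vec)}, expected {self.dimension}")

    def has_whole_word_vector(self, string: str) -> bool:
        return string in self.word_vectors

    def is_composable(self, string: str) -> bool:
        """True if at least one n-gram of the string is in the table."""
        try:
            grams = extract_ngrams(string, self.n)
        except ValueError:
            return False
        return any(g in self.ngram_vectors for g in grams)

    def compose(self, string: str, include_word_vector: bool = False, mean: bool = False) -> np.ndarray:
        """Sum the available n-gram vectors of ``string``.

        Missing n-grams contribute nothing (counted and logged); if none of
        the extracted n-grams is in the table the string is not composable.
        ``include_word_vector`` adds the stored whole-word vector when one
        exists.  ``mean`` divides by the number of summed vectors instead of
        returning the raw sum (off by default; the sum is the composition the
        models here are defined on).
        """
        grams = extract_ngrams(string, self.n)
        total = np.zeros(self.dimension, dtype=np.float64)
        n_used = 0
        n_missing = 0
        for g in grams:
            vec = self.ngram_vectors.get(g)
            if vec is None:
                n_missing += 1
            else:
                total += vec
                n_used += 1
        if include_word_vector and string in self.word_vectors:
            total += self.word_vectors[string]
            n_used += 1
        if n_used == 0:
            raise ValueError(f"string not composable: no n-grams of {string!r} in table")
        if n_missing:
            logger.debug("compose(%r): %d of %d n-grams missing", string, n_missing, len(grams))
        if mean:
            total /= n_used
        return total


def cosine_distance(v1: np.ndarray, v2: np.ndarray) -> float:
    """1 - cosine similarity; in [0, 2].  Errors on zero vectors."""
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal dimension")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(v1, v2) / (n1 * n2))


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def load_embedding_table(path, restrict_to: set[str] | None = None, n: int = 4) -> EmbeddingTable:
    """Read a word2vec-style text table (header ``count dim``, one key per line).

    Keys containing boundary markers go to ``ngram_vectors``, the rest to
    ``word_vectors``.  ``restrict_to`` keeps memory bounded by loading only
    the listed keys.  A line whose float count does not match the header
    dimension raises with the line number.
    """
    with _open_text(path, "r") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("malformed header: expected 'count dim'")
        dim = int(header[1])
        ngrams: dict[str, np.ndarray] = {}
        words: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if not parts or parts[0] == "":
                continue
            key = parts[0]
            if restrict_to is not None and key not in restrict_to:
                continue
            values = parts[1:]
            if len(values) != dim:
                raise ValueError(f"line {lineno}: expected {dim} values, got {len(values)}")
            vec = np.asarray([float(x) for x in values], dtype=np.float64)
            if BOUNDARY_START in key or BOUNDARY_END in key:
                ngrams[key] = vec
            else:
                words[key] = vec
    return EmbeddingTable(dimension=dim, ngram_vectors=ngrams, word_vectors=words, n=n)


def save_embedding_table(table: EmbeddingTable, path, fmt: str = "%.6g") -> None:
    """Write a table in the word2vec text format read by load_embedding_table."""
    keys: list[tuple[str, np.ndarray]] = list(table.ngram_vectors.items()) + list(table.word_vectors.items())
    with _open_text(path, "w") as fh:
        fh.write(f"{len(keys)} {table.dimension}\n")
        for key, vec in keys:
            fh.write(key + " " + " ".join(fmt % x for x in vec) + "\n")
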