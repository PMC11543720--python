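"""Surface-form predictors for letter strings.

Words and pseudowords are represented by counts of the letters they contain,
counts of their interior bigrams (ordered pairs of adjacent letters), and
indicator flags for their first and last letter.  These blocks combine into
the design matrices of the form->valence regression models:

* letters only                       -> 26 columns
* letters + bigrams + boundaries     -> 754 columns (26 + 676 + 26 + 26)
* all of the above + D semantic dims -> 754 + D columns (1,054 at D = 300)

Boundary information is kept as separate start/end indicator blocks rather
than as extra bigram columns, which is the only reading consistent with the
754-predictor arithmetic.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .embeddings import EmbeddingTable

logger = logging.getLogger(__name__)

ALPHABET = string.ascii_lowercase
N_LETTERS = 26
N_BIGRAMS = 676

_WORD_RE = re.compile(r"^[a-z]+$")
_LETTER_INDEX = {c: i for i, c in enumerate(ALPHABET)}

LETTER_LABELS = list(ALPHABET)
BIGRAM_LABELS = [a + b for a in ALPHABET for b in ALPHABET]
START_LABELS = ["<" + c for c in ALPHABET]
END_LABELS = [c + ">" for c in ALPHABET]


@dataclass(frozen=True)
class CleanLexicon:
    """A cleaned word->valence norm set (ratings on a 1-9 scale)."""

    words: tuple[str, ...]
    valences: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.words) != len(self.valences):
            raise ValueError("words and valences must have equal length")
        seen = set()
        for w in self.words:
            if not _WORD_RE.match(w):
                raise ValueError(f"invalid word in lexicon: {w!r}")
            if w in seen:
                raise ValueError(f"duplicate word in lexicon: {w!r}")
            seen.add(w)
        for v in self.valences:
            if not (1.0 <= v <= 9.0):
                raise ValueError(f"valence {v} outside the 1-9 rating scale")

    def __len__(self) -> int:
        return len(self.words)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.words, self.valences))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"word": self.words, "valence": self.valences})


@dataclass(frozen=True)
class FeatureSetSpec:
    """Which predictor blocks a design matrix includes.

    Column order is fixed: letters a..z, bigrams aa..zz (row-major), start
    indicators <a..<z, end indicators a>..z>, then embedding dimensions.
    """

    include_letters: bool = False
    include_bigrams: bool = False
    include_boundaries: bool = False
    include_dimensions: bool = False
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (
            self.include_letters
            or self.include_bigrams
            or self.include_boundaries
            or self.include_dimensions
        ):
            raise ValueError("feature set must include at least one block")

    def n_columns(self, n_dims: int = 0) -> int:
        n = 0
        if self.include_letters:
            n += N_LETTERS
        if self.include_bigrams:
            n += N_BIGRAMS
        if self.include_boundaries:
            n += 2 * N_LETTERS
        if self.include_dimensions:
            if n_dims <= 0:
                raise ValueError("n_dims must be positive when dimensions are included")
            n += n_dims
        return n

    def column_labels(self, n_dims: int = 0) -> list[str]:
        labels: list[str] = []
        if self.include_letters:
            labels += LETTER_LABELS
        if self.include_bigrams:
            labels += BIGRAM_LABELS
        if self.include_boundaries:
            labels += START_LABELS + END_LABELS
        if self.include_dimensions:
            labels += [f"dim{i + 1}" for i in range(n_dims)]
        return labels


#: The seven predictor combinations compared in the word-norm experiment.
#: Boundary indicators travel with the bigram block (a boundary flag is a
#: word-edge "bigram"); the letters-only model is the bare 26 counts.  Note
#: that interior bigrams plus boundary flags linearly determine the letter
#: counts, so the bigram models nest the letters model.
SEVEN_SPECS: dict[str, FeatureSetSpec] = {
    "letters": FeatureSetSpec(include_letters=True, name="letters"),
    "bigrams": FeatureSetSpec(include_bigrams=True, include_boundaries=True, name="bigrams"),
    "dimensions": FeatureSetSpec(include_dimensions=True, name="dimensions"),
    "letters+bigrams": FeatureSetSpec(
        include_letters=True, include_bigrams=True, include_boundaries=True,
        name="letters+bigrams",
    ),
    "letters+dimensions": FeatureSetSpec(
        include_letters=True, include_dimensions=True,
        name="letters+dimensions",
    ),
    "bigrams+dimensions": FeatureSetSpec(
        include_bigrams=True, include_boundaries=True, include_dimensions=True,
        name="bigrams+dimensions",
    ),
    "full": FeatureSetSpec(
        include_letters=True, include_bigrams=True, include_boundaries=True,
        include_dimensions=True, name="full",
    ),
}


def _validate_word(word: str) -> None:
    if not word:
        raise ValueError("word must be non-empty")
    for ch in word:
        if ch not in _LETTER_INDEX:
            raise ValueError(f"invalid character {ch!r} in word {word!r}")


def clean_lexicon(raw_entries: Iterable[tuple[str, float]]) -> CleanLexicon:
    """Drop entries with punctuation, capitals or whitespace, and duplicates.

    Duplicate words keep the first occurrence.  The number of removed entries
    is logged.  Raises if nothing survives.
    """
    words: list[str] = []
    valences: list[float] = []
    seen: set[str] = set()
    n_raw = 0
    for word, valence in raw_entries:
        n_raw += 1
        if not isinstance(word, str) or not _WORD_RE.match(word):
            continue
        if word in seen:
            continue
        v = float(valence)
        seen.add(word)
        words.append(word)
        valences.append(v)
    if n_raw == 0:
        raise ValueError("raw entry list is empty")
    if not words:
        raise ValueError("no valid entries after cleaning")
    n_removed = n_raw - len(words)
    logger.info("clean_lexicon: kept %d of %d entries (%d removed)", len(words), n_raw, n_removed)
    return CleanLexicon(tuple(words), tuple(valences))


def letter_counts(word: str) -> np.ndarray:
    """Count occurrences of each letter a..z (counts, not indicators)."""
    _validate_word(word)
    counts = np.zeros(N_LETTERS, dtype=np.int64)
    for ch in word:
        counts[_LETTER_INDEX[ch]] += 1
    return counts


def bigram_counts(word: str) -> np.ndarray:
    """Count interior adjacent letter pairs, ordered aa..zz row-major."""
    _validate_word(word)
    counts = np.zeros(N_BIGRAMS, dtype=np.int64)
    for a, b in zip(word, word[1:]):
        counts[_LETTER_INDEX[a] * N_LETTERS + _LETTER_INDEX[b]] += 1
    return counts


def boundary_indicators(word: str) -> tuple[np.ndarray, np.ndarray]:
    """Indicator flags for the first and last letter (one each)."""
    _validate_word(word)
    start = np.zeros(N_LETTERS, dtype=np.int64)
    end = np.zeros(N_LETTERS, dtype=np.int64)
    start[_LETTER_INDEX[word[0]]] = 1
    end[_LETTER_INDEX[word[-1]]] = 1
    return start, end


def form_feature_vector(word: str) -> np.ndarray:
    """Full 754-slot surface vector: letters, bigrams, start, end."""
    start, end = boundary_indicators(word)
    return np.concatenate([letter_counts(word), bigram_counts(word), start, end])


def build_design_matrix(
    words: Sequence[str],
    spec: FeatureSetSpec,
    embeddings: "EmbeddingTable | None" = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the design matrix for ``words`` under ``spec``.

    Rows follow the input order; columns follow the FeatureSetSpec ordering.
    When semantic dimensions are requested every word must be composable from
    the embedding table, otherwise an error lists the offending word.
    """
    if spec.include_dimensions and embeddings is None:
        raise ValueError("spec includes dimensions but no embedding table was given")
    blocks: list[np.ndarray] = []
    n = len(words)
    if spec.include_letters:
        blocks.append(np.stack([letter_counts(w) for w in words]) if n else np.empty((0, N_LETTERS)))
    if spec.include_bigrams:
        blocks.append(np.stack([bigram_counts(w) for w in words]) if n else np.empty((0, N_BIGRAMS)))
    if spec.include_boundaries:
        bounds = [np.concatenate(boundary_indicators(w)) for w in words]
        blocks.append(np.stack(bounds) if n else np.empty((0, 2 * N_LETTERS)))
    n_dims = 0
    if spec.include_dimensions:
        assert embeddings is not None
        n_dims = embeddings.dimension
        vecs = []
        for w in words:
            try:
                vecs.append(embeddings.compose(w))
            except ValueError as exc:
                raise ValueError(f"word not composable from embeddings: {w!r}") from exc
        blocks.append(np.stack(vecs) if n else np.empty((0, n_dims)))
    matrix = np.hstack(blocks).astype(np.float64) if blocks else np.empty((n, 0))
    return matrix, spec.column_labels(n_dims)


def design_matrix_frame(
    words: Sequence[str],
    spec: FeatureSetSpec,
    embeddings: "EmbeddingTable | None" = None,
) -> pd.DataFrame:
    """Design matrix as a DataFrame (words as index), e.g. for CSV export."""
    matrix, labels = build_design_matrix(words, spec, embeddings)
    return pd.DataFrame(matrix, index=list(words), columns=labels)


def read_norms(path, word_col: str = "Word", valence_col: str = "V.Mean.Sum") -> list[tuple[str, float]]:
    """Read a valence-norms table (CSV or TSV by extension) to raw entries."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    if word_col not in df.columns or valence_col not in df.columns:
        raise ValueError(f"norms file lacks columns {word_col!r}/{valence_col!r}")
    return list(zip(df[word_col].astype(str), df[valence_col].astype(float)))
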