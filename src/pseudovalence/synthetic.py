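"""Synthetic worlds for the pseudoword-valence pipeline.

Every input the pipeline consumes can be generated here with planted ground
truth, so all stages are testable end-to-end without any download:

* a lexicon of random letter strings whose latent valence combines a scale
  anchor, per-letter effects, a latent semantic score and Gaussian noise
  (clipped to the 1-9 rating scale);
* a character-4-gram embedding table whose word vectors (4-gram sums by
  construction) project onto a known weight vector approximately equal to
  each word's latent semantic score, so a dimensions-based regression can
  recover planted signal;
* pseudoword candidates spliced from lexicon words (a deliberately naive
  stand-in for phonotactic generators — candidates inherit the lexicon's
  letter statistics but no readability guarantees);
* simulated best-worst raters: per trial, item utilities are latent valence
  plus Gumbel noise (so best choices are multinomial-logit), with a
  configurable fraction of non-compliant participants answering uniformly
  at random, catch trials included.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .bws import ChoiceRecord
from .embeddings import EmbeddingTable, extract_ngrams
from .form_features import ALPHABET, CleanLexicon, letter_counts
from .stimulus_design import CatchTrial, Session, TrialSet


@dataclass(frozen=True)
class SimulationConfig:
    n_words: int = 5000
    word_length: tuple[int, int] = (3, 8)
    alphabet: str = string.ascii_lowercase
    letter_effect_sd: float = 0.15
    dimension_effect_sd: float = 0.5
    n_dims: int = 300
    noise_sd: float = 0.5
    valence_anchor: float = 5.0
    rater_noise: float = 0.25
    compliance_rate: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("letter_effect_sd", "dimension_effect_sd", "noise_sd", "rater_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.compliance_rate <= 1.0):
            raise ValueError("compliance_rate must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.word_length[0] < 1 or self.word_length[1] < self.word_length[0]:
            raise ValueError("invalid word_length range")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class LexiconGroundTruth:
    letter_effects: np.ndarray          # 26 per-letter valence effects
    semantic_scores: np.ndarray         # per-word latent semantic component
    latent_valence: np.ndarray          # per-word valence before clipping


def generate_lexicon(config: SimulationConfig) -> tuple[CleanLexicon, LexiconGroundTruth]:
    """Random lexicon with planted letter-level and semantic valence structure.

    latent = anchor + sum_letters effect(l)*count(l) + semantic_score + noise,
    clipped to [1, 9].  The ground truth is returned for recovery tests.
    """
    if config.n_words < 1:
        raise ValueError("n_words must be >= 1")
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(config.alphabet))
    lo, hi = config.word_length
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < config.n_words:
        length = int(rng.integers(lo, hi + 1))
        w = "".join(rng.choice(letters, size=length))
        if w not in seen:
            seen.add(w)
            words.append(w)
    letter_effects = np.zeros(26)
    idx = [ALPHABET.index(c) for c in config.alphabet]
    letter_effects[idx] = rng.normal(0.0, config.letter_effect_sd, size=len(idx))
    counts = np.stack([letter_counts(w) for w in words])
    semantic = rng.normal(0.0, config.dimension_effect_sd, size=len(words))
    noise = rng.normal(0.0, config.noise_sd, size=len(words))
    latent = config.valence_anchor + counts @ letter_effects + semantic + noise
    valence = np.clip(latent, 1.0, 9.0)
    lexicon = CleanLexicon(tuple(words), tuple(float(v) for v in valence))
    truth = LexiconGroundTruth(letter_effects=letter_effects, semantic_scores=semantic,
                               latent_valence=latent)
    return lexicon, truth


def generate_embedding_table(
    config: SimulationConfig,
    lexicon: CleanLexicon,
    truth: LexiconGroundTruth,
    n_correction_passes: int = 25,
) -> tuple[EmbeddingTable, np.ndarray]:
    """4-gram table whose word-vector projections track the semantic scores.

    Each 4-gram starts as an independent Gaussian vector; an iterative
    correction then nudges gram components along a known unit weight vector
    ``w`` so that each word's gram-sum projects approximately onto its
    planted semantic score.  Word vectors are stored as the exact gram sums
    (compose == stored vector by construction).  Returns (table, w).
    """
    if config.n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    rng = np.random.default_rng(config.seed + 1)
    d = config.n_dims
    grams_per_word = [extract_ngrams(w, 4) for w in lexicon.words]
    all_grams = sorted({g for grams in grams_per_word for g in grams})
    gram_idx = {g: i for i, g in enumerate(all_grams)}
    vecs = rng.normal(0.0, 1.0 / np.sqrt(d), size=(len(all_grams), d))
    w = rng.normal(size=d)
    w /= np.linalg.norm(w)
    targets = truth.semantic_scores
    if config.dimension_effect_sd > 0:
        # Jacobi-style passes: distribute each word's projection residual
        # over its grams, averaging over the words sharing each gram.
        for _ in range(n_correction_passes):
            proj = np.array([vecs[[gram_idx[g] for g in grams]].sum(axis=0) @ w
                             for grams in grams_per_word])
            resid = targets - proj
            delta = np.zeros(len(all_grams))
            counts = np.zeros(len(all_grams))
            for word_i, grams in enumerate(grams_per_word):
                share = resid[word_i] / len(grams)
                for g in grams:
                    delta[gram_idx[g]] += share
                    counts[gram_idx[g]] += 1
            np.divide(delta, counts, out=delta, where=counts > 0)
            vecs += 0.9 * np.outer(delta, w)
    ngram_vectors = {g: vecs[i].copy() for g, i in gram_idx.items()}
    word_vectors = {
        word: vecs[[gram_idx[g] for g in grams]].sum(axis=0)
        for word, grams in zip(lexicon.words, grams_per_word)
    }
    table = EmbeddingTable(dimension=d, ngram_vectors=ngram_vectors,
                           word_vectors=word_vectors, n=4)
    return table, w


def generate_candidates(lexicon: CleanLexicon, n: int, seed: int = 0) -> list[str]:
    """Pseudoword candidates: splice halves of two words or substitute one
    letter; strings equal to lexicon words are rejected.  Duplicates allowed
    (downstream filtering handles them)."""
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    rng = np.random.default_rng(seed)
    words = lexicon.words
    lex_set = set(words)
    letters = list(string.ascii_lowercase)
    out: list[str] = []
    while len(out) < n:
        if rng.random() < 0.5 and len(words) >= 2:
            i, j = rng.integers(len(words), size=2)
            a, b = words[int(i)], words[int(j)]
            cand = a[: max(1, len(a) // 2)] + b[len(b) // 2 :]
        else:
            wsrc = words[int(rng.integers(len(words)))]
            pos = int(rng.integers(len(wsrc)))
            cand = wsrc[:pos] + letters[int(rng.integers(26))] + wsrc[pos + 1 :]
        if cand not in lex_set and len(cand) >= 2:
            out.append(cand)
    return out


def make_catch_trials(seed: int = 0, trial_size: int = 6) -> tuple[list[CatchTrial], dict[str, float]]:
    """Four known-answer trials from synthetic 'real words' with extreme vs
    neutral valences.  Returns the trials and the words' latent valences
    (used by the rater simulator)."""
    rng = np.random.default_rng(seed)
    positives = ["joyfest", "blissom", "sunhome", "lovenia"]
    negatives = ["murkrot", "dreadon", "gloomax", "torvile"]
    neutrals = [f"neut{chr(97 + i)}{chr(97 + i)}" for i in range(4 * (trial_size - 2))]
    latent: dict[str, float] = {}
    for wrd in positives:
        latent[wrd] = float(rng.normal(8.5, 0.1))
    for wrd in negatives:
        latent[wrd] = float(rng.normal(1.5, 0.1))
    for wrd in neutrals:
        latent[wrd] = float(rng.normal(5.0, 0.1))
    trials = []
    for t in range(4):
        fillers = neutrals[t * (trial_size - 2) : (t + 1) * (trial_size - 2)]
        items = [positives[t]] + fillers + [negatives[t]]
        order = rng.permutation(len(items))
        items = [items[i] for i in order]
        trials.append(CatchTrial(items=tuple(items),
                                 designated_positive=positives[t],
                                 designated_negative=negatives[t]))
    return trials, latent


def catch_key_map(catch: Sequence[CatchTrial]) -> dict[tuple[str, ...], tuple[str, str]]:
    return {tuple(sorted(c.items)): (c.designated_positive, c.designated_negative)
            for c in catch}


def simulate_raters(
    trials: "TrialSet | Sequence[Session]",
    latent: Mapping[str, float],
    config: SimulationConfig,
) -> list[ChoiceRecord]:
    """Simulate best-worst choices from latent item values.

    Per trial, utility_i = latent_i + Gumbel(0, rater_noise); best is the
    argmax and worst the argmin of the remaining items.  With probability
    (1 - compliance_rate), a participant answers every trial — catch trials
    included — uniformly at random.  Given a bare TrialSet each trial is its
    own single-trial 'participant'.
    """
    rng = np.random.default_rng(config.seed + 2)
    if isinstance(trials, TrialSet):
        sessions = [Session(session_id=i, trials=[t], is_catch=[False])
                    for i, t in enumerate(trials.trials)]
    else:
        sessions = list(trials)
    records: list[ChoiceRecord] = []
    for sess in sessions:
        compliant = rng.random() < config.compliance_rate
        pid = f"p{sess.session_id}"
        for trial, is_catch in zip(sess.trials, sess.is_catch):
            missing = [i for i in trial if i not in latent]
            if missing:
                raise ValueError(f"no latent value for items: {missing}")
            if compliant:
                base = np.array([latent[i] for i in trial])
                if config.rater_noise > 0:
                    base = base + rng.gumbel(0.0, config.rater_noise, size=len(trial))
                best_i = int(np.argmax(base))
                rest = [j for j in range(len(trial)) if j != best_i]
                worst_i = rest[int(np.argmin(base[rest]))]
            else:
                best_i, worst_i = rng.choice(len(trial), size=2, replace=False)
            records.append(
                ChoiceRecord(
                    participant_id=pid,
                    items=tuple(trial),
                    best=trial[int(best_i)],
                    worst=trial[int(worst_i)],
                    is_catch=bool(is_catch),
                )
            )
    return records
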