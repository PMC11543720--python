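"""Candidate filtering, valence-stratified sampling, and best-worst trial design.

A candidate pseudoword pool is filtered (duplicates; strings the embedding
table already knows as whole words, which likely entered the training corpus
as typos), sampled so predicted valence covers its range as uniformly as
possible (equal-width slices of the range, random within slice), and the
selected items are assigned to best-worst trials: every item appears exactly
``appearances`` times, ``trial_size`` items per trial, no item twice within
a trial.  Trials are partitioned into per-participant sessions, each of
which additionally receives the same known-answer catch trials used to
screen out non-compliant raters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Candidate:
    string: str
    predicted_valence: float
    excluded: str | None = None  # 'whole_word_vector' | 'duplicate' | 'manual'


@dataclass
class CandidatePool:
    candidates: list[Candidate]

    @property
    def eligible(self) -> list[Candidate]:
        return [c for c in self.candidates if c.excluded is None]

    def exclusion_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.candidates:
            if c.excluded is not None:
                counts[c.excluded] = counts.get(c.excluded, 0) + 1
        return counts


@dataclass(frozen=True)
class CatchTrial:
    """A known-answer trial: one clearly positive word, one clearly negative,
    neutral fillers.  Used only for compliance screening, never scored."""

    items: tuple[str, ...]
    designated_positive: str
    designated_negative: str

    def __post_init__(self) -> None:
        if self.designated_positive not in self.items or self.designated_negative not in self.items:
            raise ValueError("designated items must be members of the trial")
        if self.designated_positive == self.designated_negative:
            raise ValueError("designated positive and negative must differ")


@dataclass
class TrialSet:
    trials: list[tuple[str, ...]]
    appearances: int
    trial_size: int

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for t in self.trials:
            if len(set(t)) != len(t):
                raise ValueError(f"trial contains a duplicate item: {t}")
            if len(t) != self.trial_size:
                raise ValueError("trial has wrong size")
            for item in t:
                counts[item] = counts.get(item, 0) + 1
        bad = {w: c for w, c in counts.items() if c != self.appearances}
        if bad:
            raise ValueError(f"appearance counts violated for {len(bad)} items")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def items(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            for item in t:
                seen.setdefault(item)
        return list(seen)


@dataclass
class Session:
    session_id: int
    trials: list[tuple[str, ...]]  # presentation order, catch trials included
    is_catch: list[bool]

    def __post_init__(self) -> None:
        if len(self.trials) != len(self.is_catch):
            raise ValueError("is_catch flags misaligned with trials")


def filter_candidates(strings: Sequence[str], embeddings) -> CandidatePool:
    """Mark duplicates (after the first) and strings with whole-word vectors."""
    seen: set[str] = set()
    out: list[Candidate] = []
    for s in strings:
        if s in seen:
            out.append(Candidate(s, float("nan"), excluded="duplicate"))
            continue
        seen.add(s)
        if embeddings is not None and embeddings.has_whole_word_vector(s):
            out.append(Candidate(s, float("nan"), excluded="whole_word_vector"))
        else:
            out.append(Candidate(s, float("nan")))
    pool = CandidatePool(out)
    if not pool.eligible:
        logger.warning("filter_candidates: no eligible candidates survive")
    logger.info("filter_candidates: %d eligible, exclusions %s", len(pool.eligible), pool.exclusion_counts())
    return pool


def with_predicted_valence(pool: CandidatePool, predicted: dict[str, float]) -> CandidatePool:
    """Attach predicted valences to a pool's eligible candidates."""
    out = []
    for c in pool.candidates:
        if c.excluded is None:
            out.append(Candidate(c.string, float(predicted[c.string])))
        else:
            out.append(c)
    return CandidatePool(out)


def stratified_uniform_sample(
    pool: CandidatePool,
    n_target: int,
    n_slices: int = 25,
    exclusion_list: Sequence[str] = (),
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Sample ``n_target`` items so predicted valence is near-uniform.

    The predicted-valence range of the eligible pool is cut into ``n_slices``
    equal-width intervals; items are drawn at random per slice, topping up
    from the nearest non-exhausted slices when one runs dry.  Items on the
    exclusion list (the stand-in for manual removal of unreadable strings
    and pseudocompounds) are never sampled.  Returns the sampled strings and
    the per-slice counts of the sample.
    """
    rng = np.random.default_rng(seed)
    excluded = set(exclusion_list)
    elig = [c for c in pool.eligible if c.string not in excluded]
    if n_target > len(elig):
        raise ValueError(f"n_target={n_target} exceeds eligible pool size {len(elig)}")
    vals = np.array([c.predicted_valence for c in elig])
    if np.unique(vals).size < 2:
        raise ValueError("eligible pool spans a single predicted valence; cannot stratify")
    lo, hi = vals.min(), vals.max()
    edges = np.linspace(lo, hi, n_slices + 1)
    slice_of = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_slices - 1)
    by_slice: list[list[int]] = [[] for _ in range(n_slices)]
    for i, s in enumerate(slice_of):
        by_slice[int(s)].append(i)
    for bucket in by_slice:
        rng.shuffle(bucket)

    base, extra = divmod(n_target, n_slices)
    quota = np.full(n_slices, base, dtype=int)
    # spread the remainder over randomly chosen slices
    if extra:
        quota[rng.choice(n_slices, size=extra, replace=False)] += 1

    chosen: list[int] = []
    counts = np.zeros(n_slices, dtype=int)
    deficit = 0
    for s in range(n_slices):
        take = min(quota[s], len(by_slice[s]))
        chosen.extend(by_slice[s][:take])
        by_slice[s] = by_slice[s][take:]
        counts[s] = take
        deficit += quota[s] - take
    # top up exhausted slices from the nearest slices that still have items
    while deficit > 0:
        remaining = [s for s in range(n_slices) if by_slice[s]]
        if not remaining:
            raise ValueError("pool exhausted before reaching n_target")
        # pick the remaining slice closest to an under-quota one
        s = remaining[int(rng.integers(len(remaining)))]
        chosen.append(by_slice[s].pop())
        counts[s] += 1
        deficit -= 1
    logger.info("stratified sample: per-slice counts %s", counts.tolist())
    strings = [elig[i].string for i in chosen]
    rng.shuffle(strings)
    return strings, counts


def build_trial_set(
    items: Sequence[str],
    appearances: int = 30,
    trial_size: int = 6,
    seed: int = 0,
    max_repair_sweeps: int = 100,
) -> TrialSet:
    """Assign items to trials: each item exactly ``appearances`` times,
    ``trial_size`` per trial, no within-trial duplicates.

    Construction: concatenate ``appearances`` independent seeded random
    permutations of the items, chunk into trials, then repair any trial
    holding a duplicate by swapping one offender with a compatible member of
    another trial.  Duplicates can only arise at round boundaries, so repair
    converges quickly.
    """
    items = list(items)
    n = len(items)
    if n < trial_size:
        raise ValueError("need at least trial_size distinct items")
    if len(set(items)) != n:
        raise ValueError("items must be distinct")
    total = n * appearances
    if total % trial_size != 0:
        # smallest appearances' >= appearances with n*appearances' % trial_size == 0
        a = appearances + 1
        while (n * a) % trial_size != 0:
            a += 1
        raise ValueError(
            f"{n} items x {appearances} appearances not divisible by trial size "
            f"{trial_size}; smallest compatible appearances is {a}"
        )
    rng = np.random.default_rng(seed)
    seq: list[str] = []
    for _ in range(appearances):
        perm = rng.permutation(n)
        seq.extend(items[i] for i in perm)
    n_trials = total // trial_size
    trials = [seq[t * trial_size : (t + 1) * trial_size] for t in range(n_trials)]

    for _ in range(max_repair_sweeps):
        dirty = False
        for t_idx, trial in enumerate(trials):
            seen: set[str] = set()
            for pos, item in enumerate(trial):
                if item not in seen:
                    seen.add(item)
                    continue
                dirty = True
                # swap this duplicate with a member of a random other trial
                fixed = False
                order = rng.permutation(n_trials)
                for o_idx in order:
                    if o_idx == t_idx:
                        continue
                    other = trials[o_idx]
                    for o_pos, o_item in enumerate(other):
                        if o_item not in trial and item not in (
                            x for k, x in enumerate(other) if k != o_pos
                        ):
                            trial[pos], other[o_pos] = o_item, item
                            seen.add(o_item)
                            fixed = True
                            break
                    if fixed:
                        break
                if not fixed:
                    raise RuntimeError("trial repair failed to find a swap")
        if not dirty:
            break
    else:
        raise RuntimeError("trial repair did not converge")
    return TrialSet([tuple(t) for t in trials], appearances=appearances, trial_size=trial_size)


def assign_sessions(
    trial_set: TrialSet,
    trials_per_participant: int,
    catch: Sequence[CatchTrial] = (),
    seed: int = 0,
) -> list[Session]:
    """Partition experimental trials into disjoint per-participant sessions.

    Every session receives all catch trials; presentation order within a
    session is randomised.  When the trial count is not a multiple of
    ``trials_per_participant`` the final session is short (the alternative
    would repeat trials, distorting appearance counts); the number of
    sessions is the ceiling.
    """
    if trials_per_participant < 1:
        raise ValueError("trials_per_participant must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trial_set.trials))
    shuffled = [trial_set.trials[i] for i in order]
    sessions: list[Session] = []
    n_sessions = -(-len(shuffled) // trials_per_participant)
    if len(shuffled) % trials_per_participant:
        logger.info("assign_sessions: final session is short (%d trials)",
                    len(shuffled) % trials_per_participant)
    for s in range(n_sessions):
        chunk = shuffled[s * trials_per_participant : (s + 1) * trials_per_participant]
        trials = [(t, False) for t in chunk] + [(c.items, True) for c in catch]
        perm = rng.permutation(len(trials))
        trials = [trials[i] for i in perm]
        sessions.append(
            Session(
                session_id=s,
                trials=[t for t, _ in trials],
                is_catch=[flag for _, flag in trials],
            )
        )
    return sessions


def sessions_to_frame(sessions: Sequence[Session]) -> pd.DataFrame:
    """Flatten sessions to the TSV layout: session_id, trial_index, is_catch, item1..itemK."""
    rows = []
    for sess in sessions:
        for idx, (trial, is_catch) in enumerate(zip(sess.trials, sess.is_catch)):
            row = {"session_id": sess.session_id, "trial_index": idx, "is_catch": int(is_catch)}
            for j, item in enumerate(trial, start=1):
                row[f"item{j}"] = item
            rows.append(row)
    return pd.DataFrame(rows)
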