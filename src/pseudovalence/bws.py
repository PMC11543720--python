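"""Best-worst scaling: choice records, value learning, compliance, reliability.

Each best-worst trial yields implied pairwise outcomes: the item chosen as
best beats every other item in the trial, and every item not chosen as worst
beats the worst one (the best-vs-worst pair is counted once).  Items that
were neither chosen nor rejected are not compared with each other.

The value-learning scorer turns these pairwise outcomes into a continuous
scale with an Elo-style update: each item starts at 0.5, and for every
(winner, loser) pair the winner's expected win probability is the logistic

    p = 1 / (1 + 10 ** ((v_loser - v_winner) / s))

after which v_winner += eta * (1 - p) and v_loser -= eta * (1 - p).  Pairs
are visited in seeded random order; the learning rate decays linearly across
passes and the reported score is the mean over the last fraction of passes,
which damps order effects.  The resulting scale has arbitrary location and
spread — downstream analyses only ever use it through correlations and
regressions, which are affine-invariant.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChoiceRecord:
    participant_id: str
    items: tuple[str, ...]
    best: str
    worst: str
    is_catch: bool = False

    def __post_init__(self) -> None:
        if self.best == self.worst:
            raise ValueError("best and worst must differ")
        if self.best not in self.items or self.worst not in self.items:
            raise ValueError("best and worst must be trial members")


@dataclass(frozen=True)
class ValueLearningConfig:
    initial_value: float = 0.5
    eta_start: float = 0.1
    eta_end: float = 0.001
    elo_scale: float = 0.4
    n_passes: int = 100
    average_last_fraction: float = 0.1
    seed: int = 0


@dataclass
class ValueScores:
    scores: dict[str, float]
    config: ValueLearningConfig
    n_best: dict[str, int] = field(default_factory=dict)
    n_worst: dict[str, int] = field(default_factory=dict)
    n_appearances: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.scores)
        return pd.DataFrame(
            {
                "item": items,
                "value_score": [self.scores[i] for i in items],
                "n_best": [self.n_best.get(i, 0) for i in items],
                "n_worst": [self.n_worst.get(i, 0) for i in items],
                "n_appearances": [self.n_appearances.get(i, 0) for i in items],
            }
        )


def implied_pairs(record: ChoiceRecord) -> list[tuple[str, str]]:
    """(winner, loser) pairs implied by one best-worst choice.

    For a trial of k items: best beats the k-1 others; the k-2 middle items
    beat worst.  Middle items are never paired with each other.
    """
    pairs = [(record.best, other) for other in record.items if other != record.best]
    pairs += [
        (middle, record.worst)
        for middle in record.items
        if middle not in (record.best, record.worst)
    ]
    return pairs


def value_learning(
    records: Sequence[ChoiceRecord],
    config: ValueLearningConfig = ValueLearningConfig(),
) -> ValueScores:
    """Score items from best-worst records (catch trials are ignored)."""
    scored = [r for r in records if not r.is_catch]
    if not scored:
        raise ValueError("no non-catch records to score")
    items: dict[str, int] = {}
    for r in scored:
        for item in r.items:
            items.setdefault(item, len(items))
    n_items = len(items)
    if n_items == 0:
        raise ValueError("record item set is empty")

    pairs = np.array(
        [(items[w], items[l]) for r in scored for (w, l) in implied_pairs(r)],
        dtype=np.int64,
    )
    rng = np.random.default_rng(config.seed)
    v = [config.initial_value] * n_items  # plain list: fast scalar indexing
    n_avg = max(1, int(round(config.average_last_fraction * config.n_passes)))
    acc = np.zeros(n_items)
    etas = np.linspace(config.eta_start, config.eta_end, config.n_passes)
    inv_s = 1.0 / config.elo_scale
    winners = pairs[:, 0]
    losers = pairs[:, 1]
    for p_idx in range(config.n_passes):
        eta = etas[p_idx]
        order = rng.permutation(len(pairs))
        for w, l in zip(winners[order].tolist(), losers[order].tolist()):
            p_win = 1.0 / (1.0 + 10.0 ** ((v[l] - v[w]) * inv_s))
            delta = eta * (1.0 - p_win)
            v[w] += delta
            v[l] -= delta
        if p_idx >= config.n_passes - n_avg:
            acc += v
    final = acc / n_avg

    n_best: dict[str, int] = {i: 0 for i in items}
    n_worst: dict[str, int] = {i: 0 for i in items}
    n_app: dict[str, int] = {i: 0 for i in items}
    for r in scored:
        n_best[r.best] += 1
        n_worst[r.worst] += 1
        for item in r.items:
            n_app[item] += 1
    scores = {item: float(final[idx]) for item, idx in items.items()}
    return ValueScores(scores=scores, config=config, n_best=n_best, n_worst=n_worst,
                       n_appearances=n_app)


def best_worst_counting_scores(records: Sequence[ChoiceRecord]) -> dict[str, float]:
    """Simple (best - worst) / appearances baseline scorer (sanity oracle)."""
    best: dict[str, int] = {}
    worst: dict[str, int] = {}
    app: dict[str, int] = {}
    for r in records:
        if r.is_catch:
            continue
        best[r.best] = best.get(r.best, 0) + 1
        worst[r.worst] = worst.get(r.worst, 0) + 1
        for item in r.items:
            app[item] = app.get(item, 0) + 1
    return {
        item: (best.get(item, 0) - worst.get(item, 0)) / app[item] for item in app
    }


def exclude_noncompliant(
    records: Sequence[ChoiceRecord],
    catch_keys: Mapping[tuple[str, ...], tuple[str, str]],
    max_errors: int = 1,
) -> tuple[list[ChoiceRecord], list[str]]:
    """Drop participants who miss catch trials more than ``max_errors`` times.

    ``catch_keys`` maps a catch trial's item set (as a sorted tuple) to its
    (designated_positive, designated_negative).  Choosing best != positive
    and choosing worst != negative each count as one error.
    """
    norm_keys = {tuple(sorted(k)): v for k, v in catch_keys.items()}
    errors: dict[str, int] = {}
    saw_catch: dict[str, bool] = {}
    participants: list[str] = []
    for r in records:
        if r.participant_id not in saw_catch:
            saw_catch[r.participant_id] = False
            participants.append(r.participant_id)
        if not r.is_catch:
            continue
        key = tuple(sorted(r.items))
        if key not in norm_keys:
            raise ValueError(f"unknown catch trial: {r.items}")
        saw_catch[r.participant_id] = True
        pos, neg = norm_keys[key]
        e = int(r.best != pos) + int(r.worst != neg)
        errors[r.participant_id] = errors.get(r.participant_id, 0) + e
    missing = [p for p, saw in saw_catch.items() if not saw]
    if missing:
        raise ValueError(f"participants with no catch records: {missing[:5]}")
    excluded = [p for p in participants if errors.get(p, 0) > max_errors]
    excluded_set = set(excluded)
    kept = [r for r in records if r.participant_id not in excluded_set]
    logger.info("exclude_noncompliant: removed %d of %d participants",
                len(excluded), len(participants))
    return kept, excluded


def split_half_reliability(
    records: Sequence[ChoiceRecord],
    seed: int = 0,
    config: ValueLearningConfig = ValueLearningConfig(),
) -> float:
    """Pearson r between value scores from two random halves of participants.

    Items present in only one half are dropped pairwise (logged).
    """
    participants = sorted({r.participant_id for r in records})
    if len(participants) < 2:
        raise ValueError("need at least two participants")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(participants))
    half = len(participants) // 2
    group_a = {participants[i] for i in perm[:half]}
    recs_a = [r for r in records if r.participant_id in group_a]
    recs_b = [r for r in records if r.participant_id not in group_a]
    cfg_b = dataclasses.replace(config, seed=config.seed + 1)
    scores_a = value_learning(recs_a, config).scores
    scores_b = value_learning(recs_b, cfg_b).scores
    shared = sorted(set(scores_a) & set(scores_b))
    dropped = (set(scores_a) | set(scores_b)) - set(shared)
    if dropped:
        logger.info("split_half_reliability: %d items present in one half only", len(dropped))
    if len(shared) < 3:
        raise ValueError("too few shared items across halves")
    a = np.array([scores_a[i] for i in shared])
    b = np.array([scores_b[i] for i in shared])
    return float(stats.pearsonr(a, b).statistic)


def records_to_frame(records: Sequence[ChoiceRecord]) -> pd.DataFrame:
    rows = []
    for idx, r in enumerate(records):
        row = {"participant_id": r.participant_id, "trial_index": idx,
               "is_catch": int(r.is_catch)}
        for j, item in enumerate(r.items, start=1):
            row[f"item{j}"] = item
        row["best"] = r.best
        row["worst"] = r.worst
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[ChoiceRecord]:
    item_cols = sorted((c for c in df.columns if c.startswith("item")),
                       key=lambda c: int(c[4:]))
    out = []
    for _, row in df.iterrows():
        items = tuple(row[c] for c in item_cols if isinstance(row[c], str))
        out.append(
            ChoiceRecord(
                participant_id=str(row["participant_id"]),
                items=items,
                best=row["best"],
                worst=row["worst"],
                is_catch=bool(row["is_catch"]),
            )
        )
    return out
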