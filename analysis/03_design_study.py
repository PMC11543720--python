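#!/usr/bin/env python
"""Design the pseudoword best-worst study.

Filters candidates, scores them with the selection (full) model, samples
150 items with near-uniform predicted valence across 25 slices, builds the
balanced trial plan (150 items x 30 appearances / 6 per trial = 750 trials)
and partitions it into 45-trial sessions plus four shared catch trials.
Writes per-slice counts and the session TSV.

Run:  python analysis/03_design_study.py [--seed 7]
"""

import argparse
from pathlib import Path

import pandas as pd

from pseudovalence import pipeline
from pseudovalence.stimulus_design import sessions_to_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    world = pipeline.build_synthetic_world("letters", seed=args.seed)
    study = world.study

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame({"slice": range(1, 26), "n_items": study.slice_counts}).to_csv(
        results / "slice_counts.csv", index=False
    )
    scratch = ROOT / "scratch" / "world"
    scratch.mkdir(parents=True, exist_ok=True)
    sessions_to_frame(study.sessions).to_csv(scratch / "sessions.tsv", sep="\t", index=False)

    n_exp = len(study.trial_set)
    print(f"items: {len(study.items)}  trials: {n_exp}  sessions: {len(study.sessions)}")
    print(f"per-slice counts: {study.slice_counts.tolist()}")
    short = [len(s.trials) - sum(s.is_catch) for s in study.sessions]
    print(f"experimental trials per session: {sorted(set(short))} (last session may be short)")
    print(f"catch trials per session: {sum(study.sessions[0].is_catch)}")


if __name__ == "__main__":
    main()
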