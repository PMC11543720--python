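#!/usr/bin/env python
"""Simulate raters, screen compliance, and score the best-worst choices.

Simulated participants (95% compliant, Gumbel rater noise at half the
latent SD) complete the designed sessions; participants missing the catch
trials more than once are excluded; the value-learning scorer converts the
remaining choices into continuous valence indexes.  Reports split-half
reliability and the seven observed ~ predicted regressions; in this
letters-driven world the letters model comes first.

Run:  python analysis/04_score_choices.py [--seed 7]
"""

import argparse
import json
from pathlib import Path

import numpy as np
from scipy import stats

from pseudovalence import pipeline
from pseudovalence.bws import records_to_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    world = pipeline.build_synthetic_world("letters", seed=args.seed)
    exp2 = world.exp2

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    exp2.prediction_table.round(4).to_csv(results / "exp2_prediction_models.csv", index=False)
    scratch = ROOT / "scratch" / "world"
    scratch.mkdir(parents=True, exist_ok=True)
    records_to_frame(world.records).to_csv(scratch / "choices.tsv", sep="\t", index=False)
    exp2.scores.to_frame().round(4).to_csv(scratch / "value_scores.csv", index=False)

    obs = np.array([exp2.scores.scores[i] for i in world.study.items])
    lat = np.array([world.latent[i] for i in world.study.items])
    rho = stats.spearmanr(obs, lat).statistic
    summary = {
        "n_participants": len(world.study.sessions),
        "n_excluded": len(exp2.excluded_participants),
        "split_half_r": round(float(exp2.split_half_r), 3),
        "latent_recovery_rho": round(float(rho), 3),
        "best_model": exp2.prediction_table.iloc[0]["model"],
    }
    (results / "exp2_summary.json").write_text(json.dumps(summary, indent=2))
    print(exp2.prediction_table.round(3).to_string(index=False))
    print("\nsummary:", summary)


if __name__ == "__main__":
    main()
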