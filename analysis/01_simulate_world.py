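#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds the letters-driven synthetic world (a 2,000-word lexicon with
planted per-letter valence effects, a 50-dimensional 4-gram embedding
table, 2,000 spliced pseudoword candidates) and writes the raw artifacts
under scratch/world/ (they are bulky) plus a small summary under results/.

Run:  python analysis/01_simulate_world.py [--seed 7]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from pseudovalence import synthetic
from pseudovalence.embeddings import save_embedding_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    cfg = synthetic.SimulationConfig(
        n_words=2000, n_dims=50, dimension_effect_sd=0.0,
        noise_sd=0.3, letter_effect_sd=0.2, seed=args.seed,
    )
    lexicon, truth = synthetic.generate_lexicon(cfg)
    table, w = synthetic.generate_embedding_table(cfg, lexicon, truth)
    candidates = synthetic.generate_candidates(lexicon, 2000, seed=args.seed + 4)

    scratch = ROOT / "scratch" / "world"
    scratch.mkdir(parents=True, exist_ok=True)
    lexicon.to_frame().to_csv(scratch / "lexicon.csv", index=False)
    save_embedding_table(table, scratch / "embeddings.vec")
    (scratch / "candidates.txt").write_text("\n".join(candidates) + "\n")
    (scratch / "ground_truth.json").write_text(json.dumps({
        "letter_effects": truth.letter_effects.tolist(),
        "dimension_weights": w.tolist(),
    }))

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary = {
        "seed": args.seed,
        "n_words": len(lexicon),
        "n_dims": table.dimension,
        "n_ngram_vectors": len(table.ngram_vectors),
        "n_candidates": len(candidates),
        "valence_mean": round(float(np.mean(lexicon.valences)), 3),
        "valence_sd": round(float(np.std(lexicon.valences)), 3),
    }
    (results / "world_summary.json").write_text(json.dumps(summary, indent=2))
    print("synthetic world:", summary)
    print(f"raw artifacts -> {scratch}")


if __name__ == "__main__":
    main()
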