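# pseudovalence

Do made-up words feel good or bad? Pseudowords — letter strings like
*grawp* or *simmy* that follow a language's orthographic rules but carry no
dictionary meaning — reliably evoke affective judgments, and those
judgments can be predicted from the statistical regularities of existing
words. This package implements the full computational chain for studying
that phenomenon:

1. **Form/semantic valence models on word norms.** Linear models of rated
   valence (1–9 scale) on surface features and embedding dimensions:
   letter counts (26 columns), interior bigram counts plus word-boundary
   indicators (676 + 52 columns; letters + bigrams + boundaries = 754),
   and D semantic dimensions composed from character-4-gram vectors
   (754 + 300 = 1,054 at D = 300). Seven predictor combinations are fitted
   by OLS and compared by R², Pearson r, and AIC.
2. **Subword composition.** Any string `s` gets a semantic vector
   `v(s) = Σ_g v_g` over the 4-grams `g` of `<s>` (boundary-marked), so
   out-of-vocabulary strings are first-class citizens.
3. **Stimulus design.** Candidate pseudowords are filtered (duplicates;
   strings the embedding table already knows as whole words), scored with
   the word-trained model, and sampled so predicted valence is near-uniform
   across 25 slices of its range; items are assigned to balanced best–worst
   trials (each item appears exactly *k* times, 6 items per trial, no
   within-trial repeats) and partitioned into per-participant sessions with
   shared known-answer catch trials.
4. **Best–worst scaling.** Choices are expanded into implied pairwise wins
   (best beats all; everything else beats worst) and scored with an
   Elo-style value-learning algorithm: expected win probability
   `p = 1/(1 + 10^((v_loser − v_winner)/s))`, update `±η(1 − p)`, learning
   rate decaying across passes. Compliance screening (more than one catch
   miss ⇒ exclusion) and split-half reliability are built in.
5. **Neighbor predictors.** Mean valence of the nearest orthographic
   neighbors (optimal string alignment / restricted Damerau–Levenshtein
   distance, ties averaged) and of the nearest semantic neighbor (cosine
   distance, with hub detection and configurable exclusion), alone and
   combined with the letters model via nested F-tests.
6. **Synthetic worlds.** Generators for every input — lexicons with planted
   letter effects, embedding tables with planted valence-carrying
   directions, spliced pseudoword candidates, and simulated raters with
   Gumbel choice noise and configurable compliance — so the whole pipeline
   is validated against known ground truth, no downloads required.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a synthetic
study (2,000-word lexicon, 50 embedding dimensions, 150 pseudoword items,
30 appearances each, 6 per trial, 45 trials per participant):

```bash
python analysis/01_simulate_world.py --seed 7
python analysis/02_fit_word_models.py --seed 7
python analysis/03_design_study.py   --seed 7
python analysis/04_score_choices.py  --seed 7
python analysis/05_neighbor_analysis.py --seed 7
```

`02_fit_word_models.py` prints the seven-model comparison on the lexicon
(planted signal is letters-only here):

```
             model     r  r_squared       aic    n   k  rank_r2  rank_aic
           letters 0.763      0.582 -4665.467 2000  28        6         1
           bigrams 0.850      0.723 -4086.023 2000 730        3         3
        dimensions 0.167      0.028 -2930.144 2000  52        7         7
...
best model by AIC: letters
```

The wide bigram models reach higher in-sample R² purely by fitting noise
(728 columns on 2,000 words); AIC correctly prefers the letters model, and
the embedding dimensions — which carry no planted signal — explain nothing.
Note `bigrams` and `letters+bigrams` fit identically: interior bigram
counts plus boundary flags linearly determine the letter counts.

`04_score_choices.py` simulates raters, screens compliance, scores the
choices, and regresses the observed valence indexes on each model's
predictions:

```
             model     r  r_squared  ...  rank_r2
           letters 0.970      0.940  ...        1
letters+dimensions 0.966      0.933  ...        2
...
summary: {'n_participants': 17, 'n_excluded': 4, 'split_half_r': 0.882,
          'latent_recovery_rho': 0.97, 'best_model': 'letters'}
```

The value-learning scores recover the latent item values at Spearman
ρ = 0.97, raters agree across random halves at r = 0.88, and the
letters-only model wins the prediction battery — the ordering the
generating mechanism implies. `05_neighbor_analysis.py` repeats the battery
in a second world where latent pseudoword valence is the mean valence of
each item's nearest orthographic neighbors; there the orthographic-neighbor
model wins (R² = 0.951 vs. 0.600 for letters) and its nested F-test against
the letters baseline is decisive (F ≈ 1065).

A per-string estimator in the spirit of an interactive lookup tool is
available both as `pipeline.StringPredictor` and on the command line:

```bash
pseudovalence train --norms scratch/world/lexicon.csv --spec letters \
    --out scratch/letters_model.json
pseudovalence predict grawp --model scratch/letters_model.json \
    --norms scratch/world/lexicon.csv
```

which prints the letters-model valence, the mean valence of the nearest
orthographic neighbors, and their fitted combination.

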