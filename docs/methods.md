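# Methods

This note documents the models, algorithms, defaults and design choices of
the `pseudovalence` package, in the order the pipeline uses them.

## Valence models on word norms

Valence norms are mean ratings on a 1–9 scale (higher = more positive).
The lexicon is cleaned to `^[a-z]+$` (entries with punctuation, capitals or
whitespace are dropped; duplicates keep the first occurrence, logged).

Surface-form predictors for a word are: letter **counts** (26 columns,
a–z), interior adjacent bigram **counts** (676 columns, aa–zz row-major),
and first/last-letter **indicators** (26 + 26 columns, written `<a … <z`
and `a> … z>`). The column ordering (letters, bigrams, start, end,
dimensions) is fixed for reproducibility. Boundary indicators travel with
the bigram block in the seven model specs — a boundary flag is a word-edge
"bigram" — so the letters-only model is the bare 26 counts and the
letters+bigrams model has 754 columns. A consequence worth knowing:
interior bigrams plus boundary flags linearly determine letter counts
(each occurrence of letter ℓ either precedes another letter or ends the
word), so every bigram spec nests the letters spec and fits identically to
its letters-augmented variant.

Semantic predictors are embedding dimensions of the string's composed
subword vector (below), D columns (D = 300 in full-scale use; the synthetic
studies use D = 50 to keep the widest design desk-sized).

Fits are ordinary least squares with an intercept. Wide form blocks are
routinely rank deficient (most bigrams never occur in a finite lexicon);
we use the minimum-norm least-squares solution and log aliased columns
rather than silently dropping them — predictions are unaffected, individual
aliased coefficients are not interpretable. Fitting requires more rows
than columns; the error message suggests a larger lexicon or smaller spec.

Model quality: R² = 1 − RSS/TSS, Pearson r(fitted, observed) (equals √R²
in-sample; reported separately anyway), and AIC under the fixed convention
`AIC = n·ln(RSS/n) + 2k` with `k = slopes + intercept + 1` (the +1 counts
the error variance). Absolute AIC values depend on this constant and are
only comparable within it; orderings are the meaningful output. Evaluation
is in-sample, matching how such model batteries are conventionally
reported; no cross-validation is performed.

Predictions are *not* clamped to [1, 9]: extrapolation beyond the rating
scale is legitimate for extreme strings and is preserved.

## Subword composition

A string is wrapped in boundary markers (`<s>`) and all contiguous
character 4-grams are extracted (a wrapped string shorter than the gram
length contributes itself as the single gram). The string's vector is the
**sum** of the available 4-gram vectors; missing grams contribute nothing
(counted and logged), and a string none of whose grams is in the table is
an error. A mean-normalised variant (divide by the number of summed
vectors) exists but is off by default: the sum is the composition the
models are defined on, and for fixed-length item sets the choice only
rescales features. Whole-word vectors, when the table has them, can be
added on request; their mere existence for a pseudoword is treated as a
red flag during candidate filtering (such strings likely entered the
training corpus via typos) and those candidates are excluded.

Tables are read/written in the word2vec text format (header `count dim`,
one key per line; gzip transparent). Keys containing `<` or `>` are gram
vectors, all others whole-word vectors.

## Stimulus design

Candidates are filtered for duplicates and whole-word-vector hits, then
scored with the configured selection model (default: the full spec — for
stimulus construction raw explained variance matters more than parsimony).
Sampling for valence uniformity cuts the **range** of predicted valence
into `n_slices = 25` equal-width intervals and draws a per-slice quota at
random, topping up from non-exhausted slices when one runs dry. Equal-width
slices over the eligible range are the reproducible default (empirical
distributions would otherwise dictate unequal tails). Manual screening of
unreadable items or pseudocompounds is represented by a caller-supplied
exclusion list; the package deliberately has no readability model.

Trial construction concatenates `appearances` independent random
permutations of the item list and chunks the sequence into trials of
`trial_size`; a repair pass swaps members across trials until no trial
contains a duplicate (duplicates can only arise at permutation boundaries,
so repair converges in a sweep or two). This construction guarantees exact
appearance counts for every item under any seed. `n_items × appearances`
must be divisible by `trial_size`; the error names the smallest compatible
appearance count.

Sessions partition the shuffled trials into consecutive blocks of
`trials_per_participant`; when the trial count is not a multiple, the final
session is short rather than padding with repeated trials (repetition
would distort appearance counts). Every session additionally receives the
same catch trials — one clearly positive item, one clearly negative,
neutral fillers — and the within-session presentation order is shuffled.

## Best–worst scoring

Each choice record implies pairwise outcomes: best beats the other
`k − 1` items; the `k − 2` middle items beat worst (best-vs-worst counted
once; middle items are never compared with each other). Catch trials are
excluded from scoring input.

The value-learning scorer initialises every item at 0.5 and runs 100
passes; within a pass the pooled implied pairs are visited in seeded random
order and updated Elo-style with logistic expectation
`p = 1/(1 + 10^((v_loser − v_winner)/s))` and step `η(1 − p)` added to the
winner and subtracted from the loser. Defaults: scale `s = 0.4`, `η`
decaying linearly from 0.1 to 0.001 across passes, final score = mean over
the last 10% of passes (damps visit-order effects; two runs with different
visit seeds agree at Spearman ρ ≥ 0.99 on the standard fixture). These
constants were chosen for stable recovery on the synthetic fixtures and
are all exposed in `ValueLearningConfig`. The resulting scale has
arbitrary location and spread; all downstream use is through correlation
and regression, which are affine-invariant (asserted in tests).

Compliance: a catch error is choosing best ≠ designated positive or worst
≠ designated negative (each miss counts separately); participants with more
than `max_errors = 1` errors are removed with all their records.
Split-half reliability randomly halves the participants, scores each half
separately, and correlates the shared items (items present in only one
half are dropped pairwise, logged).

## Neighbor predictors

Orthographic distance is the optimal string alignment (restricted
Damerau–Levenshtein) distance with unit costs: insertions, deletions,
substitutions, and adjacent transpositions that are never re-edited. All
lexicon words at the minimal distance are returned (integer distances make
ties the norm) and the predictor is their unweighted mean valence.
Semantic distance is cosine distance (1 − cosine similarity) between the
query's composed vector and stored word vectors; real-valued distances make
ties vanishingly rare, but exact ties (within 1e−12) are averaged.
Lexicon searches are full scans — at the scale of interest (thousands of
words) this is the honest method and runs at desk speed.

Poorly-embedded lexicon words can become the nearest semantic neighbor of
a disproportionate share of queries ("hubs") and wreck the predictor.
`hub_report` counts 1-NN shares and flags words above a configurable
threshold (default 5%); exclusion itself stays an explicit configuration
decision, never automatic.

## Synthetic worlds

The generators emulate the statistical structure the pipeline assumes:

* **Lexicon**: random letter strings (lengths uniform on 3–8 by default);
  latent valence = anchor (5.0) + Σ per-letter effects × counts + a latent
  per-word semantic score + Gaussian noise, clipped to [1, 9]. Defaults:
  letter effects ~ N(0, 0.15²) per letter, semantic score ~ N(0, 0.5²),
  noise SD 0.5. The planted effects are returned for recovery tests.
* **Embedding table**: independent Gaussian 4-gram vectors
  (N(0, 1/D) entries); iterative correction passes nudge gram components
  along a known unit direction so each word's gram-sum projects onto its
  planted semantic score. Word vectors are stored as the exact gram sums,
  so composition reproduces them identically.
* **Candidates**: splice the halves of two random lexicon words or
  substitute one letter; strings equal to lexicon words are rejected.
  Candidates inherit the lexicon's letter statistics but make no
  phonotactic or readability promises — that is out of scope.
* **Raters**: per trial, utility = latent value + Gumbel(0, scale) noise,
  best = argmax, worst = argmin of the rest; Gumbel noise makes the best
  choice multinomial-logit, which is analytically convenient and standard
  for discrete choice. A participant is non-compliant with probability
  1 − compliance_rate and then answers every trial, catch trials included,
  uniformly at random — exercising the exclusion logic.

The standard study scale used throughout tests and the acceptance script:
2,000-word lexicon, 50 dimensions, 150 items × 30 appearances × 6 per
trial (750 trials, 17 sessions of 45 with a short last one), rater noise =
0.5 × SD of the latent item values, 95% compliance. Two worlds are
analysed: *letters-driven* (latent pseudoword value = the letters model's
prediction) and *neighbor-driven* (latent value = mean valence of the
nearest orthographic neighbors). These scales keep the widest OLS design
(full spec, 804 columns) comfortably overdetermined at n = 2,000 and the
whole end-to-end battery in tens of seconds.

What passing these simulations does **not** show: real lexicons have
phonotactic structure, morphology, frequency skew and non-Gaussian norm
distributions that random-string worlds lack; real raters drift, disagree
systematically, and violate the logit noise model; real embedding spaces
have anisotropy and hubness far beyond the planted construction. The
synthetic results validate the machinery (estimators recover what was
planted; orderings follow the generating mechanism), not claims about any
natural language.

## Numerical and degenerate-input choices

* Zero-variance observed vectors are an error in fit statistics (with a
  float tolerance for exactly-constant inputs).
* Zero vectors are an error in cosine distance.
* Single-letter words are legal (empty bigram block); empty strings are
  not.
* `fit` requires strictly more observations than predictors.
* Equal-width slice boundaries use the eligible pool's min/max; items on
  a boundary go to the lower slice (`searchsorted` right).
* All generators and samplers are pure functions of (config, seed); reruns
  are byte-identical.

## Known limitations

* The value-learning constants are fixture-tuned, not derived; other
  (s, η) settings change the scale's spread but not, in our tests, the
  orderings.
* In-sample model comparison inflates R² for wide specs; AIC order is the
  robust quantity (visible directly in the worked example).
* The nested F-test assumes homoscedastic Gaussian errors; its type-I
  calibration is verified by simulation at the package's standard scale
  only.
* Semantic neighbor search composes query vectors but uses stored word
  vectors for the lexicon; recomposing lexicon vectors from grams is a
  defensible alternative we did not take (stored vectors are the
  higher-fidelity representation when available).
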