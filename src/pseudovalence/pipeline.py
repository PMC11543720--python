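"""End-to-end orchestration of the three computational experiments.

The pipeline mirrors a three-stage study design:

1. **Word-norm modelling** — fit seven linear models of valence on a word
   lexicon (letters; bigrams; dimensions; and their combinations, all form
   models including boundary indicators) and pick a selection model.
2. **Pseudoword study** — generate/filter pseudoword candidates, score them
   with the selection model, sample a stimulus set uniform in predicted
   valence, build best-worst trials and sessions with catch trials, collect
   (here: simulate) choices, screen compliance, estimate continuous valence
   indexes by value learning, and regress them on each model's predictions.
3. **Neighbor analysis** — regress the same valence indexes on the mean
   valence of orthographic (OSA) and semantic (cosine) nearest neighbors,
   alone and combined with the letters model, with nested F-tests.

Each function is deterministic given its seed and returns plain DataFrames
ready for CSV export; the analysis drivers and the acceptance script are
thin wrappers over these.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bws, neighbors, stimulus_design, synthetic, valence_model
from .embeddings import EmbeddingTable
from .form_features import SEVEN_SPECS, CleanLexicon, FeatureSetSpec, build_design_matrix
from .valence_model import LinearValenceModel


@dataclass
class Experiment1Result:
    table: pd.DataFrame                       # model, r, r_squared, aic, ranks
    models: dict[str, LinearValenceModel]
    selection_model: LinearValenceModel


def run_experiment1(
    lexicon: CleanLexicon,
    embeddings: EmbeddingTable | None,
    selection: str = "full",
    specs: Mapping[str, FeatureSetSpec] | None = None,
) -> Experiment1Result:
    """Fit the seven word-norm models and keep one as the selection model.

    The default selection is the widest spec ('full'): for stimulus
    construction, raw explained variance matters more than parsimony.
    """
    specs = dict(specs or SEVEN_SPECS)
    y = np.asarray(lexicon.valences)
    words = list(lexicon.words)
    rows = []
    models: dict[str, LinearValenceModel] = {}
    for name, spec in specs.items():
        design, labels = build_design_matrix(words, spec, embeddings)
        model = valence_model.fit(design, y, spec=spec, column_labels=labels)
        st = valence_model.fit_stats(model, design, y, name=name)
        models[name] = model
        rows.append({"model": name, "r": st.r, "r_squared": st.r_squared,
                     "aic": st.aic, "n": st.n, "k": st.k})
    table = pd.DataFrame(rows)
    table["rank_r2"] = table["r_squared"].rank(ascending=False, method="min").astype(int)
    table["rank_aic"] = table["aic"].rank(ascending=True, method="min").astype(int)
    if selection not in models:
        raise ValueError(f"unknown selection model {selection!r}")
    return Experiment1Result(table=table, models=models, selection_model=models[selection])


@dataclass
class PseudowordStudy:
    items: list[str]
    predicted: dict[str, dict[str, float]]   # model name -> item -> prediction
    trial_set: stimulus_design.TrialSet
    sessions: list[stimulus_design.Session]
    catch: list[stimulus_design.CatchTrial]
    catch_latent: dict[str, float]
    slice_counts: np.ndarray


def design_pseudoword_study(
    exp1: Experiment1Result,
    candidates: Sequence[str],
    embeddings: EmbeddingTable | None,
    n_items: int = 150,
    n_slices: int = 25,
    appearances: int = 30,
    trial_size: int = 6,
    trials_per_participant: int = 45,
    exclusion_list: Sequence[str] = (),
    seed: int = 0,
) -> PseudowordStudy:
    """Filter candidates, sample a uniform-valence stimulus set and build the
    trial/session design, including catch trials."""
    if embeddings is not None:
        # strings none of whose 4-grams the table knows cannot be scored on
        # dimension specs; drop them up front
        candidates = [c for c in candidates if embeddings.is_composable(c)]
    pool = stimulus_design.filter_candidates(candidates, embeddings)
    eligible = [c.string for c in pool.eligible]
    predictions = {
        name: dict(zip(eligible, model.predict(eligible, embeddings)))
        for name, model in exp1.models.items()
    }
    sel_name = exp1.selection_model.spec.name if exp1.selection_model.spec else "full"
    pool = stimulus_design.with_predicted_valence(pool, predictions[sel_name])
    items, slice_counts = stimulus_design.stratified_uniform_sample(
        pool, n_target=n_items, n_slices=n_slices,
        exclusion_list=exclusion_list, seed=seed,
    )
    trial_set = stimulus_design.build_trial_set(
        items, appearances=appearances, trial_size=trial_size, seed=seed + 1
    )
    catch, catch_latent = synthetic.make_catch_trials(seed=seed + 2, trial_size=trial_size)
    sessions = stimulus_design.assign_sessions(
        trial_set, trials_per_participant, catch=catch, seed=seed + 3
    )
    predicted = {name: {i: preds[i] for i in items} for name, preds in predictions.items()}
    return PseudowordStudy(
        items=items, predicted=predicted, trial_set=trial_set, sessions=sessions,
        catch=catch, catch_latent=catch_latent, slice_counts=slice_counts,
    )


@dataclass
class Experiment2Result:
    scores: bws.ValueScores
    split_half_r: float
    excluded_participants: list[str]
    prediction_table: pd.DataFrame           # seven observed ~ predicted regressions
    neighbor_table: pd.DataFrame | None      # neighbor + combined models
    f_tests: dict[str, tuple[float, float]] = field(default_factory=dict)


def score_choices(
    records: Sequence[bws.ChoiceRecord],
    catch: Sequence[stimulus_design.CatchTrial],
    scorer_config: bws.ValueLearningConfig,
    max_catch_errors: int = 1,
    split_seed: int = 0,
) -> tuple[bws.ValueScores, float, list[str]]:
    """Compliance screening, value learning, split-half reliability."""
    kept, excluded = bws.exclude_noncompliant(
        records, synthetic.catch_key_map(catch), max_errors=max_catch_errors
    )
    scores = bws.value_learning(kept, scorer_config)
    split_r = bws.split_half_reliability(kept, seed=split_seed, config=scorer_config)
    return scores, split_r, excluded


def run_experiment2(
    study: PseudowordStudy,
    records: Sequence[bws.ChoiceRecord],
    scorer_config: bws.ValueLearningConfig | None = None,
    lexicon: CleanLexicon | None = None,
    embeddings: EmbeddingTable | None = None,
    semantic_exclusions: Sequence[str] = (),
    split_seed: int = 0,
) -> Experiment2Result:
    """Score simulated/collected choices and run the full model battery.

    The seven prediction models enter as univariate regressions of the
    observed valence index on each model's predicted valence.  When a
    lexicon is supplied, neighbor predictors (orthographic always; semantic
    if an embedding table is also given) and the combined letters+neighbor
    models are added, with nested F-tests for the combined models.
    """
    scorer_config = scorer_config or bws.ValueLearningConfig()
    scores, split_r, excluded = score_choices(
        records, study.catch, scorer_config, split_seed=split_seed
    )
    items = [i for i in study.items if i in scores.scores]
    observed = np.array([scores.scores[i] for i in items])

    predictors: dict[str, np.ndarray] = {
        name: np.array([study.predicted[name][i] for i in items])
        for name in study.predicted
    }
    prediction_table = valence_model.compare_models(predictors, observed)

    neighbor_tbl = None
    f_tests: dict[str, tuple[float, float]] = {}
    if lexicon is not None:
        ortho = np.array(
            [neighbors.nearest_orthographic(i, lexicon).neighbor_valence for i in items]
        )
        nb_predictors: dict[str, np.ndarray] = {
            "letters": predictors["letters"],
            "orthographic_neighbor": ortho,
        }
        sem = None
        if embeddings is not None and embeddings.word_vectors:
            vals = lexicon.as_dict()
            lex_vecs = {w: embeddings.word_vectors[w] for w in lexicon.words
                        if w in embeddings.word_vectors}
            sem = np.array(
                [
                    neighbors.nearest_semantic(
                        i, lex_vecs, embeddings.compose(i), vals,
                        exclusion_list=semantic_exclusions,
                    ).neighbor_valence
                    for i in items
                ]
            )
            nb_predictors["semantic_neighbor"] = sem
        rows = valence_model.compare_models(nb_predictors, observed)
        # combined models: letters prediction + neighbor valences
        letters_col = predictors["letters"].reshape(-1, 1)
        combos: dict[str, np.ndarray] = {
            "letters+orthographic": np.hstack([letters_col, ortho.reshape(-1, 1)])
        }
        if sem is not None:
            combos["letters+semantic"] = np.hstack([letters_col, sem.reshape(-1, 1)])
            combos["letters+orthographic+semantic"] = np.hstack(
                [letters_col, ortho.reshape(-1, 1), sem.reshape(-1, 1)]
            )
        combo_rows = []
        for name, design in combos.items():
            model = valence_model.fit(design, observed)
            st = valence_model.fit_stats(model, design, observed, name=name)
            combo_rows.append({"model": name, "r": st.r, "r_squared": st.r_squared,
                               "aic": st.aic, "n": st.n, "k": st.k})
            f_tests[name] = valence_model.nested_f_test(letters_col, design, observed)
        neighbor_tbl = pd.concat([rows, pd.DataFrame(combo_rows)], ignore_index=True)
        neighbor_tbl["rank_r2"] = (
            neighbor_tbl["r_squared"].rank(ascending=False, method="min").astype(int)
        )
        neighbor_tbl["rank_aic"] = neighbor_tbl["aic"].rank(ascending=True, method="min").astype(int)
    return Experiment2Result(
        scores=scores, split_half_r=split_r, excluded_participants=excluded,
        prediction_table=prediction_table, neighbor_table=neighbor_tbl, f_tests=f_tests,
    )


@dataclass
class SyntheticWorld:
    """A complete simulated study with its planted ground truth."""

    config: synthetic.SimulationConfig
    lexicon: CleanLexicon
    truth: synthetic.LexiconGroundTruth
    table: EmbeddingTable
    exp1: Experiment1Result
    study: PseudowordStudy
    latent: dict[str, float]
    records: list
    exp2: Experiment2Result


def build_synthetic_world(
    kind: str,
    seed: int = 7,
    n_words: int = 2000,
    n_dims: int = 50,
    n_items: int = 150,
    compliance_rate: float = 0.95,
) -> SyntheticWorld:
    """Run the whole pipeline on a simulated study.

    ``kind`` selects the generating mechanism of pseudoword valence:
    'letters' plants surface-form signal only (latent value = the letters
    model's prediction), 'neighbor' makes latent value the mean valence of
    each item's nearest orthographic neighbors.  The study uses the standard
    scale — ``n_items`` items, 30 appearances each, 6 per trial, 45 trials
    per participant — with Gumbel rater noise at half the latent SD.
    """
    cfg = synthetic.SimulationConfig(
        n_words=n_words, n_dims=n_dims, dimension_effect_sd=0.0,
        noise_sd=0.3, letter_effect_sd=0.2, seed=seed,
    )
    lexicon, truth = synthetic.generate_lexicon(cfg)
    table, _ = synthetic.generate_embedding_table(cfg, lexicon, truth)
    exp1 = run_experiment1(lexicon, table)
    candidates = synthetic.generate_candidates(lexicon, 2000, seed=seed + 4)
    study = design_pseudoword_study(exp1, candidates, table, n_items=n_items, seed=seed + 13)
    if kind == "letters":
        latent = dict(study.predicted["letters"])
    elif kind == "neighbor":
        latent = {
            i: neighbors.nearest_orthographic(i, lexicon).neighbor_valence
            for i in study.items
        }
    else:
        raise ValueError(f"unknown world kind {kind!r}")
    sd = float(np.std([latent[i] for i in study.items]))
    latent.update(study.catch_latent)
    rater_cfg = cfg.with_(rater_noise=0.5 * sd, compliance_rate=compliance_rate)
    records = synthetic.simulate_raters(study.sessions, latent, rater_cfg)
    exp2 = run_experiment2(
        study, records, lexicon=lexicon, embeddings=table, split_seed=seed + 5
    )
    return SyntheticWorld(
        config=rater_cfg, lexicon=lexicon, truth=truth, table=table, exp1=exp1,
        study=study, latent=latent, records=records, exp2=exp2,
    )


@dataclass
class StringPrediction:
    string: str
    letters_valence: float
    orthographic_neighbor_valence: float
    combined_valence: float
    neighbors: tuple[str, ...]


@dataclass
class StringPredictor:
    """The per-string estimator: letters model, orthographic neighbors, and
    their fitted additive combination (a two-predictor regression, not a raw
    sum).  Mirrors an interactive 'type a pseudoword, get its valence' tool."""

    letters_model: LinearValenceModel
    lexicon: CleanLexicon
    combo_intercept: float
    combo_coefs: np.ndarray  # (letters, orthographic) slopes

    @classmethod
    def fit(
        cls,
        letters_model: LinearValenceModel,
        lexicon: CleanLexicon,
        items: Sequence[str],
        observed: np.ndarray,
    ) -> "StringPredictor":
        letters_pred = letters_model.predict(list(items))
        ortho = np.array(
            [neighbors.nearest_orthographic(i, lexicon).neighbor_valence for i in items]
        )
        design = np.column_stack([letters_pred, ortho])
        model = valence_model.fit(design, np.asarray(observed))
        return cls(
            letters_model=letters_model, lexicon=lexicon,
            combo_intercept=model.intercept, combo_coefs=model.coefficients,
        )

    def predict(self, pseudoword: str) -> StringPrediction:
        lv = float(self.letters_model.predict([pseudoword])[0])
        nb = neighbors.nearest_orthographic(pseudoword, self.lexicon)
        combined = float(
            self.combo_intercept + self.combo_coefs @ np.array([lv, nb.neighbor_valence])
        )
        return StringPrediction(
            string=pseudoword, letters_valence=lv,
            orthographic_neighbor_valence=nb.neighbor_valence,
            combined_valence=combined, neighbors=nb.neighbors,
        )
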