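import numpy as np
import pytest
from scipy import stats

from pseudovalence import valence_model
from pseudovalence.form_features import SEVEN_SPECS, build_design_matrix
from pseudovalence.stimulus_design import build_trial_set
from pseudovalence.synthetic import (
    SimulationConfig,
    catch_key_map,
    generate_candidates,
    generate_embedding_table,
    generate_lexicon,
    make_catch_trials,
    simulate_raters,
)


class TestConfig:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=-1.0)

    def test_compliance_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(compliance_rate=1.5)


class TestGenerateLexicon:
    def test_degenerate_config_all_anchor(self):
        cfg = SimulationConfig(n_words=50, letter_effect_sd=0, dimension_effect_sd=0,
                               noise_sd=0, seed=1)
        lex, _ = generate_lexicon(cfg)
        assert all(v == 5.0 for v in lex.valences)

    def test_deterministic(self):
        cfg = SimulationConfig(n_words=100, seed=2)
        a, _ = generate_lexicon(cfg)
        b, _ = generate_lexicon(cfg)
        assert a.words == b.words and a.valences == b.valences

    def test_letter_coefficient_recovery(self):
        """Letters-only fit on a 5,000-word letters-only lexicon recovers the
        planted per-letter effects at r >= 0.95."""
        cfg = SimulationConfig(n_words=5000, letter_effect_sd=0.15,
                               dimension_effect_sd=0.0, noise_sd=0.5, seed=3)
        lex, truth = generate_lexicon(cfg)
        design, labels = build_design_matrix(
            list(lex.words), SEVEN_SPECS["letters"]
        )
        model = valence_model.fit(design, np.asarray(lex.valences),
                                  spec=SEVEN_SPECS["letters"], column_labels=labels)
        est = model.coefficients[:26]
        r = stats.pearsonr(est, truth.letter_effects).statistic
        assert r >= 0.95


class TestGenerateEmbeddings:
    def test_null_config_uncorrelated(self):
        cfg = SimulationConfig(n_words=400, n_dims=20, dimension_effect_sd=0.0,
                               noise_sd=0.5, seed=4)
        lex, truth = generate_lexicon(cfg)
        table, w = generate_embedding_table(cfg, lex, truth)
        proj = np.array([table.word_vectors[wd] @ w for wd in lex.words])
        r = stats.pearsonr(proj, np.asarray(lex.valences)).statistic
        assert abs(r) < 0.15

    def test_compose_equals_stored_word_vector(self):
        cfg = SimulationConfig(n_words=100, n_dims=10, seed=5)
        lex, truth = generate_lexicon(cfg)
        table, _ = generate_embedding_table(cfg, lex, truth)
        for wd in lex.words[:20]:
            np.testing.assert_allclose(table.compose(wd), table.word_vectors[wd])

    def test_strong_signal_dimensions_model(self):
        """With a dominant planted semantic component, the dimensions-only
        regression explains most valence variance."""
        cfg = SimulationConfig(n_words=1200, n_dims=30, letter_effect_sd=0.0,
                               dimension_effect_sd=1.0, noise_sd=0.3, seed=6)
        lex, truth = generate_lexicon(cfg)
        table, _ = generate_embedding_table(cfg, lex, truth)
        design, labels = build_design_matrix(list(lex.words), SEVEN_SPECS["dimensions"], table)
        model = valence_model.fit(design, np.asarray(lex.valences),
                                  spec=SEVEN_SPECS["dimensions"], column_labels=labels)
        st = valence_model.fit_stats(model, design, np.asarray(lex.valences))
        assert st.r_squared >= 0.5


class TestGenerateCandidates:
    def test_never_a_lexicon_word(self):
        cfg = SimulationConfig(n_words=200, seed=7)
        lex, _ = generate_lexicon(cfg)
        cands = generate_candidates(lex, 500, seed=8)
        assert len(cands) == 500
        assert not set(cands) & set(lex.words)

    def test_deterministic(self):
        cfg = SimulationConfig(n_words=100, seed=9)
        lex, _ = generate_lexicon(cfg)
        assert generate_candidates(lex, 50, seed=10) == generate_candidates(lex, 50, seed=10)

    def test_candidates_match_lexicon_letter_statistics(self):
        """Candidate letter distribution is closer (chi-square) to the
        lexicon's than uniform random strings are."""
        rng = np.random.default_rng(11)
        cfg = SimulationConfig(n_words=500, alphabet="abcdefghij", seed=11)
        lex, _ = generate_lexicon(cfg)
        cands = generate_candidates(lex, 500, seed=12)

        def letter_freq(strings):
            counts = np.zeros(26)
            for s in strings:
                for ch in s:
                    counts[ord(ch) - 97] += 1
            return counts / counts.sum()

        lex_freq = letter_freq(lex.words)
        cand_freq = letter_freq(cands)
        uniform = [
            "".join(rng.choice(list("abcdefghijklmnopqrstuvwxyz"), size=5))
            for _ in range(500)
        ]
        uni_freq = letter_freq(uniform)
        chi_cand = np.sum((cand_freq - lex_freq) ** 2 / (lex_freq + 1e-9))
        chi_uni = np.sum((uni_freq - lex_freq) ** 2 / (lex_freq + 1e-9))
        assert chi_cand < chi_uni


class TestSimulateRaters:
    def make_fixture(self):
        items = [f"pw{i:02d}" for i in range(12)]
        latent = {w: v for w, v in zip(items, np.linspace(2, 8, 12))}
        ts = build_trial_set(items, appearances=3, trial_size=6, seed=13)
        return items, latent, ts

    def test_noiseless_choices_are_latent_extremes(self):
        items, latent, ts = self.make_fixture()
        cfg = SimulationConfig(rater_noise=0.0, compliance_rate=1.0, seed=14)
        for r in simulate_raters(ts, latent, cfg):
            assert latent[r.best] == max(latent[i] for i in r.items)
            assert latent[r.worst] == min(latent[i] for i in r.items)

    def test_missing_latent_value_errors(self):
        items, latent, ts = self.make_fixture()
        del latent[items[0]]
        with pytest.raises(ValueError, match="no latent value"):
            simulate_raters(ts, latent, SimulationConfig(seed=15))

    def test_zero_compliance_fails_catch_screening(self):
        """Fully non-compliant raters answer catch trials at random; with a
        6-item catch trial the chance of passing the designated pair is tiny,
        so essentially every participant is excluded."""
        from pseudovalence.bws import exclude_noncompliant
        from pseudovalence.stimulus_design import assign_sessions

        items, latent, ts = self.make_fixture()
        catch, catch_latent = make_catch_trials(seed=16)
        latent.update(catch_latent)
        sessions = assign_sessions(ts, trials_per_participant=2, catch=catch, seed=17)
        cfg = SimulationConfig(rater_noise=0.0, compliance_rate=0.0, seed=18)
        records = simulate_raters(sessions, latent, cfg)
        kept, excluded = exclude_noncompliant(records, catch_key_map(catch))
        # per catch trial, P(0 errors) = 1/30; with 4 trials P(<=1 error) ~ 1e-4
        assert len(excluded) == len(sessions)
        assert kept == []

    def test_full_compliance_passes_catch_screening(self):
        from pseudovalence.bws import exclude_noncompliant
        from pseudovalence.stimulus_design import assign_sessions

        items, latent, ts = self.make_fixture()
        catch, catch_latent = make_catch_trials(seed=19)
        latent.update(catch_latent)
        sessions = assign_sessions(ts, trials_per_participant=2, catch=catch, seed=20)
        cfg = SimulationConfig(rater_noise=0.05, compliance_rate=1.0, seed=21)
        records = simulate_raters(sessions, latent, cfg)
        kept, excluded = exclude_noncompliant(records, catch_key_map(catch))
        assert excluded == []

    def test_byte_identical_reruns(self):
        items, latent, ts = self.make_fixture()
        cfg = SimulationConfig(rater_noise=0.3, compliance_rate=0.9, seed=22)
        assert simulate_raters(ts, latent, cfg) == simulate_raters(ts, latent, cfg)
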