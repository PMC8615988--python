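from itertools import combinations

import numpy as np
import pytest

from lexstress.aligner import (
    InfeasibleAlignmentError,
    ModelCoverageError,
    MonophoneAligner,
    _chain_arrays,
    _viterbi_states,
    compute_mfcc,
    viterbi_align,
)
from lexstress.core_io import Waveform
from lexstress.synthgen import generate_corpus, synth_word


def brute_force_best_path(emis, log_self, log_adv):
    """Exhaustive search over all monotone state segmentations."""
    S, T = emis.shape
    best = -np.inf
    for bounds in combinations(range(1, T), S - 1):
        edges = (0, *bounds, T)
        score = log_adv[S - 1]
        for s in range(S):
            seg = slice(edges[s], edges[s + 1])
            score += emis[s, seg].sum()
            score += (edges[s + 1] - edges[s] - 1) * log_self[s]
            if s < S - 1:
                score += log_adv[s]
        best = max(best, score)
    return best


class TestMfccFrontend:
    def test_frame_count_matches_config_arithmetic(self):
        w = Waveform(np.random.default_rng(0).normal(0, 0.1, 16000), 16000)
        assert compute_mfcc(w).n_frames == 98  # (16000-400)//160 + 1

    def test_silence_gives_near_constant_frames(self):
        w = Waveform(np.zeros(8000), 16000)
        fm = compute_mfcc(w)
        assert np.all(fm.data.var(axis=0) < 1e-6)

    def test_frame_count_invariant_to_amplitude(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.05, 12000)
        a = compute_mfcc(Waveform(x, 16000))
        b = compute_mfcc(Waveform(4 * x, 16000))
        assert a.n_frames == b.n_frames

    def test_too_short_signal_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_mfcc(Waveform(np.zeros(100), 16000))


class TestViterbiOracle:
    @pytest.mark.parametrize("S,T,seed", [(4, 10, 0), (6, 12, 1),
                                          (9, 15, 2), (6, 20, 3)])
    def test_matches_exhaustive_path_enumeration(self, S, T, seed):
        rng = np.random.default_rng(seed)
        emis = rng.normal(0, 2, size=(S, T))
        p_self = rng.uniform(0.2, 0.8, S)
        _, ll = _viterbi_states(emis, np.log(p_self), np.log1p(-p_self))
        assert ll == pytest.approx(
            brute_force_best_path(emis, np.log(p_self), np.log1p(-p_self)),
            rel=1e-12)

    def test_matches_oracle_through_trained_model(self, trained_aligner,
                                                  train_corpus):
        model = trained_aligner.model_
        tok = train_corpus.tokens[0]
        frames = compute_mfcc(tok.waveform)
        short = frames.data[:16]  # 2 phones x 3 states = 6 states, 16 frames
        phones = ["sil", tok.alignment.syllables[0].phonemes[0].label]
        emis, ls, la = _chain_arrays(model, phones, model.standardize(short))
        _, ll = _viterbi_states(emis, ls, la)
        assert ll == pytest.approx(brute_force_best_path(emis, ls, la),
                                   rel=1e-12)

    def test_single_phoneme_spans_whole_token(self, trained_aligner):
        tok = synth_word("SW", seed=12)
        result = trained_aligner.align(tok.waveform, ["sil"])
        assert len(result.phonemes) == 1
        assert result.phonemes[0].start == 0.0
        assert result.phonemes[0].end == pytest.approx(
            tok.waveform.duration, abs=0.011)

    def test_infeasible_when_more_states_than_frames(self, trained_aligner):
        short = Waveform(np.zeros(800), 16000)  # 3 frames
        with pytest.raises(InfeasibleAlignmentError):
            trained_aligner.align(short, ["sil", "sil"])

    def test_unseen_phone_raises_coverage_error(self, trained_aligner):
        tok = synth_word("SW", seed=12)
        with pytest.raises(ModelCoverageError):
            trained_aligner.align(tok.waveform, ["zz"])


class TestTraining:
    def test_log_likelihood_non_decreasing_per_round(self, trained_aligner):
        h = trained_aligner.history_
        assert np.all(np.diff(h) >= -1e-6 * np.abs(h[:-1]))

    def test_retraining_same_data_identical_parameters(self, train_corpus):
        X = [t.waveform for t in train_corpus.tokens[:40]]
        y = [t.alignment for t in train_corpus.tokens[:40]]
        a = MonophoneAligner(n_iter=2).fit(X, y)
        b = MonophoneAligner(n_iter=2).fit(X, y)
        for phone in a.model_.phones:
            assert np.array_equal(a.model_.phones[phone].means,
                                  b.model_.phones[phone].means)

    def test_rare_phone_rejected(self, train_corpus):
        X = [train_corpus.tokens[0].waveform]
        y = [train_corpus.tokens[0].alignment]
        with pytest.raises(ValueError, match="occurrences"):
            MonophoneAligner().fit(X, y)


class TestWordAlignment:
    def test_boundaries_tile_token_and_are_monotone(self, trained_aligner,
                                                    train_corpus):
        tok = train_corpus.tokens[5]
        result = trained_aligner.align_word(
            tok.waveform, train_corpus.entries[tok.word])
        assert result.phonemes[0].start == 0.0
        assert result.phonemes[-1].end == pytest.approx(
            tok.waveform.duration, abs=1e-9)
        for a, b in zip(result.phonemes, result.phonemes[1:]):
            assert b.start == pytest.approx(a.end, abs=1e-12)

    def test_median_boundary_error_under_20ms(self, trained_aligner,
                                              train_corpus):
        errors = []
        fresh = generate_corpus(40, pattern_mix={"SW": 6, "WS": 6}, seed=99)
        for tok in fresh.tokens:
            res = trained_aligner.align_word(tok.waveform,
                                             fresh.entries[tok.word])
            for gt, pr in zip(tok.alignment.phonemes, res.phonemes):
                assert gt.label == pr.label
                errors += [abs(gt.start - pr.start), abs(gt.end - pr.end)]
        assert np.median(errors) <= 0.020

    def test_single_mode_uses_variant_one(self, trained_aligner, train_corpus):
        tok = train_corpus.tokens[0]
        res = trained_aligner.align_word(
            tok.waveform, train_corpus.entries[tok.word], mode="single")
        assert res.variant_used == 1

    def test_multiple_mode_log_likelihood_at_least_single(self, trained_aligner,
                                                          train_corpus):
        for tok in train_corpus.tokens[:10]:
            entry = train_corpus.entries[tok.word]
            single = trained_aligner.align_word(tok.waveform, entry, "single")
            multi = trained_aligner.align_word(tok.waveform, entry, "multiple")
            assert multi.log_likelihood >= single.log_likelihood - 1e-9

    def test_one_variant_entry_modes_agree(self, trained_aligner, train_corpus):
        from lexstress.core_io import PronEntry

        tok = train_corpus.tokens[0]
        entry = train_corpus.entries[tok.word]
        solo = PronEntry(entry.word, entry.variants[:1])
        s = trained_aligner.align_word(tok.waveform, solo, "single")
        m = trained_aligner.align_word(tok.waveform, solo, "multiple")
        assert s.log_likelihood == m.log_likelihood
        assert [p.end for p in s.phonemes] == [p.end for p in m.phonemes]

    def test_variant_recovery_with_vowel_substitution(self, trained_aligner,
                                                      train_corpus):
        hits = 0
        n = 40
        for i in range(n):
            lex = train_corpus.lexicon[i % len(train_corpus.lexicon)]
            tok = synth_word(lex.pattern, lex_word=lex, seed=2000 + i, variant=2)
            res = trained_aligner.align_word(
                tok.waveform, train_corpus.entries[tok.word], "multiple")
            hits += res.variant_used == 2
        assert hits / n >= 0.9
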