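import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protlm import (
    CANONICAL_AA,
    ParameterError,
    SchemaError,
    SmoothingConfig,
    TooShortError,
    UndefinedContextError,
    conditional_prob,
    count_ngrams,
    generate_labeled_corpora,
    load_model,
    log_likelihood,
    perplexity,
    random_chain_spec,
    save_model,
    train_model,
)
from conftest import ALPHABET4, make_corpus, random_small_corpus
from oracles import brute_chain_loglik, brute_count, brute_loglik

NEG_INF = float("-inf")


class TestCounting:
    def test_overlapping_windows_and_context_windows(self):
        table = count_ngrams(make_corpus(["AAA"]), 2)
        assert dict(table.counts_n) == {"AA": 2}
        assert dict(table.counts_context) == {"A": 3}
        assert table.context_totals["A"] == 2  # left-prefix marginal

    def test_order1_letter_frequencies(self):
        table = count_ngrams(make_corpus(["ACDA"]), 1)
        assert dict(table.counts_n) == {"A": 2, "C": 1, "D": 1}
        assert table.total_tokens == 4

    def test_no_cross_sequence_windows(self):
        table = count_ngrams(make_corpus(["ACAC", "CA"]), 2)
        assert dict(table.counts_n) == {"AC": 2, "CA": 2}
        assert dict(table.counts_n) == brute_count(["ACAC", "CA"], 2)

    def test_order_below_one_rejected(self):
        with pytest.raises(ParameterError):
            count_ngrams(make_corpus(["ACDE"]), 0)

    def test_all_too_short_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="shorter than order"):
            table = count_ngrams(make_corpus(["AC", "DE"]), 5)
        assert not table.counts_n

    def test_count_conservation(self, corpus4):
        for order in (1, 2, 3):
            table = count_ngrams(corpus4, order)
            expected = sum(max(s.length - order + 1, 0) for s in corpus4)
            assert table.total_tokens == expected


class TestConditionalProb:
    def setup_method(self):
        # counts_n {"AA": 2, "AC": 1} with marginal context total 3
        self.corpus = make_corpus(["AAAC"])

    def test_mle_ratio(self, mle4):
        model = train_model(self.corpus, 2, mle4, alphabet=ALPHABET4)
        assert conditional_prob(model, "A", "A") == pytest.approx(2 / 3, abs=1e-15)

    def test_add_k(self):
        model = train_model(
            self.corpus, 2, SmoothingConfig(method="add-k", k=1.0, alphabet_size=20),
            alphabet=CANONICAL_AA,
        )
        assert conditional_prob(model, "A", "A") == pytest.approx(3 / 23, abs=1e-15)

    def test_unseen_context_uniform_under_add_k(self):
        model = train_model(
            self.corpus, 2, SmoothingConfig(method="add-k", k=1.0, alphabet_size=20),
            alphabet=CANONICAL_AA,
        )
        for r in CANONICAL_AA:
            assert conditional_prob(model, "W", r) == pytest.approx(1 / 20, abs=1e-15)

    def test_unseen_context_mle_is_explicit_error(self, mle4):
        model = train_model(self.corpus, 2, mle4, alphabet=ALPHABET4)
        with pytest.raises(UndefinedContextError):
            conditional_prob(model, "E", "A")

    def test_bad_residue_rejected(self, mle4):
        model = train_model(self.corpus, 2, mle4, alphabet=ALPHABET4)
        with pytest.raises(ParameterError):
            conditional_prob(model, "A", "W")  # not in the 4-letter alphabet


class TestNormalization:
    def test_seen_contexts_sum_to_one_mle(self, corpus4, mle4):
        model = train_model(corpus4, 2, mle4, alphabet=ALPHABET4)
        for ctx in model.counts.context_totals:
            total = sum(conditional_prob(model, ctx, r) for r in ALPHABET4)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_all_contexts_sum_to_one_add_k(self, corpus4, smoothing4):
        model = train_model(corpus4, 3, smoothing4, alphabet=ALPHABET4)
        for a in ALPHABET4:
            for b in ALPHABET4:
                total = sum(conditional_prob(model, a + b, r) for r in ALPHABET4)
                assert total == pytest.approx(1.0, abs=1e-9)


class TestLogLikelihood:
    def test_iid_case(self, mle4):
        model = train_model(make_corpus(["ACDE"]), 1, mle4, alphabet=ALPHABET4)
        assert log_likelihood(model, "AA") == pytest.approx(2 * math.log(0.25), abs=1e-12)

    def test_self_trained_degenerate_chain_scores_zero(self, mle4):
        model = train_model(make_corpus(["AAA"]), 2, mle4, alphabet=ALPHABET4)
        # P(A|A) = 1 under the normalized (marginal) denominator
        assert log_likelihood(model, "AAA", prefix="eq4") == 0.0

    def test_zero_probability_gives_sentinel_not_exception(self, mle4):
        model = train_model(make_corpus(["ACAC"]), 2, mle4, alphabet=ALPHABET4)
        assert log_likelihood(model, "ACCA") == NEG_INF  # "CC" never seen

    def test_too_short_eq4_raises_chain_scores(self, mle4):
        model = train_model(make_corpus(["ACDE"]), 3, mle4, alphabet=ALPHABET4)
        with pytest.raises(TooShortError):
            log_likelihood(model, "AC", prefix="eq4")
        assert math.isfinite(log_likelihood(model, "AC", prefix="chain"))

    def test_chain_prefix_matches_full_factorization_oracle(self, smoothing4):
        train = ["ACDEACDE", "ADADAD"]
        model = train_model(make_corpus(train), 3, smoothing4, alphabet=ALPHABET4)
        for s in ("ACDA", "EEE", "AD"):
            got = log_likelihood(model, s, prefix="chain")
            want = brute_chain_loglik(train, 3, s, ALPHABET4, "add-k", 0.01)
            assert got == pytest.approx(want, abs=1e-12)

    def test_appending_residue_never_increases_loglik(self, smoothing4):
        rng = np.random.default_rng(5)
        model = train_model(
            random_small_corpus(rng, max_seqs=5, max_len=20, min_len=5),
            2, smoothing4, alphabet=ALPHABET4,
        )
        s = "AC"
        prev = log_likelihood(model, s)
        for _ in range(10):
            s += ALPHABET4[int(rng.integers(0, 4))]
            cur = log_likelihood(model, s)
            assert cur <= prev + 1e-12
            prev = cur


class TestOracleEquivalence:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), order=st.integers(1, 3),
           method=st.sampled_from(["none", "add-k"]))
    def test_counts_and_logliks_match_bruteforce(self, seed, order, method):
        """Windowed counts and truncated log-likelihoods agree with an
        explicit sliding-window re-implementation on tiny corpora."""
        rng = np.random.default_rng(seed)
        corpus = random_small_corpus(rng, min_len=order)
        strings = [s.residues for s in corpus]
        table = count_ngrams(corpus, order)
        assert dict(table.counts_n) == brute_count(strings, order)
        k = 0.01 if method == "add-k" else 0.0
        cfg = SmoothingConfig(method=method, k=max(k, 0.01), alphabet_size=4) \
            if method == "add-k" else SmoothingConfig(method="none", alphabet_size=4)
        model = train_model(corpus, order, cfg, alphabet=ALPHABET4)
        query = random_small_corpus(rng, max_seqs=3, min_len=order)
        for q in query:
            got = log_likelihood(model, q)
            want = brute_loglik(strings, order, q.residues, ALPHABET4, method, k)
            if want == NEG_INF:
                assert got == NEG_INF
            else:
                assert got == pytest.approx(want, abs=1e-12)


class TestPerplexity:
    def test_uniform_model_scores_alphabet_size(self):
        # one copy of each canonical residue -> exactly uniform MLE
        model = train_model(
            make_corpus([CANONICAL_AA]), 1,
            SmoothingConfig(method="none", alphabet_size=20),
        )
        ppl = perplexity(model, make_corpus(["ACDE", "WWYY"]))
        assert ppl == pytest.approx(20.0, rel=1e-12)

    def test_mle_beats_uniform_on_training_data(self, mle4):
        corpus = make_corpus(["ACDEACDE"])
        model = train_model(corpus, 1, mle4, alphabet=ALPHABET4)
        assert perplexity(model, corpus) <= 4.0

    def test_unseen_event_gives_infinite_perplexity(self, mle4):
        model = train_model(make_corpus(["ACAC"]), 2, mle4, alphabet=ALPHABET4)
        assert perplexity(model, make_corpus(["CCCC"])) == float("inf")


class TestParameterRecovery:
    def test_error_shrinks_with_sample_size(self):
        """Estimated order-2 conditionals approach the generating chain's
        transition rows as the training sample grows."""
        spec = random_chain_spec(ALPHABET4, order=1, seed=11, concentration=1.0)
        errs = []
        for n in (10, 300):
            corpus, _ = generate_labeled_corpora(spec, spec, n, ("fixed", 200), seed=21)
            model = train_model(corpus, 2, SmoothingConfig(method="none", alphabet_size=4),
                                alphabet=ALPHABET4)
            err = 0.0
            for ctx, row in spec.transition.items():
                for j, r in enumerate(ALPHABET4):
                    err = max(err, abs(conditional_prob(model, ctx, r) - row[j]))
            errs.append(err)
        assert errs[1] < errs[0]
        assert errs[1] < 0.05


class TestSerialization:
    def test_round_trip_bit_identical(self, tmp_path, corpus4, smoothing4):
        model = train_model(corpus4, 3, smoothing4, alphabet=ALPHABET4, class_label="human")
        path = save_model(model, tmp_path / "m.json")
        loaded = load_model(path)
        assert loaded.order == model.order
        assert loaded.smoothing == model.smoothing
        assert loaded.class_label == "human"
        for ctx in model.counts.context_totals:
            for r in ALPHABET4:
                assert conditional_prob(loaded, ctx, r) == conditional_prob(model, ctx, r)
        # re-saving the loaded model reproduces the file byte for byte
        path2 = save_model(loaded, tmp_path / "m2.json")
        assert path.read_bytes() == path2.read_bytes()

    def test_schema_version_mismatch(self, tmp_path, corpus4, smoothing4):
        path = save_model(train_model(corpus4, 1, smoothing4, alphabet=ALPHABET4),
                          tmp_path / "m.json")
        doc = json.loads(path.read_text())
        doc["schema_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="schema_version"):
            load_model(path)

    def test_missing_counts_context(self, tmp_path, corpus4, smoothing4):
        path = save_model(train_model(corpus4, 1, smoothing4, alphabet=ALPHABET4),
                          tmp_path / "m.json")
        doc = json.loads(path.read_text())
        del doc["tables"]["1"]["counts_context"]
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="counts_context"):
            load_model(path)

    def test_negative_count_rejected(self, tmp_path, corpus4, smoothing4):
        path = save_model(train_model(corpus4, 1, smoothing4, alphabet=ALPHABET4),
                          tmp_path / "m.json")
        doc = json.loads(path.read_text())
        key = next(iter(doc["tables"]["1"]["counts_n"]))
        doc["tables"]["1"]["counts_n"][key] = -3
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="non-negative"):
            load_model(path)
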