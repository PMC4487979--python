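"""Training formulas, scoring rules and the shared assignment logic.

Hand-evaluated expectations come from evaluating the estimators on tiny
corpora by hand; argmax equivalences are checked against independent
brute-force oracles (raw posterior products, exact multinomial likelihood,
quadratic-loop distance scans).
"""

import math

import numpy as np
import pytest
from scipy.stats import multinomial as sp_multinomial

from kmertax import (
    KmerDictionary,
    SequenceRecord,
    UNCLASSIFIED,
    assign_from_scores,
    classify_nn,
    classify_record,
    compute_log_priors,
    count_kmers,
    count_matrix,
    score_markov,
    score_multinomial,
    score_rdp,
    to_presence,
    to_profile,
    train_markov,
    train_multinomial,
    train_nn,
    train_rdp,
)
from kmertax.classifiers import classify_counts, nearest_genus
from kmertax.kmers import CountVector, presence_matrix


def random_corpus(rng, n_genera=3, per_genus=3, length=60):
    records = []
    for g in range(n_genera):
        for s in range(per_genus):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, length))
            records.append(SequenceRecord(f"g{g}s{s}", seq, genus=f"g{g}"))
    return records


class TestPriors:
    def test_abundance_priors(self):
        p = compute_log_priors([1, 3], "abundance")
        assert p == pytest.approx([math.log2(0.25), math.log2(0.75)])

    def test_abundance_equal_sizes_match_flat_argmax(self):
        p = compute_log_priors([5, 5], "abundance")
        assert p[0] == pytest.approx(p[1]) == pytest.approx(math.log2(0.5))

    def test_flat_is_constant_zero(self):
        assert np.array_equal(compute_log_priors([2, 9, 4], "flat"), np.zeros(3))

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            compute_log_priors([], "flat")
        with pytest.raises(ValueError):
            compute_log_priors([0, 2], "abundance")


class TestRdp:
    def test_background_word_probability(self, toy_two_genus, dict2):
        # AA present in 1 of 2 sequences: Pr = (1 + 0.5)/(2 + 1)
        model = train_rdp(toy_two_genus, dict2)
        assert model.word_prob[dict2.index("AA")] == pytest.approx(0.5)

    def test_absent_word_probabilities(self, toy_two_genus, dict2):
        # GG occurs nowhere: Pr = 0.5/3; genus g1 (M=1) q = (0 + 1/6)/2
        model = train_rdp(toy_two_genus, dict2)
        j = dict2.index("GG")
        assert model.word_prob[j] == pytest.approx(0.5 / 3)
        assert 2 ** model.log_q[0, j] == pytest.approx((0.5 / 3) / 2)

    def test_conditional_probability_for_present_word(self, toy_two_genus, dict2):
        model = train_rdp(toy_two_genus, dict2)
        q_aa_g1 = 2 ** model.log_q[model.genera.index("g1"), dict2.index("AA")]
        assert q_aa_g1 == pytest.approx(1.5 / 2)

    def test_probabilities_strictly_inside_unit_interval(self, toy_two_genus, dict2):
        model = train_rdp(toy_two_genus, dict2)
        assert np.all(model.word_prob > 0) and np.all(model.word_prob < 1)
        assert np.all(model.log_q < 0)  # every q in (0, 1)

    def test_toy_scores(self, toy_two_genus, dict2):
        model = train_rdp(toy_two_genus, dict2)
        z = score_rdp(model, to_presence(count_kmers("AAA", dict2)))
        assert z[model.genera.index("g1")] == pytest.approx(math.log2(0.75))
        assert z[model.genera.index("g2")] == pytest.approx(math.log2(0.25))
        assert assign_from_scores(z, model.genera).genus == "g1"

    def test_zero_evidence_is_unclassified(self, toy_two_genus, dict2):
        a = classify_record(train_rdp(toy_two_genus, dict2),
                            SequenceRecord("q", "NNNNN"), dict2)
        assert a.genus == UNCLASSIFIED

    def test_unlabelled_record_rejected(self, dict2):
        with pytest.raises(ValueError):
            train_rdp([SequenceRecord("s", "ACGT")], dict2)

    def test_log_score_argmax_matches_raw_product_posterior(self, dict2):
        """Oracle: Pr(g) * prod q^aj computed as raw products (D = 16)."""
        rng = np.random.default_rng(7)
        records = random_corpus(rng, n_genera=4, per_genus=3, length=40)
        model = train_rdp(records, dict2)
        sizes = [sum(r.genus == g for r in records) for g in model.genera]
        priors = compute_log_priors(sizes, "abundance")
        for _ in range(25):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 30))
            a = to_presence(count_kmers(seq, dict2)).values
            raw = np.array([
                (2.0 ** priors[g]) * np.prod((2.0 ** model.log_q[g]) ** a)
                for g in range(len(model.genera))
            ])
            z = score_rdp(model, CountVector(a, "presence"), priors)
            assert np.argmax(z) == np.argmax(raw)

    def test_flat_prior_omission_equivalence(self, easy_community):
        """Adding a flat prior vector never changes any assignment."""
        dictionary = KmerDictionary(3)
        model = train_rdp(easy_community, dictionary)
        flat = compute_log_priors([1] * len(model.genera), "flat")
        for rec in easy_community[::7]:
            a = to_presence(count_kmers(rec, dictionary))
            with_p = assign_from_scores(score_rdp(model, a, flat), model.genera)
            without = assign_from_scores(score_rdp(model, a), model.genera)
            assert with_p.genus == without.genus


class TestMultinomial:
    def test_hand_evaluated_row(self, dict2):
        model = train_multinomial([SequenceRecord("s", "AAA", genus="g")], dict2)
        q = 2.0 ** model.log_q[0]
        assert q[dict2.index("AA")] == pytest.approx(2.0625 / 3.0)  # 0.6875
        assert q[dict2.index("AC")] == pytest.approx(0.0625 / 3.0)

    def test_rows_are_distributions(self, easy_community):
        model = train_multinomial(easy_community, KmerDictionary(3))
        assert np.allclose((2.0 ** model.log_q).sum(axis=1), 1.0, atol=1e-9)

    def test_pseudo_count_keeps_unseen_words_positive(self, toy_two_genus, dict2):
        model = train_multinomial(toy_two_genus, dict2)
        assert np.all(np.isfinite(model.log_q))

    def test_identical_totals_identical_rows(self, dict2):
        recs = [SequenceRecord("a", "ACAC", genus="g1"),
                SequenceRecord("b", "ACAC", genus="g2")]
        model = train_multinomial(recs, dict2)
        assert np.allclose(model.log_q[0], model.log_q[1])

    def test_toy_score(self, dict2):
        model = train_multinomial([SequenceRecord("s", "AAA", genus="g")], dict2)
        z = score_multinomial(model, count_kmers("AAAA", dict2))
        assert z[0] == pytest.approx(3 * math.log2(0.6875))

    def test_zero_query_scores_equal_priors(self, toy_two_genus, dict2):
        model = train_multinomial(toy_two_genus, dict2)
        priors = compute_log_priors([1, 1], "abundance")
        z = score_multinomial(model, CountVector(np.zeros(16, dtype=np.int64),
                                                 "frequency"), priors)
        assert z == pytest.approx(priors)

    def test_argmax_matches_exact_multinomial_likelihood(self, dict2):
        """Oracle: scipy's multinomial logpmf (includes the coefficient)."""
        rng = np.random.default_rng(13)
        records = random_corpus(rng, n_genera=4, per_genus=3, length=50)
        model = train_multinomial(records, dict2)
        q = 2.0 ** model.log_q
        for _ in range(25):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 40))
            a = count_kmers(seq, dict2).values
            exact = [sp_multinomial.logpmf(a, n=a.sum(), p=q[g])
                     for g in range(len(model.genera))]
            z = score_multinomial(model, CountVector(a, "frequency"))
            assert np.argmax(z) == np.argmax(exact)


class TestMarkov:
    def test_hand_evaluated_transitions(self, dict2):
        model = train_markov([SequenceRecord("s", "AAA", genus="g")], dict2)
        q = 2.0 ** model.log_q[0]
        assert q[dict2.index("AA")] == pytest.approx(2.0625 / 2.25)
        assert q[dict2.index("AC")] == pytest.approx(0.0625 / 2.25)
        # pretext C never observed: uniform transitions
        for w in ("CA", "CC", "CG", "CT"):
            assert q[dict2.index(w)] == pytest.approx(0.25)

    def test_pretext_quadruples_sum_to_one(self, easy_community):
        model = train_markov(easy_community, KmerDictionary(3))
        q = 2.0 ** model.log_q
        quadruples = q.reshape(q.shape[0], -1, 4).sum(axis=2)
        assert np.allclose(quadruples, 1.0, atol=1e-9)

    def test_transitions_strictly_positive(self, toy_two_genus, dict2):
        model = train_markov(toy_two_genus, dict2)
        assert np.all(np.isfinite(model.log_q))

    def test_k1_rejected(self, toy_two_genus):
        with pytest.raises(ValueError):
            train_markov(toy_two_genus, KmerDictionary(1))

    def test_toy_scores(self, dict2):
        model = train_markov([SequenceRecord("s", "AAA", genus="g")], dict2)
        z_aaaa = score_markov(model, count_kmers("AAAA", dict2))
        assert z_aaaa[0] == pytest.approx(3 * math.log2(2.0625 / 2.25))
        z_cccc = score_markov(model, count_kmers("CCCC", dict2))
        assert z_cccc[0] == pytest.approx(-6.0)

    def test_pretext_index_sets(self, dict2):
        model = train_markov([SequenceRecord("s", "AAA", genus="g")], dict2)
        assert model.pretext_index_set(0).tolist() == [0, 4, 8, 12]  # ...A
        assert model.pretext_index_set(3).tolist() == [3, 7, 11, 15]  # ...T


class TestNearestNeighbour:
    def test_rows_and_profiles(self, toy_two_genus, dict2):
        model = train_nn(toy_two_genus, dict2)
        assert model.profiles.shape[0] == 2
        assert np.allclose(model.profiles.sum(axis=1), 1.0, atol=1e-9)

    def test_duplicates_retained(self, dict2):
        recs = [SequenceRecord("a", "ACGT", genus="g1"),
                SequenceRecord("b", "ACGT", genus="g1")]
        assert train_nn(recs, dict2).profiles.shape[0] == 2

    def test_identity_query(self, toy_two_genus, dict2):
        model = train_nn(toy_two_genus, dict2)
        a = classify_nn(model, to_profile(count_kmers("AAA", dict2)))
        assert a.genus == "g1"

    def test_exact_tie_across_genera_is_unclassified(self, dict2):
        recs = [SequenceRecord("a", "AAA", genus="g1"),
                SequenceRecord("b", "CCC", genus="g2")]
        model = train_nn(recs, dict2)
        # equidistant query: half AA mass, half CC mass
        q = np.zeros(16)
        q[dict2.index("AA")] = 0.5
        q[dict2.index("CC")] = 0.5
        a = classify_nn(model, CountVector(q, "profile"))
        assert a.genus == UNCLASSIFIED

    def test_tie_within_one_genus_still_classifies(self, dict2):
        recs = [SequenceRecord("a", "AAA", genus="g1"),
                SequenceRecord("b", "AAA", genus="g1"),
                SequenceRecord("c", "CCC", genus="g2")]
        model = train_nn(recs, dict2)
        a = classify_nn(model, to_profile(count_kmers("AAAA", dict2)))
        assert a.genus == "g1"

    def test_degenerate_training_sequence_skipped(self, dict2):
        recs = [SequenceRecord("a", "AAA", genus="g1"),
                SequenceRecord("n", "NNN", genus="g2")]
        model = train_nn(recs, dict2)
        assert model.profiles.shape[0] == 1

    def test_matches_brute_force_scan(self):
        """Oracle: quadratic loop over all training rows, N<=50, D<=256."""
        rng = np.random.default_rng(5)
        dictionary = KmerDictionary(4)
        records = random_corpus(rng, n_genera=5, per_genus=10, length=80)
        model = train_nn(records, dictionary)
        for _ in range(20):
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 70))
            prof = to_profile(count_kmers(seq, dictionary))
            best_d, best_rows = None, []
            for i in range(model.profiles.shape[0]):
                d = math.sqrt(((model.profiles[i] - prof.values) ** 2).sum())
                if best_d is None or d < best_d - 1e-12:
                    best_d, best_rows = d, [i]
                elif abs(d - best_d) <= 1e-12:
                    best_rows.append(i)
            oracle_genera = {model.genera[model.row_genus[i]] for i in best_rows}
            expected = oracle_genera.pop() if len(oracle_genera) == 1 else UNCLASSIFIED
            assert classify_nn(model, prof).genus == expected


class TestAssignment:
    def test_unique_maximum(self):
        a = assign_from_scores(np.array([-1.0, -2.0, -3.0]), ["g1", "g2", "g3"])
        assert a.genus == "g1"

    def test_tied_maximum_unclassified(self):
        a = assign_from_scores(np.array([-1.0, -1.0, -3.0]), ["g1", "g2", "g3"])
        assert a.genus == UNCLASSIFIED

    def test_shift_invariance(self):
        z = np.array([-4.0, -1.5, -9.0])
        for c in (0.0, 10.0, -3.7):
            assert assign_from_scores(z + c, ["a", "b", "c"]).genus == "b"

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            assign_from_scores(np.array([]), [])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assign_from_scores(np.array([np.nan, 1.0]), ["a", "b"])

    def test_near_tie_within_tolerance(self):
        z = np.array([0.0, -1e-15])
        assert assign_from_scores(z, ["a", "b"]).genus == UNCLASSIFIED


class TestSharedBehaviour:
    @pytest.mark.parametrize("trainer", [train_rdp, train_multinomial,
                                         train_markov, train_nn])
    def test_zero_training_error_on_disjoint_alphabets(
        self, trainer, disjoint_alphabet_corpus, dict2
    ):
        model = trainer(disjoint_alphabet_corpus, dict2)
        for rec in disjoint_alphabet_corpus:
            assert classify_record(model, rec, dict2).genus == rec.genus

    @pytest.mark.parametrize("trainer", [train_rdp, train_multinomial,
                                         train_markov, train_nn])
    def test_training_order_invariance(self, trainer, easy_community):
        """Permuting the training set never changes any assignment."""
        dictionary = KmerDictionary(3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(easy_community))
        m1 = trainer(easy_community, dictionary)
        m2 = trainer([easy_community[i] for i in perm], dictionary)
        queries = easy_community[::9]
        counts = count_matrix(queries, dictionary)
        a1 = classify_counts(m1, counts)
        a2 = classify_counts(m2, counts)
        assert [x.genus for x in a1] == [y.genus for y in a2]

    def test_normalization_invariants_over_random_corpora(self):
        """Multinomial rows and Markov pretext quadruples stay normalized
        across 100 random small corpora."""
        dictionary = KmerDictionary(2)
        from kmertax.classifiers import markov_from_counts, multinomial_from_counts

        for seed in range(100):
            rng = np.random.default_rng(seed)
            records = random_corpus(
                rng,
                n_genera=int(rng.integers(2, 5)),
                per_genus=int(rng.integers(1, 4)),
                length=int(rng.integers(10, 80)),
            )
            counts = count_matrix(records, dictionary)
            labels = [r.genus for r in records]
            mlt = multinomial_from_counts(counts, labels, 2)
            assert np.allclose((2.0 ** mlt.log_q).sum(axis=1), 1.0, atol=1e-9)
            mrk = markov_from_counts(counts, labels, 2)
            quads = (2.0 ** mrk.log_q).reshape(len(mlt.genera), -1, 4).sum(axis=2)
            assert np.allclose(quads, 1.0, atol=1e-9)
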