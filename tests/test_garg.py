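"""Knowledge-graph embedding tests: scoring, sampling, loss, ranking, training."""

import numpy as np
import pytest

from edafuse import (ComplExModel, GargEmbedder, SubjectMeta, build_triples,
                     complex_score, conditional_prob, extract_embeddings,
                     filtered_ranking, sample_negatives, training_loss)


def random_model(entities, relations, K, rng, scale=1.0):
    return ComplExModel(
        entities, relations,
        rng.normal(0, scale, (len(entities), K)),
        rng.normal(0, scale, (len(entities), K)),
        rng.normal(0, scale, (len(relations), K)),
        rng.normal(0, scale, (len(relations), K)),
    )


def complex_oracle(model, triple):
    """Form the full complex trilinear product and take the real part."""
    h, r, t = triple
    w = model.rel_re[r] + 1j * model.rel_im[r]
    es = model.ent_re[h] + 1j * model.ent_im[h]
    eo = model.ent_re[t] + 1j * model.ent_im[t]
    return float(np.real(np.sum(w * es * np.conj(eo))))


class TestBuildTriples:
    def test_two_subjects_sharing_an_age(self):
        subs = [SubjectMeta("a", "F", 28), SubjectMeta("b", "M", 28)]
        g = build_triples(subs)
        assert len(g.triples) == 4
        assert g.n_entities == 5  # 2 participants + age:28 + F + M

    def test_single_subject(self):
        g = build_triples([SubjectMeta("a", "F", 30)])
        assert len(g.triples) == 2

    def test_distinct_ages_counting(self):
        subs = [SubjectMeta(f"s{i}", "F" if i % 2 else "M", 20 + i)
                for i in range(57)]
        g = build_triples(subs)
        assert len(g.triples) == 114
        assert g.n_entities == 57 + 57 + 2

    def test_duplicate_subject_rejected(self):
        subs = [SubjectMeta("a", "F", 28), SubjectMeta("a", "M", 30)]
        with pytest.raises(ValueError):
            build_triples(subs)

    def test_haslabel_only_for_listed_subjects(self):
        subs = [SubjectMeta("a", "F", 28), SubjectMeta("b", "M", 30)]
        g = build_triples(subs, train_labels={"a": "high"})
        has_label = [t for t in g.triples if t[1] == g.relation_index["HasLabel"]]
        assert len(has_label) == 1
        assert g.entities[has_label[0][0]] == "a"


class TestComplexScore:
    def test_zero_embeddings_score_zero(self):
        m = ComplExModel(["a", "b"], ["r"], np.zeros((2, 4)), np.zeros((2, 4)),
                         np.zeros((1, 4)), np.zeros((1, 4)))
        assert complex_score(m, (0, 0, 1)) == 0.0

    def test_purely_real_reduces_to_trilinear(self):
        rng = np.random.default_rng(0)
        re_e, re_r = rng.normal(size=(2, 4)), rng.normal(size=(1, 4))
        m = ComplExModel(["a", "b"], ["r"], re_e, np.zeros((2, 4)),
                         re_r, np.zeros((1, 4)))
        want = float(np.sum(re_r[0] * re_e[0] * re_e[1]))
        assert complex_score(m, (0, 0, 1)) == pytest.approx(want, abs=1e-12)

    def test_matches_complex_arithmetic_oracle(self):
        rng = np.random.default_rng(1)
        for i in range(100):
            K = int(rng.integers(1, 17))
            m = random_model(["a", "b", "c"], ["r", "q"], K, rng)
            triple = (int(rng.integers(3)), int(rng.integers(2)), int(rng.integers(3)))
            assert complex_score(m, triple) == pytest.approx(
                complex_oracle(m, triple), abs=1e-12)

    def test_out_of_vocabulary_raises(self):
        m = ComplExModel(["a"], ["r"], np.zeros((1, 2)), np.zeros((1, 2)),
                         np.zeros((1, 2)), np.zeros((1, 2)))
        with pytest.raises(IndexError):
            complex_score(m, (0, 0, 5))


class TestConditionalProb:
    def test_single_candidate_probability_one(self):
        rng = np.random.default_rng(2)
        m = random_model(["a", "b"], ["r"], 4, rng)
        assert conditional_prob(m, (0, 0, 1), [], "object") == pytest.approx(1.0)

    def test_uniform_when_scores_equal(self):
        m = ComplExModel(list("abcde"), ["r"], np.zeros((5, 3)), np.zeros((5, 3)),
                         np.zeros((1, 3)), np.zeros((1, 3)))
        p = conditional_prob(m, (0, 0, 1), [2, 3, 4], "object")
        assert p == pytest.approx(0.25)

    def test_matches_softmax_oracle_and_normalizes(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = random_model(list("abcdef"), ["r"], 5, rng)
            triple = (0, 0, 1)
            negs = [2, 3, 4, 5]
            scores = np.array([complex_oracle(m, (0, 0, c)) for c in [1] + negs])
            want = np.exp(scores - scores.max())
            want /= want.sum()
            assert conditional_prob(m, triple, negs, "object") == pytest.approx(
                want[0], abs=1e-12)
            # full candidate-set normalization
            total = sum(
                np.exp(complex_oracle(m, (0, 0, c)) - scores.max()) for c in [1] + negs
            ) / want.sum() * want.sum()
            assert want.sum() == pytest.approx(1.0, abs=1e-12)

    def test_true_completion_among_negatives_rejected(self):
        rng = np.random.default_rng(4)
        m = random_model(["a", "b", "c"], ["r"], 3, rng)
        with pytest.raises(ValueError):
            conditional_prob(m, (0, 0, 1), [1, 2], "object")


class TestSampleNegatives:
    def graph(self):
        subs = [SubjectMeta("a", "F", 28), SubjectMeta("b", "M", 28)]
        return build_triples(subs)

    def test_filter_excludes_positives(self):
        g = self.graph()
        triple = g.triples[0]
        positives = g.observed_completions(triple, "object")
        for _ in range(20):
            negs = sample_negatives(g, triple, 3, "object", rng=_)
            assert not set(negs) & positives

    def test_forced_single_candidate(self):
        # 1 subject, ages entity and genders: corrupting GenderIs object for
        # the only subject leaves every entity except the true gender.
        g = build_triples([SubjectMeta("a", "F", 28)])
        triple = [t for t in g.triples if t[1] == g.relation_index["GenderIs"]][0]
        with pytest.warns(UserWarning):
            negs = sample_negatives(g, triple, 10, "object", rng=0)
        assert set(negs) == set(range(g.n_entities)) - {triple[2]}

    def test_deterministic_under_seed(self):
        g = self.graph()
        a = sample_negatives(g, g.triples[0], 3, "object", rng=99)
        b = sample_negatives(g, g.triples[0], 3, "object", rng=99)
        np.testing.assert_array_equal(a, b)

    def test_uniformity_over_candidates(self):
        subs = [SubjectMeta(f"s{i}", "F", 20 + i) for i in range(10)]
        g = build_triples(subs)
        triple = g.triples[0]
        valid = sorted(set(range(g.n_entities))
                       - g.observed_completions(triple, "object"))
        rng = np.random.default_rng(0)
        counts = {v: 0 for v in valid}
        n_draws = 1000
        for _ in range(n_draws):
            for e in sample_negatives(g, triple, 1, "object", rng):
                counts[e] += 1
        p = 1.0 / len(valid)
        sigma = np.sqrt(n_draws * p * (1 - p))
        for v in valid:
            assert abs(counts[v] - n_draws * p) <= 3 * sigma


class TestTrainingLoss:
    def test_zero_model_uniform_softmax_closed_form(self):
        subs = [SubjectMeta(f"s{i}", "F" if i % 2 else "M", 20 + i) for i in range(6)]
        g = build_triples(subs)
        K = 4
        zero = ComplExModel(g.entities, g.relations,
                            np.zeros((g.n_entities, K)), np.zeros((g.n_entities, K)),
                            np.zeros((2, K)), np.zeros((2, K)))
        n_neg = 5
        rng = np.random.default_rng(0)
        negs = {(i, d): sample_negatives(g, t, n_neg, d, rng)
                for i, t in enumerate(g.triples) for d in ("object", "subject")}
        loss = training_loss(zero, g, negs, lam=0.0)
        assert loss == pytest.approx(2 * len(g.triples) * np.log(n_neg + 1), rel=1e-12)

    def test_matches_explicit_softmax_oracle(self):
        rng = np.random.default_rng(7)
        subs = [SubjectMeta(f"s{i}", "F", 20 + i) for i in range(4)]
        g = build_triples(subs)
        m = random_model(g.entities, g.relations, 3, rng)
        negs = {(i, d): sample_negatives(g, t, 3, d, rng)
                for i, t in enumerate(g.triples) for d in ("object", "subject")}
        lam = 0.37
        want = 0.0
        for i, (h, r, t) in enumerate(g.triples):
            for d in ("object", "subject"):
                true = t if d == "object" else h
                cands = [true] + list(negs[(i, d)])
                scores = [complex_oracle(m, (h, r, c) if d == "object" else (c, r, t))
                          for c in cands]
                e = np.exp(np.array(scores) - max(scores))
                want -= np.log(e[0] / e.sum())
        want += lam * sum(np.sum(a**2) for a in
                          (m.ent_re, m.ent_im, m.rel_re, m.rel_im))
        assert training_loss(m, g, negs, lam) == pytest.approx(want, rel=1e-10)

    def test_penalty_positivity(self):
        rng = np.random.default_rng(8)
        subs = [SubjectMeta(f"s{i}", "F", 20 + i) for i in range(4)]
        g = build_triples(subs)
        m = random_model(g.entities, g.relations, 3, rng)
        negs = {(i, d): sample_negatives(g, t, 3, d, np.random.default_rng(1))
                for i, t in enumerate(g.triples) for d in ("object", "subject")}
        assert training_loss(m, g, negs, 0.5) > training_loss(m, g, negs, 0.0)


class TestFilteredRanking:
    def test_perfect_model_mrr_one(self):
        subs = [SubjectMeta("a", "F", 28), SubjectMeta("b", "M", 30)]
        g = build_triples(subs)
        # craft embeddings so each true triple scores far above corruptions
        emb = GargEmbedder(dim=16, epochs=400, seed=0).fit(subs)
        rep = filtered_ranking(emb.model_, emb.graph_)
        assert rep["mrr"] == 1.0 and rep["hits@1"] == 1.0

    def test_zero_model_closed_form_tied_rank(self):
        subs = [SubjectMeta("a", "F", 28), SubjectMeta("b", "M", 30)]
        g = build_triples(subs)
        K = 3
        zero = ComplExModel(g.entities, g.relations,
                            np.zeros((g.n_entities, K)), np.zeros((g.n_entities, K)),
                            np.zeros((2, K)), np.zeros((2, K)))
        rep = filtered_ranking(zero, g)
        # all candidates tie: rank of each case = (m_case + 1) / 2
        want_ranks = []
        for triple in g.triples:
            for d in ("object", "subject"):
                true = triple[2] if d == "object" else triple[0]
                m_case = g.n_entities - len(g.observed_completions(triple, d)) + 1
                want_ranks.append((m_case + 1) / 2)
        np.testing.assert_allclose(sorted(rep["ranks"]), sorted(want_ranks))
        assert rep["mrr"] == pytest.approx(np.mean([1 / r for r in want_ranks]))

    def test_matches_brute_force_oracle_on_small_graph(self):
        subs = [SubjectMeta("a", "F", 28), SubjectMeta("b", "M", 28)]
        g = build_triples(subs)  # 5 entities + nothing else
        rng = np.random.default_rng(11)
        m = random_model(g.entities, g.relations, 4, rng)
        rep = filtered_ranking(m, g)
        want = []
        for (h, r, t) in g.triples:
            for d in ("object", "subject"):
                true = t if d == "object" else h
                positives = g.observed_completions((h, r, t), d)
                cands = [e for e in range(g.n_entities)
                         if e == true or e not in positives]
                scores = {c: complex_oracle(m, (h, r, c) if d == "object"
                                            else (c, r, t)) for c in cands}
                greater = sum(1 for c in cands if scores[c] > scores[true])
                ties = sum(1 for c in cands if scores[c] == scores[true])
                want.append(greater + (ties + 1) / 2)
        np.testing.assert_allclose(rep["ranks"], want)


class TestTraining:
    def test_loss_decreases_and_beats_random_rank(self):
        subs = [SubjectMeta(f"s{i}", "F" if i % 2 else "M", 20 + i % 5)
                for i in range(10)]
        emb = GargEmbedder(dim=8, epochs=200, seed=0).fit(subs)
        assert emb.loss_history_[-1] < emb.loss_history_[0]
        rep = filtered_ranking(emb.model_, emb.graph_)
        # random-guess expectation of the mean rank is (m+1)/2 per case
        random_mean = np.mean([
            (emb.graph_.n_entities - len(emb.graph_.observed_completions(t, d)) + 2) / 2
            for t in emb.graph_.triples for d in ("object", "subject")
        ])
        assert rep["mean_rank"] < random_mean

    def test_strong_penalty_shrinks_norms(self):
        subs = [SubjectMeta(f"s{i}", "F", 20 + i) for i in range(6)]
        emb = GargEmbedder(dim=8, epochs=100, lam=1e3, lr=1e-2, seed=0).fit(subs)
        init = np.random.default_rng(0).normal(0, 1 / np.sqrt(8),
                                               (emb.graph_.n_entities, 8))
        assert np.linalg.norm(emb.model_.ent_re) < np.linalg.norm(init)

    def test_deterministic_under_seed(self):
        subs = [SubjectMeta(f"s{i}", "M", 25 + i) for i in range(5)]
        a = GargEmbedder(dim=6, epochs=50, seed=3).fit(subs)
        b = GargEmbedder(dim=6, epochs=50, seed=3).fit(subs)
        np.testing.assert_array_equal(a.model_.ent_re, b.model_.ent_re)
        np.testing.assert_array_equal(a.model_.rel_im, b.model_.rel_im)


class TestExtractEmbeddings:
    def test_real_part_row(self):
        m = ComplExModel(["a"], ["r"],
                         np.array([[1.0, 0.0, -1.0]]), np.array([[2.0, 0.0, 0.0]]),
                         np.zeros((1, 3)), np.zeros((1, 3)))
        G = extract_embeddings(m, [SubjectMeta("a", "F", 28)])
        np.testing.assert_array_equal(G.loc["a"].to_numpy(), [1.0, 0.0, -1.0])

    def test_unknown_subject_raises(self):
        m = ComplExModel(["a"], ["r"], np.zeros((1, 2)), np.zeros((1, 2)),
                         np.zeros((1, 2)), np.zeros((1, 2)))
        with pytest.raises(KeyError):
            extract_embeddings(m, [SubjectMeta("zzz", "F", 28)])

    def test_shape(self, small_subjects):
        emb = GargEmbedder(dim=12, epochs=10, seed=0).fit(small_subjects)
        assert emb.transform(small_subjects).shape == (len(small_subjects), 12)
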