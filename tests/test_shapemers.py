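import math

import numpy as np
import pytest

from af2conf.shapemers import (
    FragmentDescriptor,
    ShapemerCounts,
    assign_topics_knee,
    cosine_match,
    describe_fragments,
    discretize_shapemer,
    fragment_model,
    moment_invariants,
    nmf_topics,
    residue_topic_scores,
    shapemer_counts,
    tfidf_matrix,
)
from af2conf.synth import ModelSpec, synth_model
from tests.conftest import constant_model, random_rigid_motion


def moments_oracle(coords):
    """Direct per-point summation of the four invariants, written without
    vectorization so it stays independent of the implementation."""
    coords = [tuple(p) for p in coords]
    n = len(coords)
    cx = sum(p[0] for p in coords) / n
    cy = sum(p[1] for p in coords) / n
    cz = sum(p[2] for p in coords) / n

    def mu(p_, q_, r_):
        return sum((x - cx) ** p_ * (y - cy) ** q_ * (z - cz) ** r_
                   for x, y, z in coords)

    o3 = mu(2, 0, 0) + mu(0, 2, 0) + mu(0, 0, 2)
    o4 = (mu(2, 0, 0) * mu(0, 2, 0) + mu(2, 0, 0) * mu(0, 0, 2)
          + mu(0, 2, 0) * mu(0, 0, 2)
          - mu(1, 1, 0) ** 2 - mu(1, 0, 1) ** 2 - mu(0, 1, 1) ** 2)
    t = [[mu(2, 0, 0), mu(1, 1, 0), mu(1, 0, 1)],
         [mu(1, 1, 0), mu(0, 2, 0), mu(0, 1, 1)],
         [mu(1, 0, 1), mu(0, 1, 1), mu(0, 0, 2)]]
    o5 = (t[0][0] * (t[1][1] * t[2][2] - t[1][2] * t[2][1])
          - t[0][1] * (t[1][0] * t[2][2] - t[1][2] * t[2][0])
          + t[0][2] * (t[1][0] * t[2][1] - t[1][1] * t[2][0]))
    f = (mu(3, 0, 0) ** 2 + mu(0, 3, 0) ** 2 + mu(0, 0, 3) ** 2
         + 3 * (mu(2, 1, 0) ** 2 + mu(2, 0, 1) ** 2 + mu(1, 2, 0) ** 2
                + mu(0, 2, 1) ** 2 + mu(1, 0, 2) ** 2 + mu(0, 1, 2) ** 2)
         + 6 * mu(1, 1, 1) ** 2)
    return o3, o4, o5, f


class TestFragmentModel:
    def test_kmer_count(self):
        m = constant_model(20, 90.0)
        frags = fragment_model(m, "kmer", k=16)
        assert len(frags) == 5
        assert all(len(f.members) == 16 for f in frags)

    def test_chain_shorter_than_k_yields_none(self):
        assert fragment_model(constant_model(10, 90.0), "kmer", k=16) == []

    def test_isolated_residue_radius_fragment(self):
        m = constant_model(3, 90.0)
        m.ca = np.array([[0.0, 0, 0], [50.0, 0, 0], [100.0, 0, 0]])
        frags = fragment_model(m, "radius", r=10.0)
        assert all(list(f.members) == [f.center] for f in frags)

    def test_radius_membership_matches_all_pairs_oracle(self):
        m, _ = synth_model(ModelSpec.from_tuples([("coil", 40, 80, 5, False)], seed=5))
        frags = fragment_model(m, "radius", r=10.0)
        d = np.linalg.norm(m.ca[:, None] - m.ca[None, :], axis=-1)
        for f in frags:
            expected = sorted(int(j) for j in np.flatnonzero(d[f.center] <= 10.0))
            assert sorted(f.members) == expected


class TestMomentInvariants:
    def test_collinear_degenerate(self):
        coords = np.column_stack([np.arange(16.0), np.zeros(16), np.zeros(16)])
        o3, o4, o5, f = moment_invariants(coords)
        assert o3 > 0
        assert o4 == pytest.approx(0.0, abs=1e-9)
        assert o5 == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=5, size=(16, 3))
        base = np.array(moment_invariants(coords))
        for _ in range(10):
            rot, trans = random_rigid_motion(rng)
            moved = np.array(moment_invariants(coords @ rot.T + trans))
            np.testing.assert_allclose(moved, base, rtol=1e-8, atol=1e-10)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(scale=4, size=(16, 3))
        got = moment_invariants(coords)
        expected = moments_oracle(coords)
        np.testing.assert_allclose(got, expected, rtol=1e-9)


class TestDiscretize:
    def _frag(self, inv, kind="kmer"):
        f = FragmentDescriptor(0, kind, np.arange(3))
        f.invariants = inv
        return f

    def test_zeros(self):
        assert discretize_shapemer(self._frag((0.0, 0.0, 0.0, 0.0)), 4.0) == \
            ("kmer", 0, 0, 0, 0)

    def test_closed_form_value(self):
        sid = discretize_shapemer(self._frag((10.0, 0, 0, 0)), 4.0)
        assert sid[1] == round(4 * math.log(11))  # = 10

    def test_deterministic_and_sign_aware(self):
        a = discretize_shapemer(self._frag((5.0, -5.0, 2.0, 1.0)), 6.0)
        b = discretize_shapemer(self._frag((5.0, -5.0, 2.0, 1.0)), 6.0)
        assert a == b
        assert a[1] == -a[2]

    def test_monotone_in_each_invariant(self):
        vals = [discretize_shapemer(self._frag((v, 0, 0, 0)), 4.0)[1]
                for v in np.linspace(0, 100, 50)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invalid_resolution(self):
        with pytest.raises(ValueError):
            discretize_shapemer(self._frag((1.0, 1, 1, 1)), 0.0)


class TestShapemerCounts:
    def test_two_copies_double_counts(self, helix_model):
        m = helix_model
        n = len(m)
        double = constant_model(2 * n, 90.0)
        double.chain_ids = ["A"] * n + ["B"] * n
        double.numbers = np.concatenate([np.arange(1, n + 1), np.arange(1, n + 1)])
        double.ca = np.vstack([m.ca, m.ca + 500.0])
        c1 = shapemer_counts(m)
        c2 = shapemer_counts(double)
        assert c2.counts == {k: 2 * v for k, v in c1.counts.items()}

    def test_rigid_motion_invariance(self, helix_model):
        rng = np.random.default_rng(2)
        base = shapemer_counts(helix_model)
        rot, trans = random_rigid_motion(rng)
        moved = helix_model.subset(range(len(helix_model)))
        moved.ca = helix_model.ca @ rot.T + trans
        assert shapemer_counts(moved).counts == base.counts

    def test_end_to_end_brute_force_oracle(self, helix_model):
        got = shapemer_counts(helix_model)
        expected: dict = {}
        ca = helix_model.ca
        n = len(helix_model)
        for s in range(n - 16 + 1):  # kmer fragments
            o3, o4, o5, f = moments_oracle(ca[s:s + 16])
            sid = ("kmer",) + tuple(
                int(round(4.0 * math.copysign(1, v) * math.log1p(abs(v)))) if v else 0
                for v in (o3, o4, o5, f))
            expected[sid] = expected.get(sid, 0) + 1
        for i in range(n):  # radius fragments
            members = [j for j in range(n)
                       if np.linalg.norm(ca[i] - ca[j]) <= 10.0]
            o3, o4, o5, f = moments_oracle(ca[members])
            sid = ("radius",) + tuple(
                int(round(6.0 * math.copysign(1, v) * math.log1p(abs(v)))) if v else 0
                for v in (o3, o4, o5, f))
            expected[sid] = expected.get(sid, 0) + 1
        assert got.counts == expected

    def test_fragments_respect_segment_boundaries(self):
        from af2conf.segment import Segment

        m = constant_model(60, 90.0)
        segs = [Segment("A", 0, 30, 90.0, 90.0), Segment("A", 30, 60, 90.0, 90.0)]
        frags = fragment_model(m, "kmer", k=16, segments=segs)
        assert len(frags) == 2 * (30 - 16 + 1)
        assert all(f.members.max() < 30 or f.members.min() >= 30 for f in frags)


class TestTfidf:
    def test_ubiquitous_term_has_unit_idf(self):
        docs = [ShapemerCounts({("kmer", 1, 0, 0, 0): c}) for c in (2, 3, 4)]
        X, vocab = tfidf_matrix(docs)
        np.testing.assert_allclose(X[:, 0], [2.0, 3.0, 4.0])

    def test_hand_computed_three_doc_corpus(self):
        a, b = ("kmer", 1, 0, 0, 0), ("radius", 2, 0, 0, 0)
        docs = [ShapemerCounts({a: 2}), ShapemerCounts({a: 1, b: 3}),
                ShapemerCounts({a: 4})]
        X, vocab = tfidf_matrix(docs)
        ja, jb = vocab.index(a), vocab.index(b)
        idf_a = math.log(4 / 4) + 1          # df = 3, n = 3
        idf_b = math.log(4 / 2) + 1          # df = 1
        np.testing.assert_allclose(X[:, ja], [2 * idf_a, 1 * idf_a, 4 * idf_a])
        np.testing.assert_allclose(X[:, jb], [0.0, 3 * idf_b, 0.0])

    def test_matches_sklearn_transformer(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 5, size=(6, 8)).astype(float)
        docs = [ShapemerCounts({("kmer", j, 0, 0, 0): int(raw[i, j])
                                for j in range(8) if raw[i, j] > 0})
                for i in range(6)]
        X, vocab = tfidf_matrix(docs)
        from sklearn.feature_extraction.text import TfidfTransformer

        ref = TfidfTransformer(norm=None, smooth_idf=True,
                               sublinear_tf=False).fit_transform(raw).toarray()
        cols = [vocab.index(("kmer", j, 0, 0, 0))
                for j in range(8) if ("kmer", j, 0, 0, 0) in vocab]
        np.testing.assert_allclose(X[:, cols],
                                   ref[:, [j for j in range(8)
                                           if ("kmer", j, 0, 0, 0) in vocab]],
                                   rtol=1e-12)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            tfidf_matrix([])


class TestNmf:
    def test_rank_one_exact(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.random(8), rng.random(12))
        tm = nmf_topics(X, p=1)
        assert np.linalg.norm(X - tm.W @ tm.H) / np.linalg.norm(X) < 1e-6

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(1)
        tm = nmf_topics(rng.random((10, 15)), p=4)
        objs = tm.objectives
        assert all(a >= b - 1e-9 * objs[0] for a, b in zip(objs, objs[1:]))

    def test_full_rank_limit(self):
        rng = np.random.default_rng(2)
        X = rng.random((6, 9))
        tm = nmf_topics(X, p=6)
        assert np.linalg.norm(X - tm.W @ tm.H) / np.linalg.norm(X) < 1e-3

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.random((8, 10))
        t1, t2 = nmf_topics(X, p=3), nmf_topics(X, p=3)
        np.testing.assert_array_equal(t1.W, t2.W)
        np.testing.assert_array_equal(t1.H, t2.H)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            nmf_topics(np.array([[1.0, -1.0]]), p=1)

    def test_planted_topic_recovery(self):
        from itertools import permutations

        rng = np.random.default_rng(4)
        Wt = rng.gamma(1.0, 1.0, size=(40, 3))
        Ht = rng.gamma(0.5, 1.0, size=(3, 60))
        X = rng.poisson(Wt @ Ht * 5).astype(float)
        tm = nmf_topics(X, p=3)
        best = 0.0
        for perm in permutations(range(3)):
            cos = np.mean([
                Ht[i] @ tm.H[perm[i]]
                / (np.linalg.norm(Ht[i]) * np.linalg.norm(tm.H[perm[i]]) + 1e-12)
                for i in range(3)])
            best = max(best, cos)
        assert best >= 0.9

    def test_reconstruction_competitive_with_sklearn(self):
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(5)
        X = rng.random((12, 20))
        ours = nmf_topics(X, p=4)
        err_ours = np.linalg.norm(X - ours.W @ ours.H)
        sk = NMF(n_components=4, init="nndsvda", max_iter=500, random_state=0)
        W = sk.fit_transform(X)
        err_sk = np.linalg.norm(X - W @ sk.components_)
        assert err_ours <= err_sk * 1.05


class TestKneeAssignment:
    def test_clear_knee(self):
        W = np.array([[10.0], [9.0], [8.0], [0.1], [0.1], [0.1]])
        assert assign_topics_knee(W) == [{0, 1, 2}]

    def test_all_zero_column_empty(self):
        assert assign_topics_knee(np.zeros((6, 1))) == [set()]

    def test_uniform_column_empty(self):
        assert assign_topics_knee(np.full((6, 1), 3.3)) == [set()]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_topics_knee(np.array([[-1.0]]))


class TestResidueTopicScores:
    def _setup(self, helix_model):
        frags = describe_fragments(helix_model, "kmer")
        vocab = sorted({f.shapemer for f in frags})
        return frags, vocab

    def test_zero_h_row_zero_scores(self, helix_model):
        frags, vocab = self._setup(helix_model)
        H = np.zeros((2, len(vocab)))
        scores = residue_topic_scores(helix_model, frags, H, vocab, topic=0)
        assert np.all(scores == 0.0)

    def test_center_contribution_is_topic_weight(self, helix_model):
        frags, vocab = self._setup(helix_model)
        f0 = frags[0]
        H = np.zeros((1, len(vocab)))
        H[0, vocab.index(f0.shapemer)] = 2.5
        only = [f0]
        scores = residue_topic_scores(helix_model, only, H, vocab, topic=0)
        assert scores[f0.center] == pytest.approx(2.5)

    def test_two_fragment_hand_oracle(self, helix_model):
        frags, vocab = self._setup(helix_model)
        two = frags[:2]
        rng = np.random.default_rng(0)
        H = rng.random((1, len(vocab)))
        sigma = 5.0
        got = residue_topic_scores(helix_model, two, H, vocab, topic=0,
                                   sigma_rbf=sigma)
        expected = np.zeros(len(helix_model))
        for f in two:
            h = H[0, vocab.index(f.shapemer)]
            for i in f.members:
                d2 = np.sum((helix_model.ca[i] - helix_model.ca[f.center]) ** 2)
                expected[i] += h * math.exp(-d2 / (2 * sigma**2))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_unknown_shapemer_contributes_zero(self, helix_model):
        frags, vocab = self._setup(helix_model)
        scores = residue_topic_scores(helix_model, frags, np.ones((1, 1)),
                                      [("radius", 99, 99, 99, 99)], topic=0)
        assert np.all(scores == 0.0)


class TestCosineMatch:
    def test_self_similarity_one(self):
        c = ShapemerCounts({("kmer", 1, 0, 0, 0): 3})
        assert cosine_match(c, [c])[0] == (0, pytest.approx(1.0))

    def test_disjoint_vocabularies_zero(self):
        a = ShapemerCounts({("kmer", 1, 0, 0, 0): 3})
        b = ShapemerCounts({("kmer", 2, 0, 0, 0): 3})
        assert cosine_match(a, [b])[0][1] == 0.0

    def test_scale_invariance(self):
        a = ShapemerCounts({("kmer", 1, 0, 0, 0): 1, ("kmer", 2, 0, 0, 0): 2})
        b = ShapemerCounts({("kmer", 1, 0, 0, 0): 2, ("kmer", 2, 0, 0, 0): 4})
        assert cosine_match(a, [b])[0][1] == pytest.approx(1.0)

    def test_zero_query_rejected(self):
        with pytest.raises(ValueError):
            cosine_match(ShapemerCounts({}), [ShapemerCounts({("kmer", 0, 0, 0, 0): 1})])

    def test_rotated_copy_found_in_corpus(self, helix_model):
        rng = np.random.default_rng(7)
        rot, trans = random_rigid_motion(rng)
        moved = helix_model.subset(range(len(helix_model)))
        moved.ca = helix_model.ca @ rot.T + trans
        decoy, _ = synth_model(ModelSpec.from_tuples([("coil", 30, 80, 5, False)], seed=9))
        corpus = [shapemer_counts(decoy), shapemer_counts(moved)]
        ranked = cosine_match(shapemer_counts(helix_model), corpus)
        assert ranked[0][0] == 1
        assert ranked[0][1] >= 0.999
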