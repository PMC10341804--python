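import numpy as np
import pytest
from scipy.stats import poisson

from allostate.genome import GenomeLayout
from allostate.hmm import (
    BernoulliHMM,
    BinaryMatrix,
    Segmentation,
    binarize,
    decode,
    match_states,
    pool_tracks,
    relabel_states,
    state_coverage,
)

from conftest import (
    brute_force_best_path_logprob,
    brute_force_loglik,
    make_track,
    path_logprob,
    random_tiny_hmm,
)


class TestBinarize:
    def test_zero_count_is_never_called(self, toy_layout):
        chip = make_track(toy_layout, {"A01": [0, 0, 0, 0, 5], "D01": [0] * 10})
        calls = binarize(chip, None, p_threshold=1e-4)
        assert calls["A01"][0] == 0  # P(X >= 0) = 1

    def test_poisson_tail_thresholds(self):
        # lambda = 1: c=10 -> sf ~1.1e-7 <= 1e-4 called; c=3 -> 0.080 not
        layout = GenomeLayout.from_records([("A01", 2000, "A")])
        chip = make_track(layout, {"A01": [1, 1, 1, 1, 1, 1, 1, 10, 3, 1]})
        control = make_track(layout, {"A01": [1] * 10}, mark="Mock")
        # scale control so lambda ~= (chip total / control total) * 1 >= 1
        calls = binarize(chip, control, p_threshold=1e-4)
        lam = chip.total / 10  # scaled control = lam everywhere
        assert poisson.sf(9, lam) <= 1e-4
        assert poisson.sf(2, lam) > 1e-4
        assert calls["A01"][7] == 1
        assert calls["A01"][8] == 0

    def test_negative_counts_rejected(self, toy_layout):
        with pytest.raises(ValueError):
            make_track(toy_layout, {"A01": [-1, 0, 0, 0, 0], "D01": [0] * 10})


def test_pool_tracks_sums_counts(toy_layout):
    a = make_track(toy_layout, {"A01": [1, 2, 3, 4, 5], "D01": [1] * 10})
    b = make_track(toy_layout, {"A01": [5, 4, 3, 2, 1], "D01": [2] * 10}, replicate=2)
    pooled = pool_tracks([a, b])
    assert pooled.counts["A01"].tolist() == [6] * 5
    assert pooled.total == a.total + b.total


class TestForwardOracle:
    def test_single_state_closed_form(self):
        T = 17
        model = BernoulliHMM(n_states=1)
        model.startprob_ = np.array([1.0])
        model.transmat_ = np.array([[1.0]])
        model.emissionprob_ = np.array([[0.5]])
        X = np.random.default_rng(0).integers(0, 2, size=(T, 1)).astype(np.uint8)
        assert model.score(X) == pytest.approx(T * np.log(0.5))

    def test_exhaustive_path_enumeration(self, rng):
        # 200 random tiny instances, T<=8, K<=3, M<=2
        for _ in range(200):
            K = int(rng.integers(1, 4))
            M = int(rng.integers(1, 3))
            T = int(rng.integers(1, 9))
            start, trans, emission, obs = random_tiny_hmm(rng, K, M, T)
            model = BernoulliHMM(n_states=K)
            model.startprob_, model.transmat_, model.emissionprob_ = start, trans, emission
            assert model.score(obs) == pytest.approx(
                brute_force_loglik(start, trans, emission, obs), abs=1e-8
            )

    def test_state_permutation_invariance(self, rng):
        start, trans, emission, obs = random_tiny_hmm(rng, 3, 2, 8)
        model = BernoulliHMM(n_states=3)
        model.startprob_, model.transmat_, model.emissionprob_ = start, trans, emission
        perm = np.array([2, 0, 1])
        permuted = BernoulliHMM(n_states=3)
        permuted.startprob_ = start[perm]
        permuted.transmat_ = trans[np.ix_(perm, perm)]
        permuted.emissionprob_ = emission[perm]
        assert model.score(obs) == pytest.approx(permuted.score(obs), abs=1e-10)


class TestViterbiOracle:
    def test_exhaustive_argmax(self, rng):
        for _ in range(200):
            K = int(rng.integers(1, 4))
            M = int(rng.integers(1, 3))
            T = int(rng.integers(1, 9))
            start, trans, emission, obs = random_tiny_hmm(rng, K, M, T)
            model = BernoulliHMM(n_states=K)
            model.startprob_, model.transmat_, model.emissionprob_ = start, trans, emission
            path = model.predict(obs, method="viterbi")
            assert path_logprob(start, trans, emission, obs, path) == pytest.approx(
                brute_force_best_path_logprob(start, trans, emission, obs), abs=1e-8
            )

    def test_posterior_equals_viterbi_when_separable(self, rng):
        # near-deterministic emissions: both decoders read the data
        emission = np.array([[0.999, 0.001], [0.001, 0.999]])
        trans = np.array([[0.9, 0.1], [0.1, 0.9]])
        start = np.array([0.5, 0.5])
        states = rng.integers(0, 2, size=500)
        # state 0 fires mark 0, state 1 fires mark 1
        obs = np.stack([1 - states, states], axis=1).astype(np.uint8)
        model = BernoulliHMM(n_states=2)
        model.startprob_, model.transmat_, model.emissionprob_ = start, trans, emission
        v = model.predict(obs, method="viterbi")
        p = model.predict(obs, method="posterior")
        assert np.array_equal(v, p)
        assert np.array_equal(v, states)


class TestBaumWelch:
    def test_monotone_loglik_over_random_instances(self, rng):
        for _ in range(100):
            K = int(rng.integers(2, 4))
            T = int(rng.integers(50, 200))
            X = rng.integers(0, 2, size=(T, 2)).astype(np.uint8)
            m = BernoulliHMM(n_states=K, n_restarts=1, max_iter=15,
                             random_state=int(rng.integers(2**31)))
            m.fit(X)
            diffs = np.diff(m.history_[0])
            assert (diffs >= -1e-8).all()

    def test_two_state_parameter_recovery(self, rng):
        emission = np.array([[0.9, 0.1], [0.1, 0.9]])
        trans = np.array([[0.95, 0.05], [0.05, 0.95]])
        cum = np.cumsum(trans, axis=1)
        T = 50_000
        states = np.empty(T, dtype=int)
        states[0] = 0
        u = rng.random(T)
        for t in range(1, T):
            states[t] = np.searchsorted(cum[states[t - 1]], u[t])
        X = (rng.random((T, 2)) < emission[states]).astype(np.uint8)
        m = BernoulliHMM(n_states=2, n_restarts=3, random_state=1).fit(X)
        mapping = match_states(emission, m.emissionprob_)
        order = np.empty(2, dtype=int)
        order[mapping] = np.arange(2)
        assert np.abs(m.emissionprob_[order] - emission).max() < 0.05

    def test_deterministic_emission_fixed_point(self):
        # emissions that identify the state exactly: one EM step lands on
        # the empirical MLE and a second step does not move
        rng = np.random.default_rng(5)
        emission = np.array([[1.0, 0.0], [0.0, 1.0]])
        trans = np.array([[0.8, 0.2], [0.3, 0.7]])
        start = np.array([0.6, 0.4])
        cum = np.cumsum(trans, axis=1)
        states = np.empty(400, dtype=int)
        states[0] = 0
        u = rng.random(400)
        for t in range(1, 400):
            states[t] = np.searchsorted(cum[states[t - 1]], u[t])
        X = np.stack([states == 0, states == 1], axis=1).astype(np.uint8)

        def one_step(s, tr, em, n_iter):
            m = BernoulliHMM(n_states=2, max_iter=n_iter, tol=0.0,
                             startprob_init=s, transmat_init=tr,
                             emissionprob_init=em, emission_floor=1e-12)
            m.fit(X)
            return m.startprob_, m.transmat_, m.emissionprob_

        s1, t1, e1 = one_step(start, trans, emission, 1)
        # emissions already at the empirical truth stay there
        assert np.abs(e1 - emission).max() < 1e-9
        s2, t2, e2 = one_step(s1, t1, e1, 1)
        np.testing.assert_allclose(t2, t1, atol=1e-9)
        np.testing.assert_allclose(e2, e1, atol=1e-9)
        np.testing.assert_allclose(s2, s1, atol=1e-9)

    def test_seed_determinism(self, rng):
        X = rng.integers(0, 2, size=(500, 3)).astype(np.uint8)
        m1 = BernoulliHMM(n_states=3, n_restarts=2, random_state=7, max_iter=30).fit(X)
        m2 = BernoulliHMM(n_states=3, n_restarts=2, random_state=7, max_iter=30).fit(X)
        assert np.array_equal(m1.emissionprob_, m2.emissionprob_)
        assert np.array_equal(m1.transmat_, m2.transmat_)
        assert m1.loglik_ == m2.loglik_

    def test_too_many_states_rejected(self):
        X = np.zeros((3, 2), dtype=np.uint8)
        with pytest.raises(ValueError):
            BernoulliHMM(n_states=10, n_restarts=1).fit(X)


class TestSegmentationAndRelabel:
    def _toy_model(self):
        m = BernoulliHMM(n_states=3)
        m.startprob_ = np.array([0.4, 0.3, 0.3])
        m.transmat_ = np.full((3, 3), 1 / 3)
        m.emissionprob_ = np.array([[0.2, 0.9], [0.8, 0.3], [0.8, 0.9]])
        m.loglik_ = 0.0
        return m

    def test_relabel_hand_sorted_order(self):
        m = self._toy_model()
        new, _, order = relabel_states(m)
        # descending lexicographic: (0.8,0.9) > (0.8,0.3) > (0.2,0.9)
        assert order.tolist() == [2, 1, 0]
        np.testing.assert_allclose(
            new.emissionprob_, [[0.8, 0.9], [0.8, 0.3], [0.2, 0.9]]
        )

    def test_relabel_idempotent_and_permutation_symmetric(self):
        m = self._toy_model()
        once, _, _ = relabel_states(m)
        twice, _, order = relabel_states(once)
        assert order.tolist() == [0, 1, 2]
        np.testing.assert_allclose(once.emissionprob_, twice.emissionprob_)
        # swapping two states then relabelling gives the same canon
        perm = np.array([1, 0, 2])
        swapped = BernoulliHMM(n_states=3)
        swapped.startprob_ = m.startprob_[perm]
        swapped.transmat_ = m.transmat_[np.ix_(perm, perm)]
        swapped.emissionprob_ = m.emissionprob_[perm]
        canon, _, _ = relabel_states(swapped)
        np.testing.assert_allclose(canon.emissionprob_, once.emissionprob_)
        np.testing.assert_allclose(canon.transmat_, once.transmat_)

    def test_relabel_consistent_with_segmentation(self):
        m = self._toy_model()
        seg = Segmentation({"A01": np.array([0, 0, 2, 1, 2])}, 3, 200)
        new_m, new_seg, order = relabel_states(m, seg)
        for old, new in [(0, 2), (1, 1), (2, 0)]:
            assert (seg.states["A01"] == old).sum() == (
                new_seg.states["A01"] == new
            ).sum()
        # the state occupying each bin keeps its emission signature
        for b in range(5):
            old_k = seg.states["A01"][b]
            new_k = new_seg.states["A01"][b]
            np.testing.assert_allclose(
                m.emissionprob_[old_k], new_m.emissionprob_[new_k]
            )

    def test_single_state_decode_and_coverage(self, toy_layout):
        m = BernoulliHMM(n_states=1)
        m.startprob_ = np.array([1.0])
        m.transmat_ = np.array([[1.0]])
        m.emissionprob_ = np.array([[0.5]])
        bm = BinaryMatrix(("m",), {"A01": np.zeros((5, 1), dtype=np.uint8),
                                   "D01": np.ones((10, 1), dtype=np.uint8)})
        seg = decode(m, bm)
        assert all((s == 0).all() for s in seg.states.values())
        cov = state_coverage(seg, toy_layout)
        assert cov["fraction"].sum() == pytest.approx(1.0)
        assert cov.loc[0, "fraction"] == pytest.approx(1.0)

    def test_alternating_two_state_coverage(self, toy_layout):
        seg = Segmentation(
            {"A01": np.array([0, 1, 0, 1, 0]), "D01": np.tile([1, 0], 5)}, 2, 200
        )
        cov = state_coverage(seg, toy_layout)
        assert cov["fraction"].sum() == pytest.approx(1.0)
        assert cov.loc[0, "bases"] == 600 + 1000

    def test_segmentation_partitions_genome(self, toy_layout, rng):
        seg = Segmentation(
            {"A01": rng.integers(0, 6, 5), "D01": rng.integers(0, 6, 10)}, 6, 200
        )
        ivs = seg.intervals(toy_layout)
        for chrom, length in toy_layout.lengths.items():
            chrom_ivs = sorted(
                (iv for iv, _ in ivs if iv.chrom == chrom), key=lambda i: i.start
            )
            assert chrom_ivs[0].start == 0
            assert chrom_ivs[-1].end == length
            for a, b in zip(chrom_ivs, chrom_ivs[1:]):
                assert a.end == b.start
        cov = state_coverage(seg, toy_layout)
        assert cov["fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        # per-subgenome fractions each sum to 1
        sub = state_coverage(seg, toy_layout, by_subgenome=True)
        for sg in ("A", "D"):
            assert sub[sub.subgenome == sg]["fraction"].sum() == pytest.approx(1.0)


def test_binary_matrix_round_trip(tmp_path, rng):
    bm = BinaryMatrix(
        ("H3K4me3", "DNase"),
        {"A01": rng.integers(0, 2, (7, 2)).astype(np.uint8),
         "D01": rng.integers(0, 2, (4, 2)).astype(np.uint8)},
    )
    bm.write(tmp_path)
    paths = sorted(str(p) for p in tmp_path.glob("*_binary.txt"))
    back = BinaryMatrix.read(paths)
    assert back.marks == bm.marks
    for chrom in bm.data:
        assert np.array_equal(back.data[chrom], bm.data[chrom])


def test_model_json_round_trip(tmp_path):
    m = BernoulliHMM(n_states=2)
    m.startprob_ = np.array([0.3, 0.7])
    m.transmat_ = np.array([[0.9, 0.1], [0.2, 0.8]])
    m.emissionprob_ = np.array([[0.8, 0.1], [0.2, 0.9]])
    m.loglik_ = -12.5
    m.to_json(tmp_path / "model.json", marks=["a", "b"])
    back = BernoulliHMM.from_json(tmp_path / "model.json")
    np.testing.assert_allclose(back.transmat_, m.transmat_)
    np.testing.assert_allclose(back.emissionprob_, m.emissionprob_)
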