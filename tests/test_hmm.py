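"""Bernoulli-HMM correctness against explicit path enumeration and
independent likelihood oracles, plus labelling and model I/O."""

import numpy as np
import pytest

from chromstate import (
    BernoulliHMM,
    ChromatinStateModel,
    GenomeLayout,
    LabelRule,
    SimulationConfig,
    fit_model,
    label_states,
    match_states,
    posterior_marginals,
    read_model_tsv,
    select_state_count,
    simulate_marks,
    simulate_state_chain,
    stack_tracks,
    viterbi_decode,
    write_model_tsv,
)
from chromstate.hmm import emission_redundancy

from _oracles import enum_loglik, enum_posteriors, enum_viterbi, random_hmm


def _model(start, trans, emis, marks=None):
    K, M = emis.shape
    return ChromatinStateModel(
        initial=start,
        transition=trans,
        emission=emis,
        mark_names=tuple(marks or (f"m{j}" for j in range(M))),
        state_labels=tuple(f"S{k}" for k in range(K)),
    )


class TestExactInference:
    """Scaled recursions must agree with brute-force path enumeration."""

    @pytest.mark.parametrize("K,T,M", [(2, 6, 2), (2, 8, 3), (3, 6, 2), (3, 8, 1)])
    def test_loglik_posteriors_match_enumeration(self, K, T, M):
        rng = np.random.default_rng(K * 100 + T)
        for _ in range(5):
            start, trans, emis = random_hmm(rng, K, M)
            X = rng.integers(0, 2, size=(T, M)).astype(float)
            est = BernoulliHMM.from_model(_model(start, trans, emis))
            assert est.score(X) == pytest.approx(
                enum_loglik(start, trans, emis, X), abs=1e-9
            )
            np.testing.assert_allclose(
                est.predict_proba(X), enum_posteriors(start, trans, emis, X),
                atol=1e-9,
            )

    @pytest.mark.parametrize("K,T", [(2, 6), (3, 8), (3, 5)])
    def test_viterbi_attains_max_path_score(self, K, T):
        rng = np.random.default_rng(K * 10 + T)
        for _ in range(5):
            start, trans, emis = random_hmm(rng, K, 2)
            X = rng.integers(0, 2, size=(T, 2)).astype(float)
            est = BernoulliHMM.from_model(_model(start, trans, emis))
            path = est.predict(X)
            best_path, best_logp = enum_viterbi(start, trans, emis, X)
            # the decoded path must attain the optimum (and with random
            # continuous parameters the optimum is a.s. unique)
            assert tuple(path) == best_path

    def test_posterior_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        start, trans, emis = random_hmm(rng, 3, 4)
        X = rng.integers(0, 2, size=(50, 4)).astype(float)
        gamma = BernoulliHMM.from_model(_model(start, trans, emis)).predict_proba(X)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_single_state_degenerate(self):
        X = np.array([[1.0], [0.0], [1.0]])
        est = BernoulliHMM(n_states=1).fit(X)
        assert est.transmat_.tolist() == [[1.0]]
        assert est.predict(X).tolist() == [0, 0, 0]
        np.testing.assert_allclose(est.predict_proba(X), 1.0)

    def test_noiseless_tracks_emitting_state(self):
        # 0/1-degenerate emissions and identity transitions: the decoded
        # state follows the emitting state exactly
        emis = np.array([[1.0, 0.0], [0.0, 1.0]])
        trans = np.eye(2)
        start = np.array([0.5, 0.5])
        X = np.array([[1, 0], [1, 0], [1, 0]], dtype=float)
        est = BernoulliHMM.from_model(_model(start, trans, emis))
        assert est.predict(X).tolist() == [0, 0, 0]
        Y = np.array([[0, 1], [0, 1]], dtype=float)
        assert est.predict(Y).tolist() == [1, 1]

    def test_score_matches_hmmlearn_on_symbol_encoding(self):
        """Independent oracle: CategoricalHMM over the 2^M symbol alphabet."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(11)
        K, M, T = 3, 3, 200
        start, trans, emis = random_hmm(rng, K, M)
        X = rng.integers(0, 2, size=(T, M)).astype(float)
        # expand product-Bernoulli emissions over all 2^M binary symbols
        symbols = np.array(
            [[(s >> j) & 1 for j in range(M)] for s in range(2**M)], dtype=float
        )
        emat = np.prod(
            emis[:, None, :] ** symbols[None, :, :]
            * (1 - emis[:, None, :]) ** (1 - symbols[None, :, :]),
            axis=2,
        )
        ch = hmmlearn.CategoricalHMM(n_components=K)
        ch.startprob_ = start
        ch.transmat_ = trans
        ch.emissionprob_ = emat
        ch.n_features = 2**M
        codes = (X.astype(int) * (2 ** np.arange(M))).sum(axis=1)
        want = ch.score(codes.reshape(-1, 1))
        got = BernoulliHMM.from_model(_model(start, trans, emis)).score(X)
        assert got == pytest.approx(want, abs=1e-8)


class TestTraining:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(500, 3)).astype(float)
        m = fit_model(X, 1, seed=0)
        np.testing.assert_allclose(m.emission[0], X.mean(axis=0), atol=1e-9)
        assert m.transition.tolist() == [[1.0]]

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(400, 3)).astype(float)
        est = BernoulliHMM(n_states=3, max_iter=50, tol=-1.0, random_state=3)
        est.fit(X, lengths=[200, 200])
        diffs = np.diff(est.history_)
        assert diffs.min() >= -1e-8

    def test_parameter_recovery_two_states(self):
        """Truth K=2, sticky chain, 5e4 bins: emissions within 0.03 MAE."""
        layout = GenomeLayout(("chr1",), (10_000_000,), 200)
        emis = np.array([[0.9, 0.1], [0.1, 0.9]])
        cfg = SimulationConfig(
            layout=layout,
            state_names=("A", "B"),
            mark_names=("m1", "m2"),
            emission_truth=emis,
            transition_truth=np.array([[0.95, 0.05], [0.05, 0.95]]),
            seed=42,
        )
        seg = simulate_state_chain(cfg)
        obs, _ = stack_tracks(simulate_marks(seg, cfg))
        m = fit_model(obs, 2, lengths=layout.chain_lengths(), seed=7)
        perm = match_states(emis, m.emission)
        assert np.abs(emis - m.emission[perm]).mean() <= 0.03

    def test_default_study_recovery(self):
        """Six canonical states, five marks, 2e5 bins: emission MAE <= 0.03."""
        cfg = SimulationConfig(seed=12)
        seg = simulate_state_chain(cfg)
        obs, marks = stack_tracks(simulate_marks(seg, cfg))
        m = fit_model(
            obs, cfg.n_states, lengths=cfg.layout.chain_lengths(), seed=1,
            mark_names=marks,
        )
        perm = match_states(cfg.emission_truth, m.emission)
        assert np.abs(cfg.emission_truth - m.emission[perm]).mean() <= 0.03

    def test_relabeling_equivariance(self):
        """Decoding and marginals commute with a permutation of states."""
        rng = np.random.default_rng(8)
        start, trans, emis = random_hmm(rng, 3, 2)
        X = rng.integers(0, 2, size=(40, 2)).astype(float)
        base = BernoulliHMM.from_model(_model(start, trans, emis))
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        permuted = BernoulliHMM.from_model(
            _model(start[perm], trans[np.ix_(perm, perm)], emis[perm])
        )
        np.testing.assert_allclose(
            base.predict_proba(X), permuted.predict_proba(X)[:, inv], atol=1e-12
        )
        # permuted state j plays the role of original state perm[j]
        assert np.array_equal(perm[permuted.predict(X)], base.predict(X))

    def test_non_binary_observations_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            BernoulliHMM(n_states=2).fit(np.array([[0.5, 1.0]] * 4))

    def test_too_many_states_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            BernoulliHMM(n_states=10).fit(np.zeros((4, 2)))


class TestStateCountSelection:
    def test_single_k_range(self):
        X = np.random.default_rng(0).integers(0, 2, (100, 2)).astype(float)
        rep = select_state_count(X, [1], seed=0)
        assert rep.recommended_K == 1
        assert rep.redundancies == [0.0]

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_state_count(np.zeros((10, 2)), [])

    def test_loglik_non_decreasing_in_k(self):
        """A (K+1)-state fit warm-started by splitting a K-state solution
        can only improve the likelihood (EM is monotone from any start)."""
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, size=(2000, 3)).astype(float)
        prev = None
        for K in (1, 2, 3):
            if prev is None:
                est = BernoulliHMM(n_states=K, random_state=0).fit(X)
            else:
                start = np.append(prev.startprob_ * [1] * (K - 1), 0.0)
                start[-1] = start[0] / 2
                start[0] /= 2
                trans = np.full((K, K), 1e-6)
                trans[: K - 1, : K - 1] = prev.transmat_
                trans[-1] = trans[0]
                trans /= trans.sum(axis=1, keepdims=True)
                emis = np.vstack([prev.emissionprob_, prev.emissionprob_[0] + 1e-3])
                est = BernoulliHMM(
                    n_states=K, random_state=0, init_params=(start, trans, emis)
                ).fit(X)
            if prev is not None:
                assert est.loglik_ >= prev.loglik_ - 1e-6
            prev = est

    def test_recovers_truth_k_with_crisp_states(self):
        """Three crisp single-mark states; surplus states duplicate and
        trip the redundancy threshold, so the rule recommends 3."""
        layout = GenomeLayout(("chr1",), (4_000_000,), 200)
        emis = np.array(
            [
                [0.999, 0.001, 0.001, 0.001, 0.001],
                [0.001, 0.999, 0.999, 0.001, 0.001],
                [0.001, 0.001, 0.001, 0.001, 0.999],
            ]
        )
        cfg = SimulationConfig(
            layout=layout,
            state_names=("TssS", "EnhS", "Tx"),
            emission_truth=emis,
            seed=0,
        )
        seg = simulate_state_chain(cfg)
        obs, _ = stack_tracks(simulate_marks(seg, cfg))
        rep = select_state_count(
            obs, [2, 3, 4, 5], seed=100, lengths=layout.chain_lengths()
        )
        assert rep.recommended_K == 3

    def test_redundancy_of_duplicate_rows_is_one(self):
        e = np.array([[0.9, 0.1, 0.2], [0.9, 0.1, 0.2], [0.1, 0.8, 0.9]])
        assert emission_redundancy(e) == pytest.approx(1.0)


class TestLabelling:
    MARKS = ("H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3", "H3K36me3")

    @pytest.mark.parametrize(
        "row,expected",
        [
            ([1.0, 0.0, 0.0, 0.0, 0.0], "TssS"),
            ([0.0, 0.9, 0.9, 0.0, 0.0], "EnhS"),
            ([0.0, 0.8, 0.1, 0.0, 0.0], "EnhW"),
            ([0.0, 0.1, 0.0, 0.0, 0.9], "Tx"),
            ([0.0, 0.0, 0.0, 0.9, 0.0], "ReprPC"),
            ([0.05, 0.05, 0.05, 0.05, 0.05], "Quies"),
            ([0.3, 0.3, 0.3, 0.3, 0.3], "Mixed"),
        ],
    )
    def test_default_rules(self, row, expected):
        emis = np.vstack([row, [0.4, 0.4, 0.4, 0.4, 0.4]])
        m = _model(
            np.array([0.5, 0.5]),
            np.full((2, 2), 0.5),
            emis,
            marks=self.MARKS,
        )
        labelled = label_states(m)
        assert labelled.state_labels[0] == f"1_{expected}"

    def test_promoter_beats_enhancer_priority(self):
        # high K4me3 with high K4me1/K27ac is still a promoter state
        emis = np.array([[0.8, 0.9, 0.9, 0.0, 0.0], [0.0] * 5])
        m = _model(np.array([0.5, 0.5]), np.full((2, 2), 0.5), emis, self.MARKS)
        assert label_states(m).state_labels[0] == "1_TssS"

    def test_unknown_mark_in_rules_rejected(self):
        m = _model(
            np.array([1.0]), np.ones((1, 1)), np.array([[0.5, 0.5]]),
            marks=("H3K4me3", "H3K4me1"),
        )
        with pytest.raises(KeyError, match="H3K9me3"):
            label_states(m, rules=[LabelRule("Het", min_emission={"H3K9me3": 0.5})])


class TestModelIO:
    def test_tsv_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        start, trans, emis = random_hmm(rng, 4, 5)
        m = _model(start, trans, emis)
        p = tmp_path / "model.tsv"
        write_model_tsv(m, p)
        back = read_model_tsv(p)
        assert np.array_equal(back.initial, m.initial)
        assert np.array_equal(back.transition, m.transition)
        assert np.array_equal(back.emission, m.emission)
        assert back.mark_names == m.mark_names
        assert back.state_labels == m.state_labels


class TestDecodeSegmentation:
    def test_viterbi_decode_returns_labelled_segmentation(self, small_layout):
        rng = np.random.default_rng(1)
        start, trans, emis = random_hmm(rng, 2, 2)
        m = _model(start, trans, emis)
        X = rng.integers(0, 2, (small_layout.n_bins, 2)).astype(float)
        seg = viterbi_decode(m, X, small_layout)
        assert seg.states.shape == (small_layout.n_bins,)
        assert seg.state_labels == m.state_labels

    def test_dimension_mismatch_rejected(self, small_layout):
        rng = np.random.default_rng(1)
        start, trans, emis = random_hmm(rng, 2, 3)
        with pytest.raises(ValueError, match="marks"):
            viterbi_decode(
                _model(start, trans, emis),
                np.zeros((small_layout.n_bins, 2)),
                small_layout,
            )
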