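"""Bernoulli-HMM inference, training, decoding, collapse and enrichment."""

import numpy as np
import pandas as pd
import pytest

from chromdyn import (BinGrid, Segmentation, StateModel, baum_welch_train,
                      collapse_states, decode_sequences, emission_loglik,
                      feature_fold_enrichment, forward_backward,
                      select_state_number)
from chromdyn.hmm import n_free_parameters

from conftest import (brute_force_loglik, brute_force_posteriors,
                      match_states, random_hmm_instance)


def _model(pi, A, em, marks=None):
    K, M = np.asarray(em).shape
    return StateModel(K, np.asarray(pi, float), np.asarray(A, float),
                      np.asarray(em, float),
                      marks or tuple(f"m{j}" for j in range(M)))


def _sample_hmm(pi, A, em, T, rng):
    K, M = em.shape
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(K, p=pi)
    for t in range(1, T):
        states[t] = rng.choice(K, p=A[states[t - 1]])
    obs = (rng.random((T, M)) < em[states]).astype(float)
    return states, obs


TWO_STATE = dict(
    pi=np.array([0.6, 0.4]),
    A=np.array([[0.95, 0.05], [0.10, 0.90]]),
    em=np.array([[0.9, 0.9, 0.1], [0.1, 0.1, 0.9]]),
)


class TestEmission:
    def test_uniform_emissions_give_uniform_likelihood(self):
        m = _model([1.0], [[1.0]], [[0.5] * 5])
        for obs in ([0, 0, 0, 0, 0], [1, 0, 1, 0, 1], [1] * 5):
            assert emission_loglik(np.array(obs), 1, m) == pytest.approx(
                np.log(1 / 32))

    def test_matching_hard_emissions_give_probability_one(self):
        m = _model([1.0], [[1.0]], [[1.0, 0.0, 1.0]])
        ll = emission_loglik(np.array([1, 0, 1]), 1, m)
        assert ll == pytest.approx(0.0, abs=1e-5)   # up to the 1e-6 clamp

    def test_hand_case(self):
        m = _model([1.0], [[1.0]], [[0.9, 0.1]])
        assert emission_loglik(np.array([1, 0]), 1, m) == pytest.approx(
            np.log(0.81))


class TestForwardBackward:
    @pytest.mark.parametrize("K", [1, 2, 3])
    @pytest.mark.parametrize("T", [1, 3, 6])
    @pytest.mark.parametrize("M", [1, 3])
    def test_matches_path_enumeration(self, K, T, M):
        rng = np.random.default_rng(1000 * K + 10 * T + M)
        obs, pi, A, em = random_hmm_instance(K, T, M, rng)
        ll, gamma = forward_backward(obs, _model(pi, A, em))
        assert ll == pytest.approx(brute_force_loglik(obs, pi, A, em),
                                   abs=1e-9)
        np.testing.assert_allclose(
            gamma, brute_force_posteriors(obs, pi, A, em), atol=1e-9)

    def test_single_state_reduces_to_emission_sum(self):
        rng = np.random.default_rng(3)
        obs = (rng.random((20, 4)) < 0.5).astype(float)
        em = np.array([[0.7, 0.2, 0.5, 0.9]])
        m = _model([1.0], [[1.0]], em)
        ll, _ = forward_backward(obs, m)
        expected = sum(emission_loglik(o, 1, m) for o in obs)
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_posteriors_normalized(self):
        rng = np.random.default_rng(4)
        obs, pi, A, em = random_hmm_instance(3, 200, 4, rng)
        _, gamma = forward_backward(obs, _model(pi, A, em))
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            forward_backward(np.empty((0, 2)), _model(*TWO_STATE.values()))


class TestBaumWelch:
    def test_loglik_never_decreases(self):
        rng = np.random.default_rng(5)
        _, obs = _sample_hmm(TWO_STATE["pi"], TWO_STATE["A"], TWO_STATE["em"],
                             500, rng)
        model = baum_welch_train([obs], K=2, seed=11, max_iter=40,
                                 tol=1e-10, n_restarts=1)
        hist = np.array(model.training_history)
        assert len(hist) > 1 and np.all(np.diff(hist) >= -1e-8)

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        _, obs = _sample_hmm(TWO_STATE["pi"], TWO_STATE["A"], TWO_STATE["em"],
                             300, rng)
        m1 = baum_welch_train([obs], K=2, seed=3, max_iter=15, n_restarts=2)
        m2 = baum_welch_train([obs], K=2, seed=3, max_iter=15, n_restarts=2)
        np.testing.assert_array_equal(m1.emission, m2.emission)
        np.testing.assert_array_equal(m1.transition, m2.transition)

    def test_two_state_emission_recovery(self):
        """Well-separated 2-state data, 50k bins: emissions within 0.03."""
        rng = np.random.default_rng(7)
        _, obs = _sample_hmm(TWO_STATE["pi"], TWO_STATE["A"], TWO_STATE["em"],
                             50_000, rng)
        model = baum_welch_train([obs], K=2, seed=1, max_iter=100, tol=1e-4,
                                 n_restarts=2)
        perm = match_states(model.emission, TWO_STATE["em"])
        aligned = model.emission[np.argsort(perm)]
        assert np.abs(aligned - TWO_STATE["em"]).max() < 0.03

    def test_excess_states_warn(self):
        obs = np.zeros((50, 2))
        obs[25:, 0] = 1            # two distinct patterns
        with pytest.warns(UserWarning, match="distinct observation patterns"):
            baum_welch_train([obs], K=4, seed=0, max_iter=5, n_restarts=1)

    def test_multiple_sequences_contribute(self):
        rng = np.random.default_rng(8)
        seqs = [_sample_hmm(TWO_STATE["pi"], TWO_STATE["A"], TWO_STATE["em"],
                            400, rng)[1] for _ in range(3)]
        model = baum_welch_train(seqs, K=2, seed=2, max_iter=30, n_restarts=1)
        assert np.isfinite(model.log_likelihood)


class TestDecode:
    def test_uniform_model_ties_break_to_state_one(self):
        m = _model([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
                   [[0.5, 0.5], [0.5, 0.5]])
        obs = np.array([[0, 1], [1, 1], [0, 0]], dtype=float)
        (states, _), = decode_sequences([obs], m)
        assert (states == 1).all()

    def test_single_bin_equals_initial_times_emission(self):
        pi, A, em = TWO_STATE["pi"], TWO_STATE["A"], TWO_STATE["em"]
        m = _model(pi, A, em)
        obs = np.array([[1, 1, 0]], dtype=float)
        post = pi * np.exp([emission_loglik(obs[0], k, m) for k in (1, 2)])
        (states, mp), = decode_sequences([obs], m)
        assert states[0] == np.argmax(post) + 1
        assert mp[0] == pytest.approx(post.max() / post.sum())

    def test_planted_state_recovery_above_95pct(self):
        rng = np.random.default_rng(9)
        states, obs = _sample_hmm(TWO_STATE["pi"], TWO_STATE["A"],
                                  TWO_STATE["em"], 50_000, rng)
        model = baum_welch_train([obs], K=2, seed=1, max_iter=100, tol=1e-4,
                                 n_restarts=2)
        perm = match_states(model.emission, TWO_STATE["em"])
        (dec, _), = decode_sequences([obs], model)
        assert (perm[dec - 1] == states).mean() > 0.95

    def test_viterbi_agrees_on_clean_data(self):
        rng = np.random.default_rng(10)
        em = np.array([[0.99, 0.01], [0.01, 0.99]])
        _, obs = _sample_hmm(np.array([0.5, 0.5]),
                             np.array([[0.9, 0.1], [0.1, 0.9]]), em, 500, rng)
        m = _model([0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], em)
        (post, _), = decode_sequences([obs], m, method="posterior")
        (vit, _), = decode_sequences([obs], m, method="viterbi")
        assert (post == vit).mean() > 0.99


class TestModelSelection:
    def test_requested_k_row_present(self):
        rng = np.random.default_rng(11)
        _, obs = _sample_hmm(TWO_STATE["pi"], TWO_STATE["A"], TWO_STATE["em"],
                             800, rng)
        tab = select_state_number([obs], [2], seed=0, max_iter=20,
                                  n_restarts=1)
        assert tab["K"].tolist() == [2]

    def test_loglik_nondecreasing_in_k(self):
        rng = np.random.default_rng(12)
        _, obs = _sample_hmm(TWO_STATE["pi"], TWO_STATE["A"], TWO_STATE["em"],
                             2_000, rng)
        tab = select_state_number([obs], [1, 2, 3], seed=0, max_iter=40,
                                  n_restarts=2)
        ll = tab["log_likelihood"].to_numpy()
        assert ll[1] >= ll[0] - 1e-6 and ll[2] >= ll[1] - 1.0  # restart noise

    def test_bic_arithmetic(self):
        rng = np.random.default_rng(13)
        _, obs = _sample_hmm(TWO_STATE["pi"], TWO_STATE["A"], TWO_STATE["em"],
                             300, rng)
        tab = select_state_number([obs], [2], seed=0, max_iter=10,
                                  n_restarts=1)
        K, M, n = 2, 3, 300
        p = (K - 1) + K * (K - 1) + K * M
        assert n_free_parameters(K, M) == p
        expected = -2 * tab.loc[0, "log_likelihood"] + p * np.log(n)
        assert tab.loc[0, "BIC"] == pytest.approx(expected)


MARKS5 = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3", "H3K9me3")


class TestCollapse:
    def _collapse_row(self, row):
        return collapse_states(np.array([row]), mark_names=MARKS5)[1]

    def test_all_low_is_quiescent(self):
        assert self._collapse_row([0.1, 0.15, 0.1, 0.05, 0.19]) == "quiescent"

    def test_poised_promoter_wins_over_repression(self):
        # high H3K4me3 with high H3K27me3: a poised promoter, still a promoter
        assert self._collapse_row([0.1, 0.1, 0.8, 0.6, 0.1]) == "promoter"

    def test_poised_enhancer_by_h3k4me1_alone(self):
        # high H3K4me1, low H3K27ac
        assert self._collapse_row([0.1, 0.7, 0.1, 0.1, 0.1]) == "enhancer"

    def test_heterochromatin_and_repressed(self):
        assert self._collapse_row([0.1, 0.1, 0.1, 0.6, 0.9]) == "heterochromatin"
        assert self._collapse_row([0.1, 0.1, 0.1, 0.6, 0.1]) == "repressed"

    def test_pure_function_commutes_with_permutation(self):
        rng = np.random.default_rng(14)
        em = rng.uniform(0, 1, size=(6, 5))
        base = collapse_states(em, mark_names=MARKS5)
        perm = rng.permutation(6)
        permuted = collapse_states(em[perm], mark_names=MARKS5)
        for new_idx, old_idx in enumerate(perm, start=1):
            assert permuted[new_idx] == base[old_idx + 1]

    def test_attaches_to_model(self):
        m = _model([1.0], [[1.0]], [[0.9, 0.1, 0.1, 0.1, 0.1]], MARKS5)
        cats = collapse_states(m)
        assert cats == {1: "enhancer"} and m.category_of_state == cats


class TestFoldEnrichment:
    def _segmentation(self, states):
        grid = BinGrid([("chr1", 200 * len(states))], 200)
        return Segmentation(grid, np.asarray(states), np.ones(len(states)))

    def test_whole_genome_feature_is_one(self):
        seg = self._segmentation([1] * 50 + [2] * 50)
        feats = {"genome": pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                         "end": [200 * 100]})}
        fe = feature_fold_enrichment(seg, feats)
        np.testing.assert_allclose(fe["genome"], 1.0)

    def test_disjoint_state_is_zero(self):
        seg = self._segmentation([1] * 50 + [2] * 50)
        feats = {"late": pd.DataFrame({"chrom": ["chr1"],
                                       "start": [200 * 50],
                                       "end": [200 * 100]})}
        fe = feature_fold_enrichment(seg, feats)
        assert fe.loc["E1", "late"] == 0.0
        assert fe.loc["E2", "late"] == pytest.approx(2.0)

    def test_counting_oracle(self):
        # state 2 covers 10 bins, 8 on the feature; feature covers 20 of 100
        states = np.ones(100, dtype=int)
        states[:10] = 2
        seg = self._segmentation(states)
        feat = pd.DataFrame({"chrom": ["chr1"] * 2,
                             "start": [0, 200 * 88],
                             "end": [200 * 8, 200 * 100]})
        fe = feature_fold_enrichment(seg, {"f": feat})
        assert fe.loc["E2", "f"] == pytest.approx((8 / 10) / (20 / 100))

    def test_empty_feature_is_missing(self):
        seg = self._segmentation([1] * 10)
        feat = pd.DataFrame({"chrom": ["chrZ"], "start": [0], "end": [100]})
        fe = feature_fold_enrichment(seg, {"nowhere": feat})
        assert fe["nowhere"].isna().all()
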