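import numpy as np
import pytest
from scipy.special import logsumexp

from gaitphase import GaitPhaseHMM, LabelSequence
from gaitphase.hmm import (HmmModel, LEFT_RIGHT_A, ObservationSequence,
                           UNIFORM_PI, baum_welch, forward_loglik, init_model,
                           train_spt, train_sst, viterbi, viterbi_score)
from conftest import brute_force_path_stats, random_left_right_model


def labeled_gaussian_data(rng, n_per_state=300, fs=200.0):
    """Synthetic per-state Gaussian features with known means."""
    means = np.array([[200.0, -2000.0], [0.0, 0.0], [150.0, 1500.0], [300.0, 3000.0]])
    feats, labels = [], []
    for i in range(4):
        feats.append(rng.normal(means[i], [20.0, 200.0], size=(n_per_state, 2)))
        labels.append(np.full(n_per_state, i, dtype=np.int8))
    x = np.vstack(feats)
    lab = np.concatenate(labels)
    return ObservationSequence(x, fs), LabelSequence(lab, fs), means


class TestInit:
    def test_transition_matrix_and_pi_are_the_left_right_prior(self, healthy_pairs):
        model = init_model([p[0] for p in healthy_pairs[:2]],
                           [p[1] for p in healthy_pairs[:2]], seed=0)
        assert model.A[0, 0] == 0.9 and model.A[0, 1] == 0.1
        assert np.array_equal(model.A, LEFT_RIGHT_A)
        assert np.allclose(model.pi, 0.25)

    def test_mixture_means_bracket_state_sample_mean(self):
        rng = np.random.default_rng(0)
        obs, lab, means = labeled_gaussian_data(rng)
        model = init_model([obs], [lab], seed=0)
        for i in range(4):
            state_mean = obs.features[lab.labels == i].mean(axis=0)
            lo = model.means[i].min(axis=0)
            hi = model.means[i].max(axis=0)
            assert np.all(lo <= state_mean + 1e-9)
            assert np.all(hi >= state_mean - 1e-9)
            assert np.allclose(model.weights[i] @ model.means[i], state_mean,
                               rtol=0.05, atol=5.0)

    def test_underpopulated_state_rejected(self):
        obs = ObservationSequence(np.zeros((6, 2)), 200.0)
        lab = LabelSequence(np.array([0, 0, 0, 1, 2, 3]), 200.0)  # SP has 1 sample
        with pytest.raises(ValueError, match="at least 3"):
            init_model([obs], [lab], seed=0)


class TestForward:
    def test_single_observation_closed_form(self):
        rng = np.random.default_rng(2)
        model = random_left_right_model(rng)
        obs = ObservationSequence(rng.normal(0, 3, (1, 2)), 200.0)
        expect = logsumexp(np.log(model.pi) + model.log_emission(obs.features)[0])
        assert forward_loglik(model, obs) == pytest.approx(float(expect), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        model = random_left_right_model(rng)
        L = int(rng.integers(2, 7))
        obs = ObservationSequence(rng.normal(0, 3, (L, 2)), 200.0)
        brute_ll, brute_best = brute_force_path_stats(model, obs)
        assert forward_loglik(model, obs) == pytest.approx(brute_ll, abs=1e-8)
        assert viterbi_score(model, obs) == pytest.approx(brute_best, abs=1e-8)

    def test_state_permutation_of_identical_emissions_preserves_likelihood(self):
        rng = np.random.default_rng(4)
        model = random_left_right_model(rng)
        # identical emissions in every state: only the chain remains
        model.weights[:] = model.weights[0]
        model.means[:] = model.means[0]
        model.covs[:] = model.covs[0]
        obs = ObservationSequence(rng.normal(0, 3, (30, 2)), 200.0)
        ll = forward_loglik(model, obs)
        rolled = HmmModel(model.A, model.pi, model.weights, model.means, model.covs)
        assert forward_loglik(rolled, obs) == pytest.approx(ll, abs=1e-9)

    def test_extreme_observations_do_not_underflow(self):
        rng = np.random.default_rng(5)
        model = random_left_right_model(rng)
        obs = ObservationSequence(np.full((50, 2), 1e4), 200.0)
        assert np.isfinite(forward_loglik(model, obs))


class TestViterbi:
    def test_recovers_cyclic_sequence_with_separated_emissions(self):
        rng = np.random.default_rng(1)
        model = random_left_right_model(rng)
        centers = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [-100.0, -100.0]])
        for i in range(4):
            model.means[i] = centers[i]
            model.covs[i] = np.eye(2)[None].repeat(3, axis=0)
            model.weights[i] = [1 / 3] * 3
        path_true = np.repeat([0, 1, 2, 3, 0, 1, 2, 3], 5)
        obs = ObservationSequence(centers[path_true], 200.0)
        decoded = viterbi(model, obs)
        assert np.array_equal(decoded.labels, path_true)

    def test_single_observation_is_map_state(self):
        rng = np.random.default_rng(3)
        model = random_left_right_model(rng)
        obs = ObservationSequence(rng.normal(0, 3, (1, 2)), 200.0)
        expect = int(np.argmax(np.log(model.pi) + model.log_emission(obs.features)[0]))
        assert viterbi(model, obs).labels[0] == expect

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ObservationSequence(np.empty((0, 2)), 200.0)


class TestBaumWelch:
    def test_loglik_nondecreasing_and_zeros_preserved(self, healthy_pairs):
        obs = [p[0] for p in healthy_pairs[:2]]
        labs = [p[1] for p in healthy_pairs[:2]]
        model = init_model(obs, labs, seed=0)
        trained, trace = baum_welch(model, obs, max_iter=15)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) >= -1e-8)
        assert np.all(trained.A[LEFT_RIGHT_A == 0.0] == 0.0)
        trained.validate(atol=1e-8)

    def test_rows_stochastic_and_covariances_pd_each_iteration(self, healthy_pairs):
        obs = [healthy_pairs[0][0]]
        model = init_model(obs, [healthy_pairs[0][1]], seed=1)
        for _ in range(5):
            model, _ = baum_welch(model, obs, max_iter=1, tol=0.0)
            assert np.allclose(model.A.sum(axis=1), 1.0, atol=1e-9)
            for i in range(4):
                for k in range(3):
                    assert np.all(np.linalg.eigvalsh(model.covs[i, k]) > 0)

    def test_near_fixed_point_on_model_generated_data(self):
        """Data sampled exactly from the model: EM moves parameters < 1 %."""
        rng = np.random.default_rng(6)
        model = random_left_right_model(rng)
        model.means *= 10  # separate states so the fit is identifiable
        # sample a long sequence from the model
        T = 4000
        states = np.empty(T, dtype=int)
        states[0] = rng.choice(4, p=model.pi)
        for t in range(1, T):
            states[t] = rng.choice(4, p=model.A[states[t - 1]])
        x = np.empty((T, 2))
        for t in range(T):
            k = rng.choice(3, p=model.weights[states[t]])
            x[t] = rng.multivariate_normal(model.means[states[t], k],
                                           model.covs[states[t], k])
        obs = ObservationSequence(x, 200.0)
        # EM converges to the sample MLE; near it, one more iteration
        # moves the parameters by well under 1 %
        near, _ = baum_welch(model, [obs], max_iter=8, tol=0.0)
        step, _ = baum_welch(near, [obs], max_iter=1, tol=0.0)
        assert np.max(np.abs(step.A - near.A)) < 0.01
        rel = np.abs(step.means - near.means) / (np.abs(near.means) + 1.0)
        assert np.max(rel) < 0.01

    def test_frozen_transitions_stay_at_prior(self, healthy_pairs):
        obs = [healthy_pairs[0][0]]
        model = init_model(obs, [healthy_pairs[0][1]], seed=0)
        trained, _ = baum_welch(model, obs, max_iter=5, update_transitions=False)
        assert np.array_equal(trained.A, LEFT_RIGHT_A)

    def test_matches_hmmlearn_forward_likelihood(self, healthy_pairs):
        """Independent implementation check of the forward pass."""
        from hmmlearn.hmm import GMMHMM

        obs = healthy_pairs[0][0]
        model = init_model([obs], [healthy_pairs[0][1]], seed=0)
        gh = GMMHMM(n_components=4, n_mix=3, covariance_type="full", init_params="")
        gh.startprob_ = model.pi
        gh.transmat_ = model.A
        gh.weights_ = model.weights
        gh.means_ = model.means
        gh.covars_ = model.covs
        assert forward_loglik(model, obs) == pytest.approx(
            gh.score(obs.features), rel=1e-10)


class TestTrainingRegimes:
    def test_sst_folds_cover_each_trial_once(self, healthy_pairs):
        folds = train_sst(healthy_pairs, seed=0, max_iter=10)
        assert len(folds) == 3
        assert sorted(f[1] for f in folds) == [0, 1, 2]
        for _, held, pred in folds:
            assert len(pred) == len(healthy_pairs[held][0])

    def test_sst_identical_trials_give_identical_models(self, healthy_pairs):
        same = [healthy_pairs[0]] * 3
        folds = train_sst(same, seed=0, max_iter=20)
        a, b = folds[0][0], folds[1][0]
        assert np.max(np.abs(a.A - b.A)) < 1e-3
        assert np.max(np.abs(a.means - b.means)) < 1e-3
        assert np.max(np.abs(a.covs - b.covs)) < 1e-3

    def test_sst_requires_three_trials(self, healthy_pairs):
        with pytest.raises(ValueError):
            train_sst(healthy_pairs[:2], seed=0)

    def test_spt_healthy_excludes_target(self, healthy_pairs):
        subjects = {"A": healthy_pairs, "B": healthy_pairs, "C": healthy_pairs}
        with pytest.raises(ValueError):
            train_spt(subjects, "not-a-subject", mode="healthy")

    def test_spt_patient_average_of_identicals_equals_individual(self, clean_trial):
        """With identical strides the ensemble-average stride equals any
        single stride's normalized trace, so the trained emission means sit
        on the template values."""
        from gaitphase.hmm import SPT_POINTS, _phase_segments
        from gaitphase.models import observation_pair
        from gaitphase.phases import GaitPhase
        from gaitphase.preprocessing import time_normalize_segments

        obs, lab = observation_pair(clean_trial.imu, clean_trial.fsr)
        strides = _phase_segments(lab)
        assert len(strides) >= 5
        omega = obs.features[:, 0]
        # every stride is identical (no jitter): per-index spread ~ 0
        for phase in GaitPhase:
            rows = np.vstack([
                time_normalize_segments(omega, [s[int(phase)]], SPT_POINTS[phase])
                for s in strides])
            # identical strides; residual spread comes only from the 200 Hz
            # sampling phase beating against the stride period on steep slopes
            assert np.max(rows.std(axis=0)) < 0.05 * 400.0
        subjects = {"A": [(obs, lab), (obs, lab)], "B": [(obs, lab), (obs, lab)]}
        model = train_spt(subjects, "P1", mode="patient", seed=0, max_iter=5)
        model.validate(atol=1e-6)
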