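import numpy as np
import pytest

from gaitphase import (GaitSimParams, simulate_trial)
from gaitphase.hmm import HmmModel, ObservationSequence, UNIFORM_PI
from gaitphase.models import observation_pair


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, jitter-free healthy conditions (deterministic waveform)."""
    return GaitSimParams(n_strides=10, stride_cv=0.0, noise_sd_gyro=0.0,
                         noise_sd_accel=0.0, seed=1)


@pytest.fixture(scope="session")
def clean_trial(clean_params):
    return simulate_trial(clean_params)


@pytest.fixture(scope="session")
def healthy_pairs():
    """Three default-noise healthy trials as (observations, labels) pairs."""
    trials = [simulate_trial(GaitSimParams(n_strides=10, seed=7 + k))
              for k in range(3)]
    return [observation_pair(t.imu, t.fsr) for t in trials]


def random_left_right_model(rng) -> HmmModel:
    """A random valid model on the left-right topology (for oracle tests)."""
    A = np.zeros((4, 4))
    diag = rng.uniform(0.6, 0.95, 4)
    for i in range(4):
        A[i, i] = diag[i]
        A[i, (i + 1) % 4] = 1.0 - diag[i]
    weights = rng.dirichlet(np.ones(3), size=4)
    means = rng.normal(0.0, 3.0, (4, 3, 2))
    covs = np.empty((4, 3, 2, 2))
    for i in range(4):
        for k in range(3):
            L = rng.normal(0.0, 1.0, (2, 2))
            covs[i, k] = L @ L.T + 0.5 * np.eye(2)
    return HmmModel(A, UNIFORM_PI.copy(), weights, means, covs)


def brute_force_path_stats(model: HmmModel, obs: ObservationSequence):
    """Enumerate all 4^T state paths: (log total likelihood, best path score)."""
    import itertools

    from scipy.special import logsumexp

    logb = model.log_emission(obs.features)
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logpi = np.log(model.pi)
    T = logb.shape[0]
    scores = []
    for path in itertools.product(range(4), repeat=T):
        lp = logpi[path[0]] + logb[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logb[t, path[t]]
        scores.append(lp)
    return float(logsumexp(scores)), float(max(scores))
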