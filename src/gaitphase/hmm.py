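"""Left-right continuous HMM gait-phase detector.

The gait cycle is modeled as a 4-state hidden Markov chain whose states
are the gait phases in cyclic order (HS, FF, HO, SP).  The left-right
structure allows only self-transitions and steps to the cyclic successor;
because phase transitions occupy a narrow fraction of the cycle the
initial transition matrix places 0.9 on the diagonal and 0.1 on the
successor (the SP row wraps back to HS, making the chain ergodic over
whole strides)::

        [0.9 0.1 0.0 0.0]
    A = [0.0 0.9 0.1 0.0]
        [0.0 0.0 0.9 0.1]
        [0.1 0.0 0.0 0.9]

The initial state distribution is uniform.  Emissions are bivariate
feature vectors (sagittal angular velocity omega in deg/s and its
first-order finite-difference derivative alpha in deg/s^2), described per
state by a three-component Gaussian mixture — the standard trade-off
between flexibility and parameter count for foot gyroscope signals.

Training is expectation-maximization (Baum-Welch) over pooled observation
sequences, initialized from FSR-labeled data (per-state mixtures fitted
by EM on the labeled subsets); decoding is the Viterbi algorithm.  The
structural zeros of the transition matrix are invariant under EM, so the
left-right topology survives re-estimation.

Two training regimes mirror clinical practice: subject-specific training
(SST) — leave-one-trial-out across a subject's three trials — and
standardized-parameters training (SPT), which pools (healthy target) or
stride-averages (patient target) data from the remaining healthy subjects.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .phases import GaitPhase, LabelSequence, N_PHASES, PHASE_NAMES
from .preprocessing import angular_acceleration, time_normalize_segments

LEFT_RIGHT_A = np.array([
    [0.9, 0.1, 0.0, 0.0],
    [0.0, 0.9, 0.1, 0.0],
    [0.0, 0.0, 0.9, 0.1],
    [0.1, 0.0, 0.0, 0.9],
])
UNIFORM_PI = np.full(4, 0.25)
N_MIX = 3
_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ObservationSequence:
    """Ordered bivariate emission features at a fixed rate."""

    features: np.ndarray  # (T, 2): omega [deg/s], alpha [deg/s^2]
    fs: float

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != 2:
            raise ValueError("features must be a (T, 2) array")
        if self.features.shape[0] < 1:
            raise ValueError("observation sequence must be nonempty")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")

    def __len__(self) -> int:
        return self.features.shape[0]


@dataclass
class HmmModel:
    """Model parameters lambda = (A, B, pi) with per-state 3-component GMMs."""

    A: np.ndarray            # (4, 4) row-stochastic, left-right zero pattern
    pi: np.ndarray           # (4,)
    weights: np.ndarray      # (4, 3)
    means: np.ndarray        # (4, 3, 2)
    covs: np.ndarray         # (4, 3, 2, 2) symmetric positive definite

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)

    def validate(self, atol: float = 1e-9) -> None:
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=atol):
            raise ValueError("rows of A must sum to 1")
        if np.any(self.A[LEFT_RIGHT_A == 0.0] != 0.0):
            raise ValueError("A must preserve the left-right zero pattern")
        if not math.isclose(float(self.pi.sum()), 1.0, abs_tol=atol):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=atol):
            raise ValueError("mixture weights must sum to 1 per state")
        for i in range(N_PHASES):
            for k in range(N_MIX):
                c = self.covs[i, k]
                if not np.allclose(c, c.T, atol=1e-8) or np.any(np.linalg.eigvalsh(c) <= 0):
                    raise ValueError(f"covariance ({i},{k}) must be symmetric positive definite")

    def copy(self) -> "HmmModel":
        return HmmModel(self.A.copy(), self.pi.copy(), self.weights.copy(),
                        self.means.copy(), self.covs.copy())

    # ---- emission densities -------------------------------------------------

    def _component_logpdf(self, obs: np.ndarray) -> np.ndarray:
        """Per-component Gaussian log densities, shape (T, 4, 3)."""
        T = obs.shape[0]
        out = np.empty((T, N_PHASES, N_MIX))
        for i in range(N_PHASES):
            for k in range(N_MIX):
                cov = self.covs[i, k]
                chol = np.linalg.cholesky(cov)
                diff = obs - self.means[i, k]
                sol = np.linalg.solve(chol, diff.T)  # (2, T)
                maha = np.sum(sol * sol, axis=0)
                logdet = 2.0 * np.sum(np.log(np.diag(chol)))
                out[:, i, k] = -0.5 * (maha + logdet + 2 * _LOG2PI)
        return out

    def log_emission(self, obs: np.ndarray) -> np.ndarray:
        """log b_i(o_t) for every state, shape (T, 4)."""
        comp = self._component_logpdf(obs)
        with np.errstate(divide="ignore"):
            logw = np.log(self.weights)
        return logsumexp(comp + logw[None, :, :], axis=2)

    # ---- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "A": self.A.tolist(), "pi": self.pi.tolist(),
            "weights": self.weights.tolist(), "means": self.means.tolist(),
            "covs": self.covs.tolist(), "states": list(PHASE_NAMES),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HmmModel":
        d = json.loads(text)
        return cls(np.array(d["A"]), np.array(d["pi"]), np.array(d["weights"]),
                   np.array(d["means"]), np.array(d["covs"]))


def features_from_gyro(gy, fs: float) -> ObservationSequence:
    """Observation vectors (omega, alpha) from an angular-velocity trace."""
    gy = np.asarray(gy, dtype=float)
    return ObservationSequence(
        np.column_stack((gy, angular_acceleration(gy, fs))), fs)


# ---------------------------------------------------------------------------
# initialization


def init_model(
    train_features: list[ObservationSequence],
    train_labels: list[LabelSequence],
    seed: int = 0,
) -> HmmModel:
    """Supervised initialization from FSR-labeled feature sequences.

    A is the left-right prior (0.9 diagonal / 0.1 successor), pi uniform;
    each state's 3-component bivariate GMM is fitted by EM (k-means
    initialized with ``seed``) to the labeled feature subset of that state.
    """
    if len(train_features) != len(train_labels):
        raise ValueError("features and labels must pair per trial")
    per_state: list[list[np.ndarray]] = [[] for _ in range(N_PHASES)]
    for obs, lab in zip(train_features, train_labels):
        x = obs.features
        codes = lab.labels
        m = min(x.shape[0], codes.size)
        for i in range(N_PHASES):
            sel = x[:m][codes[:m] == i]
            if sel.size:
                per_state[i].append(sel)
    weights = np.empty((N_PHASES, N_MIX))
    means = np.empty((N_PHASES, N_MIX, 2))
    covs = np.empty((N_PHASES, N_MIX, 2, 2))
    for i in range(N_PHASES):
        data = np.vstack(per_state[i]) if per_state[i] else np.empty((0, 2))
        if data.shape[0] < N_MIX:
            raise ValueError(
                f"state {PHASE_NAMES[i]} has {data.shape[0]} labeled samples; "
                f"need at least {N_MIX} to fit the mixture")
        gm = GaussianMixture(n_components=N_MIX, covariance_type="full",
                             reg_covar=1e-6, random_state=seed & 0x7FFFFFFF,
                             n_init=1, init_params="k-means++")
        gm.fit(data)
        weights[i] = gm.weights_
        means[i] = gm.means_
        covs[i] = gm.covariances_
    model = HmmModel(LEFT_RIGHT_A.copy(), UNIFORM_PI.copy(), weights, means, covs)
    model.validate(atol=1e-6)
    return model


# ---------------------------------------------------------------------------
# inference


def _forward_scaled(logb: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward recursion.

    Works on shifted emission probabilities (b~ = exp(logb - max)) so
    densities far below underflow remain usable; the per-step scale
    factors recover the exact log-likelihood.
    """
    T = logb.shape[0]
    alpha = np.empty((T, N_PHASES))
    shifts = np.max(logb, axis=1)
    b = np.exp(logb - shifts[:, None])
    logc = np.empty(T)
    a = pi * b[0]
    s = a.sum()
    if s <= 0 or not np.isfinite(s):
        raise FloatingPointError("forward recursion underflow at t=0")
    alpha[0] = a / s
    logc[0] = np.log(s) + shifts[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * b[t]
        s = a.sum()
        if s <= 0 or not np.isfinite(s):
            raise FloatingPointError(f"forward recursion underflow at t={t}")
        alpha[t] = a / s
        logc[t] = np.log(s) + shifts[t]
    return alpha, logc


def forward_loglik(model: HmmModel, obs: ObservationSequence) -> float:
    """Total observation log-likelihood (nats) by the scaled forward pass."""
    logb = model.log_emission(obs.features)
    _, logc = _forward_scaled(logb, model.A, model.pi)
    return float(np.sum(logc))


def viterbi(model: HmmModel, obs: ObservationSequence) -> LabelSequence:
    """Most likely state path (maximum a posteriori in log space).

    Ties break toward the lower state index.
    """
    if len(obs) == 0:
        raise ValueError("empty observation sequence")
    logb = model.log_emission(obs.features)
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logpi = np.log(model.pi)
    T = logb.shape[0]
    delta = logpi + logb[0]
    psi = np.zeros((T, N_PHASES), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(N_PHASES)] + logb[t]
    path = np.empty(T, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return LabelSequence(path, obs.fs)


def viterbi_score(model: HmmModel, obs: ObservationSequence) -> float:
    """Log-probability of the Viterbi path (joint, nats)."""
    logb = model.log_emission(obs.features)
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logpi = np.log(model.pi)
    delta = logpi + logb[0]
    for t in range(1, logb.shape[0]):
        delta = np.max(delta[:, None] + logA, axis=0) + logb[t]
    return float(np.max(delta))


# ---------------------------------------------------------------------------
# Baum-Welch


def baum_welch(
    model: HmmModel,
    obs_list: list[ObservationSequence],
    tol: float = 1e-4,
    max_iter: int = 100,
    update_transitions: bool = True,
    cov_floor_scale: float = 1e-6,
):
    """EM re-estimation of lambda over pooled observation sequences.

    Stops when the relative improvement of the total log-likelihood falls
    below ``tol`` or after ``max_iter`` iterations.  Structural zeros of A
    are invariant (their expected transition counts are identically zero);
    a diagonal covariance floor of ``cov_floor_scale`` times the pooled
    per-dimension data variance keeps the 3-component mixtures from
    collapsing on small per-phase datasets.

    Returns
    -------
    (HmmModel, list of float)
        The re-estimated model and the per-iteration log-likelihood trace
        (trace[k] is the likelihood *under the model of iteration k*, so
        the trace is non-decreasing for exact EM).
    """
    if not obs_list:
        raise ValueError("need at least one observation sequence")
    model = model.copy()
    pooled = np.vstack([o.features for o in obs_list])
    floor = cov_floor_scale * np.var(pooled, axis=0)
    floor = np.where(floor > 0, floor, 1e-12)
    trace: list[float] = []
    prev_ll = -np.inf
    for it in range(max_iter):
        ll_total = 0.0
        A_num = np.zeros((N_PHASES, N_PHASES))
        pi_acc = np.zeros(N_PHASES)
        w_acc = np.zeros((N_PHASES, N_MIX))
        mu_acc = np.zeros((N_PHASES, N_MIX, 2))
        cov_acc = np.zeros((N_PHASES, N_MIX, 2, 2))
        for obs in obs_list:
            x = obs.features
            comp = model._component_logpdf(x)           # (T, 4, 3)
            with np.errstate(divide="ignore"):
                logw = np.log(model.weights)
            logb = logsumexp(comp + logw[None], axis=2)  # (T, 4)
            alpha, logc = _forward_scaled(logb, model.A, model.pi)
            ll_total += float(np.sum(logc))
            # scaled backward pass
            T = x.shape[0]
            beta = np.empty((T, N_PHASES))
            beta[-1] = 1.0
            b = np.exp(logb - np.max(logb, axis=1)[:, None])
            for t in range(T - 2, -1, -1):
                v = model.A @ (b[t + 1] * beta[t + 1])
                s = v.sum()
                beta[t] = v / s
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            # expected transition counts
            for t in range(T - 1):
                m = (alpha[t][:, None] * model.A * (b[t + 1] * beta[t + 1])[None, :])
                s = m.sum()
                if s > 0:
                    A_num += m / s
            pi_acc += gamma[0]
            # per-component responsibilities
            with np.errstate(divide="ignore"):
                logr = comp + logw[None] - logb[:, :, None]
            r = gamma[:, :, None] * np.exp(logr)         # (T, 4, 3)
            w_acc += r.sum(axis=0)
            mu_acc += np.einsum("tik,td->ikd", r, x)
            for i in range(N_PHASES):
                for k in range(N_MIX):
                    d = x - model.means[i, k]
                    cov_acc[i, k] += (r[:, i, k][:, None] * d).T @ d
        if not np.isfinite(ll_total):
            raise FloatingPointError(f"non-finite likelihood at iteration {it}")
        trace.append(ll_total)
        # M-step
        if update_transitions:
            denom = A_num.sum(axis=1, keepdims=True)
            newA = np.where(denom > 0, A_num / np.where(denom > 0, denom, 1.0), model.A)
            newA[LEFT_RIGHT_A == 0.0] = 0.0
            newA /= newA.sum(axis=1, keepdims=True)
            model.A = newA
            model.pi = pi_acc / pi_acc.sum()
        occ = w_acc.sum(axis=1, keepdims=True)
        model.weights = w_acc / np.where(occ > 0, occ, 1.0)
        denom = np.where(w_acc > 0, w_acc, 1.0)
        model.means = mu_acc / denom[:, :, None]
        covs = cov_acc / denom[:, :, None, None]
        covs = 0.5 * (covs + np.swapaxes(covs, -1, -2))
        covs[..., 0, 0] += floor[0]
        covs[..., 1, 1] += floor[1]
        model.covs = covs
        if prev_ll > -np.inf:
            rel = (ll_total - prev_ll) / max(abs(prev_ll), 1.0)
            if rel < tol:
                break
        prev_ll = ll_total
    return model, trace


# ---------------------------------------------------------------------------
# training regimes


def train_sst(
    trials: list[tuple[ObservationSequence, LabelSequence]],
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 100,
):
    """Subject-specific training: leave-one-trial-out over three trials.

    For each fold, the model is initialized and Baum-Welch-trained on two
    trials and decoded (Viterbi) on the held-out one.

    Returns a list of three (model, held_out_index, predicted labels).
    """
    if len(trials) != 3:
        raise ValueError("subject-specific training expects exactly 3 trials")
    folds = []
    for held in range(3):
        train = [trials[i] for i in range(3) if i != held]
        model = init_model([t[0] for t in train], [t[1] for t in train], seed=seed)
        model, _ = baum_welch(model, [t[0] for t in train], tol=tol, max_iter=max_iter)
        pred = viterbi(model, trials[held][0])
        folds.append((model, held, pred))
    return folds


def _phase_segments(labels: LabelSequence):
    """Per-stride, per-phase (start, stop) index ranges between HS onsets."""
    runs = labels.runs()
    strides = []
    current: dict[int, tuple[int, int]] = {}
    for phase, a, b in runs:
        if phase is GaitPhase.HS:
            if len(current) == 4:
                strides.append(current)
            current = {}
        if int(phase) not in current:
            current[int(phase)] = (a, b)
    if len(current) == 4:
        strides.append(current)
    return strides


# normalized points per phase for the stride-ensemble average (101 total)
SPT_POINTS = {GaitPhase.HS: 10, GaitPhase.FF: 35, GaitPhase.HO: 26, GaitPhase.SP: 30}


def train_spt(
    healthy_trials: dict[str, list[tuple[ObservationSequence, LabelSequence]]],
    target_subject: str,
    mode: str = "healthy",
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> HmmModel:
    """Standardized-parameters training from a healthy-subject pool.

    mode="healthy": pool the first two trials of every healthy subject
    except the target and train on the pooled set (the target must be a
    pool member, and is excluded).

    mode="patient": time-normalize each healthy stride per phase, average
    the angular velocity across strides at each normalized index,
    re-derive the derivative feature from the averaged velocity, and train
    on the resulting ensemble-average stride dataset (labels follow the
    normalized segment layout).
    """
    if mode not in ("healthy", "patient"):
        raise ValueError("mode must be 'healthy' or 'patient'")
    if mode == "healthy":
        if target_subject not in healthy_trials:
            raise ValueError("healthy-mode target must be one of the healthy subjects "
                             "(and is excluded from the pool)")
        pool = [(o, l) for subj, trials in healthy_trials.items()
                if subj != target_subject for (o, l) in trials[:2]]
    else:
        pool = [(o, l) for trials in healthy_trials.values() for (o, l) in trials[:2]]
    if len(pool) < 2:
        raise ValueError("need at least two healthy training trials")

    if mode == "healthy":
        model = init_model([p[0] for p in pool], [p[1] for p in pool], seed=seed)
        model, _ = baum_welch(model, [p[0] for p in pool], tol=tol, max_iter=max_iter)
        return model

    # patient mode: stride-ensemble average of angular velocities
    per_phase_rows = {p: [] for p in GaitPhase}
    durations = []
    fs = pool[0][0].fs
    for obs, lab in pool:
        omega = obs.features[:, 0]
        for stride in _phase_segments(lab):
            durations.append(sum(b - a for a, b in stride.values()) / lab.fs)
            for phase in GaitPhase:
                a, b = stride[int(phase)]
                rows = time_normalize_segments(omega, [(a, b)], SPT_POINTS[phase])
                per_phase_rows[phase].append(rows[0])
    if not durations:
        raise ValueError("no complete strides in the healthy pool")
    mean_T = float(np.mean(durations))
    omega_avg = np.concatenate(
        [np.mean(np.vstack(per_phase_rows[p]), axis=0) for p in GaitPhase])
    labels_avg = np.concatenate(
        [np.full(SPT_POINTS[p], int(p), dtype=np.int8) for p in GaitPhase])
    fs_norm = omega_avg.size / mean_T  # effective rate of the normalized stride
    # several repeats so transition statistics exist
    reps = 3
    omega_rep = np.tile(omega_avg, reps)
    labels_rep = np.tile(labels_avg, reps)
    obs_avg = features_from_gyro(omega_rep, fs_norm)
    lab_avg = LabelSequence(labels_rep, fs_norm)
    model = init_model([obs_avg], [lab_avg], seed=seed)
    model, _ = baum_welch(model, [obs_avg], tol=tol, max_iter=max_iter)
    return model
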