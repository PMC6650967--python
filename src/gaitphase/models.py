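"""Model/Results front end for the two gait-phase detectors.

:class:`GaitPhaseHMM` wraps the left-right GMM-HMM in the familiar
model-object idiom: construct from labeled training data, ``fit()`` to
run Baum-Welch, and use the returned :class:`GaitPhaseHMMResults` to
decode new trials, inspect the estimated parameters and print a summary
table.  :class:`ThresholdDetector` gives the rule-based finite-state
machine the same construct/fit/predict surface, where "fitting" is the
step-count threshold calibration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hmm as _hmm
from .evaluation import ClassifierScore, sample_metrics, timing_errors
from .phases import GaitPhase, LabelSequence, PHASE_NAMES
from .streams import ImuStream
from .threshold import TbConfig, calibrate_thresholds, tb_detect


def observation_pair(imu, fsr, median_window: int = 5):
    """(ObservationSequence, LabelSequence) for one trial, length-aligned.

    Conditions the IMU (median + low-pass + 200 Hz resample), extracts the
    (omega, alpha) features, labels the FSR stream, and trims both to the
    shared length.
    """
    from .fsr import binarize_fsr, label_from_fsr
    from .preprocessing import preprocess_imu

    pp = preprocess_imu(imu, median_window=median_window, fs_out=200.0)
    obs = _hmm.features_from_gyro(pp.gy, pp.fs)
    ref = label_from_fsr(binarize_fsr(fsr))
    n = min(len(obs), len(ref))
    return (_hmm.ObservationSequence(obs.features[:n], obs.fs),
            LabelSequence(ref.labels[:n], ref.fs, t0=ref.t0))


class GaitPhaseHMM:
    """Left-right continuous HMM for gait-phase decoding.

    Parameters
    ----------
    observations : list of ObservationSequence
        Training emission sequences (omega, alpha) per trial.
    labels : list of LabelSequence
        FSR reference labels aligned with the observations, used for the
        supervised initialization of the per-state mixtures.
    """

    def __init__(self, observations, labels):
        if len(observations) != len(labels):
            raise ValueError("observations and labels must pair per trial")
        self.observations = list(observations)
        self.labels = list(labels)

    @classmethod
    def from_imu(cls, imu_streams, label_sequences, preprocess: bool = True):
        """Build from raw IMU streams (median + low-pass + 200 Hz resample)."""
        from .preprocessing import preprocess_imu

        obs = []
        for imu in imu_streams:
            if preprocess:
                imu = preprocess_imu(imu, fs_out=200.0)
            obs.append(_hmm.features_from_gyro(imu.gy, imu.fs))
        return cls(obs, list(label_sequences))

    def fit(self, seed: int = 0, tol: float = 1e-4, max_iter: int = 100,
            update_transitions: bool = True) -> "GaitPhaseHMMResults":
        """Initialize from the labeled data and run Baum-Welch to convergence."""
        model = _hmm.init_model(self.observations, self.labels, seed=seed)
        model, trace = _hmm.baum_welch(model, self.observations, tol=tol,
                                       max_iter=max_iter,
                                       update_transitions=update_transitions)
        return GaitPhaseHMMResults(model=self, params=model, loglik_trace=trace)


@dataclass
class GaitPhaseHMMResults:
    """Fitted HMM: estimated lambda, convergence trace, decode/summary."""

    model: GaitPhaseHMM
    params: _hmm.HmmModel
    loglik_trace: list

    @property
    def converged(self) -> bool:
        tr = self.loglik_trace
        if len(tr) < 2:
            return True
        return (tr[-1] - tr[-2]) / max(abs(tr[-2]), 1.0) < 1e-3

    def predict(self, obs: _hmm.ObservationSequence) -> LabelSequence:
        """Viterbi decoding of a new observation sequence."""
        return _hmm.viterbi(self.params, obs)

    def loglik(self, obs: _hmm.ObservationSequence) -> float:
        return _hmm.forward_loglik(self.params, obs)

    def score(self, obs: _hmm.ObservationSequence, ref: LabelSequence) -> ClassifierScore:
        """Decode and evaluate against a reference label sequence."""
        return sample_metrics(self.predict(obs), ref)

    def summary(self) -> str:
        p = self.params
        lines = ["Left-right gait-phase HMM (4 states, 3-component bivariate GMM)",
                 f"EM iterations: {len(self.loglik_trace)}  "
                 f"final log-likelihood: {self.loglik_trace[-1]:.2f}",
                 "",
                 "Transition matrix A (rows HS, FF, HO, SP):"]
        for i, name in enumerate(PHASE_NAMES):
            row = "  ".join(f"{v:6.4f}" for v in p.A[i])
            lines.append(f"  {name}  [{row}]")
        lines.append(f"pi: [{'  '.join(f'{v:6.4f}' for v in p.pi)}]")
        lines.append("")
        lines.append("State emission means (omega deg/s, alpha deg/s^2) and weights:")
        for i, name in enumerate(PHASE_NAMES):
            for k in range(p.means.shape[1]):
                lines.append(f"  {name} comp{k}: w={p.weights[i, k]:.3f}  "
                             f"mean=({p.means[i, k, 0]:8.1f}, {p.means[i, k, 1]:10.1f})")
        return "\n".join(lines)

    def plot_decoding(self, obs, ref=None, ax=None):
        """Plot omega with the decoded phase bands (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        pred = self.predict(obs)
        t = np.arange(len(obs)) / obs.fs
        ax.plot(t, obs.features[:, 0], color="k", lw=0.8, label="omega")
        colors = ["#d62728", "#2ca02c", "#1f77b4", "#9467bd"]
        for phase, a, b in pred.runs():
            ax.axvspan(t[a], t[b - 1], color=colors[int(phase)], alpha=0.15)
        if ref is not None:
            changes = np.flatnonzero(np.diff(ref.labels)) + 1
            for c in changes:
                ax.axvline(ref.t[c] - ref.t0, color="gray", lw=0.5, ls=":")
        ax.set_xlabel("time [s]")
        ax.set_ylabel("angular velocity [deg/s]")
        return ax


class ThresholdDetector:
    """Finite-state threshold detector with calibrate/detect surface."""

    def __init__(self, config: TbConfig):
        self.config = config

    @classmethod
    def calibrated(cls, imu: ImuStream, expected_steps: int,
                   grid: dict, base: TbConfig) -> "ThresholdDetector":
        """Grid-search calibration by expected step count."""
        return cls(calibrate_thresholds(imu, expected_steps, grid, base))

    def detect(self, imu: ImuStream) -> LabelSequence:
        return tb_detect(imu, self.config)

    def score(self, imu: ImuStream, ref: LabelSequence) -> ClassifierScore:
        return sample_metrics(self.detect(imu), ref)
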