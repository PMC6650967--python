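"""Seeded generator of coupled IMU + FSR gait trials with ground truth.

The generator composes each stride from piecewise-linear waveform
templates anchored to the four phase segments (HS, FF, HO, SP), so the
morphology the detectors consume — the swing crest and toe-off/foot-slap
troughs of the sagittal angular velocity, the heel-strike impact
transient, flat-foot dip and push-off rise of the vertical acceleration —
is controlled exactly.  This is deliberately *not* a biomechanical
simulation: joint kinematics, ground-reaction magnitudes and soft-tissue
artefacts are out of scope; the templates only reproduce the crest /
trough / neutral-band structure of foot-instep inertial data during
treadmill walking.

Anchor times are expressed per phase in local coordinates, so per-stride
duration and phase-fraction jitter warp the waveform consistently with
the ground-truth boundaries.  The FSR channels follow the canonical
activation sequence (heel only at HS; metatarsals loaded at FF; toe and
metatarsals with the heel off at HO; all off during swing), with an
optional double-support overlap that prolongs each channel's activation
to exercise the reference labeler's hold-forward rule.

Cadence defaults derive from treadmill speed via a fixed nominal stride
length (0.7 m healthy, shrinking to 0.5 m at full hemiparetic severity).
The healthy default speed is 0.639 m/s, the low end of the healthy
treadmill range, where the four-phase waveform features are well
separated in time relative to the detector's 150 ms refractory; the
hemiparetic preset slows to 0.278 m/s at full severity.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .phases import GaitPhase, LabelSequence
from .streams import FsrStream, ImuStream
from .threshold import TbConfig, TbSignalConfig

HEALTHY_SPEED_MS = 0.639       # m/s, low end of the healthy treadmill range
PATHOLOGICAL_SPEED_MIN = 0.278  # m/s, slow end of the hemiparetic range
HEALTHY_STRIDE_LENGTH_M = 0.7
PATHOLOGICAL_STRIDE_LENGTH_M = 0.5

# reference stride used to express template anchors (ms); anchors are
# converted to phase-local fractions against these default boundaries
_T_REF = 1096.0
_FRACTIONS_REF = (0.10, 0.35, 0.25, 0.30)


def _gyro_anchors(swing_amp: float, footslap_amp: float) -> list[tuple[float, float]]:
    """Sagittal angular-velocity template (ms, deg/s) over one stride.

    Swing crest (positive, dominant), foot-slap trough just after the HS
    segment, neutral plateau during flat foot, moderate heel-off bump,
    toe-off trough, swing rise.
    """
    s = swing_amp / 400.0
    return [
        (0.0, 390.0 * s), (64.0, 250.0), (105.0, 150.0),
        (140.0, -150.0), (180.0, footslap_amp), (215.0, -150.0),
        (250.0, -50.0), (270.0, 0.0), (430.0, 0.0), (440.0, 50.0),
        (465.0, 150.0), (482.0, 250.0), (540.0, 310.0), (600.0, 250.0),
        (690.0, 150.0), (745.0, 0.0), (790.0, -150.0), (830.0, -220.0),
        (870.0, -150.0), (940.0, 0.0), (1015.0, 250.0), (1090.0, 400.0 * s),
    ]


def _accel_anchors(impact_amp: float) -> list[tuple[float, float]]:
    """Vertical-acceleration template (ms, m/s^2) over one stride.

    Heel-strike impact transient with a short oscillatory after-bump,
    flat-foot dip, stance neutral band, push-off rise, early-swing crest
    and mid-swing dip.
    """
    i = impact_amp / 10.0
    return [
        (0.0, 10.0 * i), (8.0, 10.0 * i), (50.0, 6.8 * i), (62.0, 3.2),
        (95.0, 2.2), (140.0, 2.2), (170.0, 3.0), (200.0, 5.0),
        (225.0, 3.0), (238.0, -3.0), (260.0, -4.8), (290.0, -3.0),
        (310.0, -1.5), (330.0, 0.0), (660.0, 0.0), (685.0, 1.5),
        (693.0, 3.0), (700.0, 6.0), (720.0, 7.5), (745.0, 6.2),
        (800.0, 3.0), (900.0, 1.5), (925.0, 0.0), (940.0, -3.0),
        (965.0, -4.8), (985.0, -3.0), (1005.0, -1.5), (1040.0, 0.0),
        (1065.0, 1.5), (1072.0, 3.0), (1082.0, 6.0 * i), (1090.0, 9.5 * i),
    ]


# FSR activation pattern per phase: (heel, mt1, mt5, toe)
_FSR_PATTERNS = {
    GaitPhase.HS: (1, 0, 0, 0),
    GaitPhase.FF: (1, 1, 1, 0),
    GaitPhase.HO: (0, 1, 1, 1),
    GaitPhase.SP: (0, 0, 0, 0),
}


@dataclass
class GaitSimParams:
    """Study conditions for one simulated walking trial.

    Attributes
    ----------
    n_strides : int
        Number of complete strides (HS onsets) in the trial.
    cadence : float
        Strides per second; default from 0.639 m/s at a 0.7 m stride.
    phase_fractions : tuple of 4 floats
        Mean fraction of the stride spent in HS, FF, HO, SP; HS shortest
        and FF longest, matching the event distribution of normal gait.
    stride_cv : float
        Stride-duration coefficient of variation, percent (lognormal
        jitter); per-phase fractions additionally jitter at half this
        relative spread.
    noise_sd_gyro, noise_sd_accel : float
        Additive white-noise standard deviations (deg/s, m/s^2).
    gyro_swing_amp : float
        Peak swing-phase angular velocity, deg/s.
    gyro_footslap_amp : float
        Foot-slap (plantarflexion) trough depth just after HS, deg/s.
    accel_impact_amp : float
        Heel-strike impact transient peak, m/s^2.
    transition_overlap_ms : float
        Forward prolongation of each FSR channel's activation, creating
        double-support patterns that match no single-phase template.
    imu_fs, fsr_fs : float
        Sampling rates, Hz.
    seed : int
        Seed for all randomness in the trial.
    """

    n_strides: int = 10
    cadence: float = HEALTHY_SPEED_MS / HEALTHY_STRIDE_LENGTH_M  # ~0.913 /s
    phase_fractions: tuple = _FRACTIONS_REF
    stride_cv: float = 3.0
    noise_sd_gyro: float = 8.0
    noise_sd_accel: float = 0.3
    gyro_swing_amp: float = 400.0
    gyro_footslap_amp: float = -220.0
    accel_impact_amp: float = 10.0
    transition_overlap_ms: float = 0.0
    imu_fs: float = 100.0
    fsr_fs: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be positive")
        if self.cadence <= 0 or self.imu_fs <= 0 or self.fsr_fs <= 0:
            raise ValueError("rates must be positive")
        fr = np.asarray(self.phase_fractions, dtype=float)
        if fr.size != 4 or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("phase_fractions must be 4 positive values summing to 1")
        if self.stride_cv < 0 or self.stride_cv >= 50:
            raise ValueError("stride_cv out of range (negative durations possible)")
        if self.noise_sd_gyro < 0 or self.noise_sd_accel < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.gyro_swing_amp <= 0 or self.accel_impact_amp <= 0:
            raise ValueError("amplitudes must be positive")


@dataclass
class SimTrial:
    """A simulated trial: IMU stream, FSR stream, ground truth."""

    imu: ImuStream
    fsr: FsrStream
    truth: LabelSequence
    stride_onsets: np.ndarray  # seconds, HS onsets


def healthy_preset(**overrides) -> GaitSimParams:
    """Default healthy-gait study conditions."""
    return replace(GaitSimParams(), **overrides) if overrides else GaitSimParams()


def pathological_preset(severity: float, **overrides) -> GaitSimParams:
    """Hemiparetic-gait conditions interpolated by severity in [0, 1].

    Severity 0 equals the healthy defaults; severity 1 walks at the slow
    end of the hemiparetic speed range (0.278 m/s, 0.5 m strides) with
    raised stride variability and attenuated heel-strike impact and
    foot-slap trough.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    speed = HEALTHY_SPEED_MS - severity * (HEALTHY_SPEED_MS - PATHOLOGICAL_SPEED_MIN)
    stride_len = (HEALTHY_STRIDE_LENGTH_M
                  - severity * (HEALTHY_STRIDE_LENGTH_M - PATHOLOGICAL_STRIDE_LENGTH_M))
    atten = 1.0 - 0.45 * severity
    params = GaitSimParams(
        cadence=speed / stride_len,
        stride_cv=3.0 + 7.0 * severity,
        accel_impact_amp=10.0 * atten,
        gyro_footslap_amp=-220.0 * atten,
    )
    return replace(params, **overrides) if overrides else params


def generator_matched_tb_config(params: GaitSimParams | None = None) -> TbConfig:
    """Detector thresholds matched to the generator's waveform amplitudes.

    The crest thresholds sit at roughly 60 % of the corresponding template
    peaks; high thresholds above the crest thresholds (sequential feature
    evaluation saves crest-middle only between the two); neutral bands
    bracket the stance plateaus.
    """
    params = params or GaitSimParams()
    g = params.gyro_swing_amp / 400.0
    a = params.accel_impact_amp / 10.0
    gyro = TbSignalConfig(d_high=250.0 * g, d_low=-400.0, d_crest=150.0 * g,
                          d_trough=-120.0, d_neutral_min=-50.0, d_neutral_max=50.0,
                          t_crest=0.030, t_trough=0.030, t_neutral=0.100)
    accel = TbSignalConfig(d_high=6.0 * a, d_low=-8.0, d_crest=3.0 * min(a, 1.0),
                           d_trough=-3.0, d_neutral_min=-1.5, d_neutral_max=1.5,
                           t_crest=0.030, t_trough=0.030, t_neutral=0.100)
    return TbConfig(accel=accel, gyro=gyro, initial_phase=GaitPhase.SP)


def _local_anchors(anchors: list[tuple[float, float]]) -> list[tuple[int, float, float]]:
    """Convert reference-ms anchors to (phase index, local fraction, value)."""
    bounds = np.concatenate(([0.0], np.cumsum(_FRACTIONS_REF))) * _T_REF
    out = []
    for t_ms, value in anchors:
        k = int(np.searchsorted(bounds, t_ms, side="right") - 1)
        k = min(k, 3)
        local = (t_ms - bounds[k]) / (bounds[k + 1] - bounds[k])
        out.append((k, local, value))
    return out


def simulate_trial(params: GaitSimParams) -> SimTrial:
    """Generate one coupled IMU + FSR trial with ground-truth labels.

    The trial opens with the swing portion of a lead-in stride (so the
    detectors observe a full pre-HS feature sequence before the first
    labeled heel strike), followed by ``n_strides`` complete strides.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_strides
    mean_T = 1.0 / params.cadence
    cv = params.stride_cv / 100.0

    # stride durations: lognormal with unit mean
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv * cv))
        jitter = rng.lognormal(-0.5 * sigma * sigma, sigma, size=n + 1)
    else:
        jitter = np.ones(n + 1)
    stride_T = mean_T * jitter

    # per-stride phase durations with half-spread relative jitter
    fr = np.asarray(params.phase_fractions, dtype=float)
    mult = np.ones((n + 1, 4))
    if cv > 0:
        mult = np.abs(rng.normal(1.0, cv / 2.0, size=(n + 1, 4)))
    phase_dur = fr[None, :] * mult
    phase_dur /= phase_dur.sum(axis=1, keepdims=True)
    phase_dur *= stride_T[:, None]

    # absolute phase boundaries; stride 0 is the lead-in
    edges = np.concatenate(([0.0], np.cumsum(phase_dur.ravel())))  # 4*(n+1)+1
    t_start = edges[3]        # SP onset of the lead-in stride
    t_end = edges[4 * (n + 1)]

    # waveform anchors warped to this trial's boundaries
    def build_wave(anchors_ms):
        loc = _local_anchors(anchors_ms)
        at, av = [], []
        for k in range(n + 1):
            for ph, local, value in loc:
                start = edges[4 * k + ph]
                dur = edges[4 * k + ph + 1] - edges[4 * k + ph]
                at.append(start + local * dur)
                av.append(value)
        return np.asarray(at), np.asarray(av)

    gyro_at, gyro_av = build_wave(
        _gyro_anchors(params.gyro_swing_amp, params.gyro_footslap_amp))
    accel_at, accel_av = build_wave(_accel_anchors(params.accel_impact_amp))

    # IMU sampling
    n_imu = int(np.floor((t_end - t_start) * params.imu_fs))
    t_imu = t_start + np.arange(n_imu) / params.imu_fs
    gy = np.interp(t_imu, gyro_at, gyro_av)
    ay = np.interp(t_imu, accel_at, accel_av)
    if params.noise_sd_gyro > 0:
        gy = gy + rng.normal(0.0, params.noise_sd_gyro, size=n_imu)
    if params.noise_sd_accel > 0:
        ay = ay + rng.normal(0.0, params.noise_sd_accel, size=n_imu)
    imu = ImuStream.from_samples(ay, gy, params.imu_fs, t0=0.0)

    # FSR + truth sampling
    n_fsr = int(np.floor((t_end - t_start) * params.fsr_fs))
    t_fsr = t_start + np.arange(n_fsr) / params.fsr_fs
    seg = np.clip(np.searchsorted(edges, t_fsr, side="right") - 1, 0, 4 * (n + 1) - 1)
    phase_codes = (seg % 4).astype(np.int8)
    truth = LabelSequence(phase_codes, params.fsr_fs, t0=0.0)

    pattern = np.array([_FSR_PATTERNS[GaitPhase(i)] for i in range(4)], dtype=float)
    channels = pattern[phase_codes]  # (n_fsr, 4)
    if params.transition_overlap_ms > 0:
        k = int(round(params.transition_overlap_ms / 1000.0 * params.fsr_fs))
        if k > 0:
            ext = channels.copy()
            for s in range(1, k + 1):
                ext[s:] = np.maximum(ext[s:], channels[:-s])
            channels = ext
    fsr = FsrStream.from_channels(channels, params.fsr_fs, t0=0.0)

    stride_onsets = edges[4::4][:n] - t_start  # HS onsets of strides 1..n
    return SimTrial(imu=imu, fsr=fsr, truth=truth, stride_onsets=stride_onsets)


def simulate_subject(params: GaitSimParams, n_trials: int = 3) -> list[SimTrial]:
    """Repeated trials for one subject; trial k reseeds with seed + k."""
    return [simulate_trial(replace(params, seed=params.seed + k))
            for k in range(n_trials)]
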