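"""Threshold-based finite-state gait-phase detector.

Two independent feature extractors run over the conditioned vertical
acceleration (Ay) and sagittal angular velocity (Gy).  Each extractor
scans its signal sample-by-sample for seven waveform features, evaluated
sequentially (first match wins, one saved feature per sample):

1. ``crossed_high``  — signal above ``d_high``, >= 150 ms since the last
   saved feature (the refractory).
2. ``crossed_low``   — signal below ``d_low``, refractory elapsed.
3. ``crest_middle``  — signal above ``d_crest``, refractory elapsed.
4. ``crest``         — only after ``crest_middle``: the signal has fallen
   back below ``d_crest`` and ``t_crest`` has elapsed since the last
   saved feature.
5. ``trough_middle`` — signal below ``d_trough``, refractory elapsed.
6. ``trough``        — symmetric completion of a trough after ``t_trough``.
7. ``neutral``       — continuous residence in
   [``d_neutral_min``, ``d_neutral_max``] for at least ``t_neutral``.

Because evaluation is sequential, a ``crest_middle`` can only be saved
while the signal sits in (``d_crest``, ``d_high``]; sensible configs
therefore put ``d_crest`` below ``d_high`` (and ``d_trough`` above
``d_low``).

Saved features accumulate into per-signal lists which a four-state machine
inspects after every sample; when a phase transition rule is satisfied the
machine advances to the next phase and both lists are emptied.  Pending
extractor state (an unfinished crest/trough, a running neutral residence)
survives the transition, so a feature that straddles a phase boundary is
credited to the new phase's list.

Transition rules (all subsequences are in-order, gaps allowed):

- SP->HS: accel list contains crest, trough, crossed_high and the current
  accel sample is above ``d_crest`` (in crest-middle); gyro list contains
  trough then crossed_high.
- HS->FF: accel list contains the HS crest and the current accel sample is
  below ``d_trough`` (in trough-middle); gyro list contains a crest.
- FF->HO: the accel signal has resided in its neutral band for at least
  ``t_neutral``; gyro list contains neutral then crossed_high.
- HO->SP: the current accel sample is above ``d_high``; gyro list contains
  a crest.

Thresholds are calibrated per trial by an exhaustive grid search that
keeps configurations detecting the expected number of steps.
"""
from __future__ import annotations

import enum
import itertools
import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .phases import GaitPhase, LabelSequence
from .streams import ImuStream

REFRACTORY_S = 0.150


class FeatureKind(enum.Enum):
    CROSSED_HIGH = "crossed_high"
    CROSSED_LOW = "crossed_low"
    CREST_MIDDLE = "crest_middle"
    CREST = "crest"
    TROUGH_MIDDLE = "trough_middle"
    TROUGH = "trough"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class FeatureEvent:
    """A saved waveform feature with its time and inter-feature interval."""

    kind: FeatureKind
    t: float
    dt: float  # seconds since the previous saved feature on this signal


@dataclass
class TbSignalConfig:
    """Per-signal thresholds and time constants (signal units / seconds)."""

    d_high: float
    d_low: float
    d_crest: float
    d_trough: float
    d_neutral_min: float
    d_neutral_max: float
    t_crest: float = 0.030
    t_trough: float = 0.030
    t_neutral: float = 0.100
    refractory: float = REFRACTORY_S

    def __post_init__(self) -> None:
        if self.d_neutral_min >= self.d_neutral_max:
            raise ValueError("d_neutral_min must be below d_neutral_max")
        for name in ("t_crest", "t_trough", "t_neutral", "refractory"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TbConfig:
    """Full detector configuration: one sub-config per signal."""

    accel: TbSignalConfig
    gyro: TbSignalConfig
    initial_phase: GaitPhase = GaitPhase.SP

    def to_json(self) -> str:
        d = {"accel": asdict(self.accel), "gyro": asdict(self.gyro),
             "initial_phase": self.initial_phase.name}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TbConfig":
        d = json.loads(text)
        return cls(accel=TbSignalConfig(**d["accel"]),
                   gyro=TbSignalConfig(**d["gyro"]),
                   initial_phase=GaitPhase[d.get("initial_phase", "SP")])


class FeatureExtractor:
    """Stateful per-signal scanner emitting :class:`FeatureEvent`.

    The extractor's pending state (unfinished crest/trough, neutral
    residence) is private to the signal and is never reset by the FSM.
    """

    def __init__(self, cfg: TbSignalConfig):
        self.cfg = cfg
        self.t_last_saved = -math.inf
        self.t_prev = -math.inf
        self.pending_crest = False
        self.pending_trough = False
        self.neutral_since = None  # residence start time, or None

    def step(self, d_i: float, t: float) -> FeatureEvent | None:
        """Advance one sample; return the saved feature, if any."""
        if t <= self.t_prev:
            raise ValueError("timestamps must be strictly increasing")
        self.t_prev = t
        cfg = self.cfg
        # half-sample tolerance absorbs float round-off on the time grid
        eps = 1e-9
        elapsed = t - self.t_last_saved + eps

        # neutral residence bookkeeping (independent of saving)
        if cfg.d_neutral_min <= d_i <= cfg.d_neutral_max:
            if self.neutral_since is None:
                self.neutral_since = t
        else:
            self.neutral_since = None

        kind = None
        if d_i > cfg.d_high and elapsed >= cfg.refractory:
            kind = FeatureKind.CROSSED_HIGH
        elif d_i < cfg.d_low and elapsed >= cfg.refractory:
            kind = FeatureKind.CROSSED_LOW
        elif d_i > cfg.d_crest and elapsed >= cfg.refractory:
            kind = FeatureKind.CREST_MIDDLE
            self.pending_crest = True
        elif self.pending_crest and d_i < cfg.d_crest and elapsed >= cfg.t_crest:
            kind = FeatureKind.CREST
            self.pending_crest = False
        elif d_i < cfg.d_trough and elapsed >= cfg.refractory:
            kind = FeatureKind.TROUGH_MIDDLE
            self.pending_trough = True
        elif self.pending_trough and d_i > cfg.d_trough and elapsed >= cfg.t_trough:
            kind = FeatureKind.TROUGH
            self.pending_trough = False
        elif (self.neutral_since is not None
              and t - self.neutral_since + eps >= cfg.t_neutral
              and elapsed >= cfg.t_neutral):
            kind = FeatureKind.NEUTRAL

        if kind is None:
            return None
        dt = 0.0 if math.isinf(self.t_last_saved) else t - self.t_last_saved
        self.t_last_saved = t
        return FeatureEvent(kind, t, dt)

    def neutral_residence(self, t: float) -> float:
        """Current continuous residence time in the neutral band."""
        return 0.0 if self.neutral_since is None else t - self.neutral_since


def _contains_subsequence(events: list[FeatureEvent], kinds: tuple[FeatureKind, ...]) -> bool:
    it = iter(ev.kind for ev in events)
    return all(k in it for k in kinds)


def fsm_step(
    phase: GaitPhase,
    accel_features: list[FeatureEvent],
    gyro_features: list[FeatureEvent],
    accel_sample: float,
    accel_neutral_residence: float,
    cfg: TbConfig,
) -> tuple[GaitPhase, bool]:
    """Evaluate the transition rule for the current phase.

    Returns the (possibly advanced) phase and a flag; absent features
    simply mean no transition.  The caller empties the lists on a
    transition.
    """
    a, g = cfg.accel, cfg.gyro
    fire = False
    if phase is GaitPhase.SP:
        fire = (accel_sample > a.d_crest
                and _contains_subsequence(accel_features,
                                          (FeatureKind.CREST, FeatureKind.TROUGH,
                                           FeatureKind.CROSSED_HIGH))
                and _contains_subsequence(gyro_features,
                                          (FeatureKind.TROUGH, FeatureKind.CROSSED_HIGH)))
    elif phase is GaitPhase.HS:
        fire = (accel_sample < a.d_trough
                and _contains_subsequence(accel_features, (FeatureKind.CREST,))
                and _contains_subsequence(gyro_features, (FeatureKind.CREST,)))
    elif phase is GaitPhase.FF:
        fire = (accel_neutral_residence >= a.t_neutral
                and _contains_subsequence(gyro_features,
                                          (FeatureKind.NEUTRAL, FeatureKind.CROSSED_HIGH)))
    elif phase is GaitPhase.HO:
        fire = (accel_sample > a.d_high
                and _contains_subsequence(gyro_features, (FeatureKind.CREST,)))
    return (phase.successor, True) if fire else (phase, False)


def tb_detect(imu: ImuStream, cfg: TbConfig) -> LabelSequence:
    """Run the finite-state detector over a conditioned IMU stream.

    Emits one label per sample, starting from ``cfg.initial_phase``.
    Deterministic: identical input and config give identical labels.
    """
    if len(imu) == 0:
        raise ValueError("empty IMU stream")
    accel_x = FeatureExtractor(cfg.accel)
    gyro_x = FeatureExtractor(cfg.gyro)
    accel_list: list[FeatureEvent] = []
    gyro_list: list[FeatureEvent] = []
    phase = cfg.initial_phase
    out = np.empty(len(imu), dtype=np.int8)
    for i, t in enumerate(imu.t):
        ev_a = accel_x.step(imu.ay[i], float(t))
        if ev_a is not None:
            accel_list.append(ev_a)
        ev_g = gyro_x.step(imu.gy[i], float(t))
        if ev_g is not None:
            gyro_list.append(ev_g)
        phase, fired = fsm_step(phase, accel_list, gyro_list, imu.ay[i],
                                accel_x.neutral_residence(float(t)), cfg)
        if fired:
            accel_list.clear()
            gyro_list.clear()
        out[i] = int(phase)
    return LabelSequence(out, imu.fs, t0=float(imu.t[0]))


def count_detected_strides(labels: LabelSequence) -> int:
    """Number of HS onsets (stride starts) in a label sequence."""
    lab = labels.labels
    change = np.flatnonzero(np.diff(lab)) + 1
    return int(np.sum(lab[change] == int(GaitPhase.HS)))


class CalibrationError(RuntimeError):
    def __init__(self, expected: int, best: int):
        super().__init__(
            f"no threshold candidate detected the expected {expected} steps "
            f"(best achieved: {best})")
        self.expected = expected
        self.best = best


def _threshold_margin(imu: ImuStream, cfg: TbConfig) -> float:
    """Worst-case margin between signal extrema and the chosen thresholds.

    For upper thresholds the margin is how far the signal maximum clears
    them; for lower thresholds, how far the minimum undershoots.  The
    configuration with the largest worst case is the most noise-robust.
    """
    margins = []
    for x, sc in ((imu.ay, cfg.accel), (imu.gy, cfg.gyro)):
        hi, lo = float(np.max(x)), float(np.min(x))
        margins += [hi - sc.d_high, hi - sc.d_crest, sc.d_trough - lo]
        if lo < sc.d_low:
            margins.append(sc.d_low - lo)
    return min(margins)


def calibrate_thresholds(
    imu: ImuStream,
    expected_steps: int,
    grid: dict[str, list[float]],
    base: TbConfig,
) -> TbConfig:
    """Grid-search threshold calibration by expected step count.

    ``grid`` maps dotted parameter names (``"accel.d_high"``,
    ``"gyro.d_crest"``, ...) to candidate values; the exhaustive product is
    evaluated and the configuration whose detected HS-onset count equals
    ``expected_steps`` is returned.  Ties are broken by maximizing the
    worst-case margin between signal extrema and thresholds.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must provide at least one candidate per parameter")
    names = list(grid)
    best_cfg = None
    best_margin = -math.inf
    best_count = -1
    for combo in itertools.product(*(grid[n] for n in names)):
        accel = replace(base.accel)
        gyro = replace(base.gyro)
        for name, value in zip(names, combo):
            side, attr = name.split(".")
            target = {"accel": accel, "gyro": gyro}[side]
            setattr(target, attr, value)
        cfg = TbConfig(accel=accel, gyro=gyro, initial_phase=base.initial_phase)
        count = count_detected_strides(tb_detect(imu, cfg))
        if abs(count - expected_steps) < abs(best_count - expected_steps):
            best_count = count
        if count == expected_steps:
            margin = _threshold_margin(imu, cfg)
            if margin > best_margin:
                best_margin = margin
                best_cfg = cfg
    if best_cfg is None:
        raise CalibrationError(expected_steps, best_count)
    return best_cfg
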