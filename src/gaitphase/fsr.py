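"""Reference gait-phase labeling from four-channel FSR insole streams.

Each gait phase maps to a binary activation pattern of the heel, first and
fifth metatarsal, and hallux (toe) sensors:

=====  ==========================================================
Phase  Pattern
=====  ==========================================================
HS     heel active, all other channels off
FF     1st and 5th metatarsal active (heel/toe ignored by default)
HO     toe active, heel off (1st metatarsal optionally required)
SP     all channels off
=====  ==========================================================

Heel/toe participation in FF and mt1 participation in HO are per-subject
relaxations: in hemiparetic gait these channels fire inconsistently during
loading response, so by default they are "don't care" for those phases.
Samples matching no pattern (e.g. double-support overlaps) hold the
previous label, which keeps the output within the four-phase vocabulary
and lets run cleanup preserve the cyclic order.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .phases import GaitPhase, LabelSequence
from .streams import FsrStream

logger = logging.getLogger(__name__)


@dataclass
class PatternConfig:
    """Activation-pattern options for the FSR reference labeler.

    Attributes
    ----------
    ff_requires_heel, ff_requires_toe : bool
        Whether FF additionally requires heel / toe activation.
    ho_requires_mt1 : bool
        Whether HO additionally requires 1st-metatarsal activation.
    thresholds : dict or None
        Per-channel binarization thresholds (analog units).  ``None``
        defaults each channel to 50 % of its trial maximum.
    debounce_ms : float
        Activation/deactivation runs shorter than this are suppressed.
    """

    ff_requires_heel: bool = False
    ff_requires_toe: bool = False
    ho_requires_mt1: bool = False
    thresholds: dict | None = None
    debounce_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.debounce_ms < 0:
            raise ValueError("debounce_ms must be >= 0")
        if self.thresholds is not None:
            for k, v in self.thresholds.items():
                if v < 0:
                    raise ValueError(f"threshold for {k!r} must be >= 0")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PatternConfig":
        return cls(**json.loads(text))


def _debounce(binary: np.ndarray, min_run: int) -> np.ndarray:
    """Suppress 0/1 runs shorter than ``min_run`` samples (brute run merge)."""
    if min_run <= 1:
        return binary
    out = binary.copy()
    n = out.size
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if j - i < min_run and i > 0:
            out[i:j] = out[i - 1]
            # re-scan from the run before the merge point
            i = j
        else:
            i = j
    return out


def binarize_fsr(stream: FsrStream, cfg: PatternConfig | None = None) -> FsrStream:
    """Threshold analog FSR channels to binary activations.

    A channel is active where its readout is >= its threshold (default 50 %
    of the channel's trial maximum); runs shorter than the debounce time are
    suppressed.  Already-binary input passes through unchanged (up to
    debouncing).
    """
    cfg = cfg or PatternConfig()
    min_run = int(round(cfg.debounce_ms / 1000.0 * stream.fs))
    channels = {}
    for name in FsrStream.CHANNELS:
        x = getattr(stream, name)
        if cfg.thresholds and name in cfg.thresholds:
            thr = cfg.thresholds[name]
        else:
            peak = float(np.max(x)) if x.size else 0.0
            thr = 0.5 * peak if peak > 0 else np.inf
        binary = (x >= thr).astype(float)
        channels[name] = _debounce(binary, min_run)
    return FsrStream(stream.t.copy(), channels["heel"], channels["mt1"],
                     channels["mt5"], channels["toe"], stream.fs)


def label_from_fsr(binary: FsrStream, cfg: PatternConfig | None = None) -> LabelSequence:
    """Label each sample by matching the binary activation patterns.

    Patterns are checked in the order SP, HS, HO, FF (most to least
    specific, so that metatarsal loading during heel-off is not mistaken
    for flat foot).  Non-matching samples carry the previous label forward;
    a non-matching prefix is back-filled with the first matched phase.
    """
    cfg = cfg or PatternConfig()
    heel = binary.heel > 0.5
    mt1 = binary.mt1 > 0.5
    mt5 = binary.mt5 > 0.5
    toe = binary.toe > 0.5

    is_sp = ~heel & ~mt1 & ~mt5 & ~toe
    is_hs = heel & ~mt1 & ~mt5 & ~toe
    is_ho = toe & ~heel
    if cfg.ho_requires_mt1:
        is_ho &= mt1
    is_ff = mt1 & mt5
    if cfg.ff_requires_heel:
        is_ff &= heel
    if cfg.ff_requires_toe:
        is_ff &= toe
    # priority stack: later assignments win, so order from least specific up
    code = np.full(binary.t.size, -1, dtype=np.int8)
    code[is_ff] = GaitPhase.FF
    code[is_ho] = GaitPhase.HO
    code[is_hs] = GaitPhase.HS
    code[is_sp] = GaitPhase.SP

    unmatched = code < 0
    if unmatched.all():
        raise ValueError("no sample matches any FSR activation pattern")
    if unmatched[0]:
        first = code[~unmatched][0]
        logger.warning("stream begins with an ambiguous FSR pattern; "
                       "back-filling with first matched phase %s", GaitPhase(first).name)
    # hold the previous label forward over unmatched samples
    idx = np.arange(code.size)
    idx[unmatched] = 0
    np.maximum.accumulate(idx, out=idx)
    out = code[idx]
    if out[0] < 0:  # unmatched prefix: back-fill
        first_pos = int(np.argmax(out >= 0))
        out[:first_pos] = out[first_pos]
    return LabelSequence(out, binary.fs, t0=float(binary.t[0]))


def phase_onsets(labels: LabelSequence) -> dict[GaitPhase, np.ndarray]:
    """Onset times (seconds) of each phase.

    An onset is a sample whose label differs from its predecessor's and
    equals the phase; HS onsets double as stride onsets.
    """
    lab = labels.labels
    t = labels.t
    onsets: dict[GaitPhase, np.ndarray] = {}
    change = np.flatnonzero(np.diff(lab)) + 1
    for phase in GaitPhase:
        sel = change[lab[change] == int(phase)]
        onsets[phase] = t[sel]
    return onsets
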