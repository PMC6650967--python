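"""Gait-phase vocabulary and per-sample label sequences.

The gait cycle is partitioned into four phases with a fixed cyclic order:
Heel Strike (HS) -> Flat Foot (FF) -> Heel-Off (HO) -> Swing Phase (SP) ->
HS of the next stride.  A stride is the interval between consecutive HS
onsets of the same foot.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class GaitPhase(enum.IntEnum):
    """Four-phase gait model, in cyclic order."""

    HS = 0  # heel strike: initial foot-ground contact
    FF = 1  # flat foot: loading response, sole on the ground
    HO = 2  # heel-off: late stance, heel lifting
    SP = 3  # swing phase: foot airborne

    @property
    def successor(self) -> "GaitPhase":
        """The next phase in the gait cycle (cyclic)."""
        return GaitPhase((int(self) + 1) % 4)


PHASES = (GaitPhase.HS, GaitPhase.FF, GaitPhase.HO, GaitPhase.SP)
PHASE_NAMES = tuple(p.name for p in PHASES)
N_PHASES = 4


@dataclass
class LabelSequence:
    """Per-sample gait-phase labels on a uniform time grid.

    Parameters
    ----------
    labels : array of int
        One :class:`GaitPhase` code per sample.
    fs : float
        Sampling rate in Hz.
    """

    labels: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a nonempty 1-D array")
        if not np.all((self.labels >= 0) & (self.labels <= 3)):
            raise ValueError("labels must be GaitPhase codes in 0..3")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.labels.size) / self.fs

    def phase_names(self) -> np.ndarray:
        """Labels as 'HS'/'FF'/'HO'/'SP' strings."""
        return np.asarray(PHASE_NAMES, dtype=object)[self.labels]

    def runs(self) -> list[tuple[GaitPhase, int, int]]:
        """Maximal constant-label runs as (phase, start, stop) index triples."""
        lab = self.labels
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [lab.size]))
        return [(GaitPhase(lab[a]), int(a), int(b)) for a, b in zip(starts, stops)]

    @classmethod
    def from_names(cls, names, fs: float, t0: float = 0.0) -> "LabelSequence":
        codes = np.array([GaitPhase[str(n)] for n in names], dtype=np.int8)
        return cls(codes, fs, t0)
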