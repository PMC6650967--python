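"""In-memory containers for IMU and FSR sensor streams.

Both streams live on strictly uniform time grids; the IMU is nominally
sampled at 100 Hz and the force-sensitive-resistor (FSR) insole at 200 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_UNIFORM_TOL = 1e-9  # seconds


def _check_grid(t: np.ndarray, fs: float) -> None:
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time axis must be a nonempty 1-D array")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / fs)) > max(_UNIFORM_TOL, 1e-6 / fs):
            raise ValueError("timestamps must be uniform at the declared rate")


@dataclass
class ImuStream:
    """Foot-instep IMU stream.

    Attributes
    ----------
    t : array
        Sample times, seconds, uniform grid.
    ay : array
        Vertical (normal) linear acceleration, m/s^2, gravity-removed.
    gy : array
        Sagittal-plane angular velocity, deg/s.
    fs : float
        Sampling rate, Hz (nominal 100).
    """

    t: np.ndarray
    ay: np.ndarray
    gy: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.gy = np.asarray(self.gy, dtype=float)
        _check_grid(self.t, self.fs)
        if self.ay.shape != self.t.shape or self.gy.shape != self.t.shape:
            raise ValueError("ay and gy must match the time axis length")

    def __len__(self) -> int:
        return self.t.size

    @classmethod
    def from_samples(cls, ay, gy, fs: float, t0: float = 0.0) -> "ImuStream":
        ay = np.asarray(ay, dtype=float)
        t = t0 + np.arange(ay.size) / fs
        return cls(t, ay, np.asarray(gy, dtype=float), fs)


@dataclass
class FsrStream:
    """Four-channel FSR insole stream (heel, 1st metatarsal, 5th metatarsal,
    hallux/toe), either analog readouts or binary activations.

    Attributes
    ----------
    t : array
        Sample times, seconds, uniform grid.
    heel, mt1, mt5, toe : array
        Channel readouts (arbitrary analog units, or {0,1} once binarized).
    fs : float
        Sampling rate, Hz (nominal 200).
    """

    t: np.ndarray
    heel: np.ndarray
    mt1: np.ndarray
    mt5: np.ndarray
    toe: np.ndarray
    fs: float

    CHANNELS = ("heel", "mt1", "mt5", "toe")

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        _check_grid(self.t, self.fs)
        for name in self.CHANNELS:
            ch = np.asarray(getattr(self, name), dtype=float)
            if ch.shape != self.t.shape:
                raise ValueError(f"channel {name!r} must match the time axis length")
            setattr(self, name, ch)

    def __len__(self) -> int:
        return self.t.size

    def channels(self) -> np.ndarray:
        """Channels stacked as a (n, 4) array in heel, mt1, mt5, toe order."""
        return np.column_stack([getattr(self, c) for c in self.CHANNELS])

    @classmethod
    def from_channels(cls, channels: np.ndarray, fs: float, t0: float = 0.0) -> "FsrStream":
        channels = np.asarray(channels, dtype=float)
        t = t0 + np.arange(channels.shape[0]) / fs
        return cls(t, *(channels[:, i] for i in range(4)), fs)
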