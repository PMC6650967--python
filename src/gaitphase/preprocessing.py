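"""Signal conditioning for raw IMU streams.

The conditioning chain used throughout the package: a median filter removes
atypical samples, a second-order low-pass Butterworth (17 Hz for the
accelerometer, 15 Hz for the gyroscope) removes sensor noise, and the IMU
streams are linearly interpolated from 100 Hz up to the 200 Hz FSR rate so
that detector output can be scored sample-by-sample against the reference.

The Butterworth filter is applied zero-phase (forward-backward).  The study
is offline, and a causal filter's group delay would bias every timing-error
measurement; the price is that the effective magnitude response is the
*squared* second-order Butterworth response.

Edges are handled by boundary replication so that no spurious onset
features appear at trial start.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .streams import ImuStream

logger = logging.getLogger(__name__)

ACCEL_CUTOFF_HZ = 17.0
GYRO_CUTOFF_HZ = 15.0
DEFAULT_MEDIAN_WINDOW = 5


def median_filter(x, window: int = DEFAULT_MEDIAN_WINDOW) -> np.ndarray:
    """Centered running median with boundary replication.

    Parameters
    ----------
    x : sequence of float
    window : odd int
        Window length in samples; must be odd and no longer than ``x``.
    """
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > x.size:
        raise ValueError("window exceeds sequence length")
    if window == 1:
        return x.copy()
    half = window // 2
    padded = np.concatenate((np.full(half, x[0]), x, np.full(half, x[-1])))
    view = np.lib.stride_tricks.sliding_window_view(padded, window)
    return np.median(view, axis=1)


def lowpass_butterworth(x, cutoff: float, fs: float, order: int = 2) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter.

    Applied forward-backward (``filtfilt``); the effective magnitude
    response is the squared ``order``-th Butterworth response and the phase
    response is zero.  DC gain is exactly 1.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must lie strictly between 0 and the Nyquist rate")
    b, a = sps.butter(order, cutoff, btype="low", fs=fs)
    padlen = min(3 * max(len(a), len(b)), x.size - 1)
    return sps.filtfilt(b, a, x, padlen=padlen)


def resample_linear(x, fs_src: float, fs_dst: float) -> np.ndarray:
    """Linear interpolation of a uniform sequence onto a new rate.

    The shared time span [0, (n-1)/fs_src] is preserved; the first sample is
    kept exactly.  Identity when ``fs_dst == fs_src``.
    """
    x = np.asarray(x, dtype=float)
    if fs_src <= 0 or fs_dst <= 0:
        raise ValueError("sampling rates must be positive")
    if x.size < 2:
        raise ValueError("need at least 2 samples to resample")
    if fs_dst == fs_src:
        return x.copy()
    span = (x.size - 1) / fs_src
    n_dst = int(np.floor(span * fs_dst)) + 1
    t_dst = np.arange(n_dst) / fs_dst
    t_src = np.arange(x.size) / fs_src
    return np.interp(t_dst, t_src, x)


def angular_acceleration(gy, fs: float) -> np.ndarray:
    """First-order backward finite difference, scaled to units/s.

    ``out[i] = (gy[i] - gy[i-1]) * fs``; the first element duplicates the
    second so the derivative aligns 1:1 with the input samples.
    """
    gy = np.asarray(gy, dtype=float)
    if gy.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    out = np.empty_like(gy)
    out[1:] = np.diff(gy) * fs
    out[0] = out[1]
    return out


def time_normalize_segments(x, boundaries, n_points: int) -> np.ndarray:
    """Linearly resample each segment of ``x`` to a common length.

    Parameters
    ----------
    x : sequence of float
    boundaries : iterable of (start, stop) index pairs
        Half-open sample ranges; empty segments are skipped with a warning.
    n_points : int
        Output length per segment.

    Returns
    -------
    (n_segments, n_points) array
    """
    x = np.asarray(x, dtype=float)
    if n_points < 1:
        raise ValueError("n_points must be positive")
    rows = []
    for start, stop in boundaries:
        seg = x[int(start):int(stop)]
        if seg.size == 0:
            logger.warning("empty segment (%s, %s) skipped", start, stop)
            continue
        if seg.size == 1:
            rows.append(np.full(n_points, seg[0]))
            continue
        pos = np.linspace(0.0, seg.size - 1, n_points)
        rows.append(np.interp(pos, np.arange(seg.size), seg))
    return np.vstack(rows) if rows else np.empty((0, n_points))


def preprocess_imu(
    imu: ImuStream,
    median_window: int = DEFAULT_MEDIAN_WINDOW,
    accel_cutoff: float = ACCEL_CUTOFF_HZ,
    gyro_cutoff: float = GYRO_CUTOFF_HZ,
    fs_out: float | None = None,
) -> ImuStream:
    """Standard conditioning chain: median filter, low-pass, optional resample.

    ``fs_out=200`` matches the FSR reference rate for sample-wise scoring;
    ``fs_out=None`` keeps the native IMU rate.
    """
    ay = lowpass_butterworth(median_filter(imu.ay, median_window), accel_cutoff, imu.fs)
    gy = lowpass_butterworth(median_filter(imu.gy, median_window), gyro_cutoff, imu.fs)
    fs = imu.fs
    if fs_out is not None and fs_out != imu.fs:
        ay = resample_linear(ay, imu.fs, fs_out)
        gy = resample_linear(gy, imu.fs, fs_out)
        fs = fs_out
    return ImuStream.from_samples(ay, gy, fs, t0=float(imu.t[0]))


def emission_features(gy, fs: float) -> np.ndarray:
    """Bivariate HMM observation vectors (omega, alpha).

    omega is the sagittal angular velocity (deg/s) and alpha its first-order
    finite-difference derivative (deg/s^2) at the stream rate.
    """
    gy = np.asarray(gy, dtype=float)
    return np.column_stack((gy, angular_acceleration(gy, fs)))
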