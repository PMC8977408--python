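"""Surface EMG preprocessing and time-domain feature extraction.

The feature set is the classic myoelectric control battery computed on a
sliding analysis window: mean absolute value (MAV), zero crossings (ZC),
slope sign changes (SSC), waveform length (WL), and the first two
coefficients of a fourth-order autoregressive (AR) model.  With the default
200 ms window advanced every 50 ms, an 8-channel recording yields a 20 Hz
stream of 48 features (muscle-major, feature-minor ordering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from statsmodels.regression.linear_model import burg

__all__ = [
    "EMG_CHANNELS",
    "FEATURE_NAMES",
    "EMGRecording",
    "EMGFeatureStream",
    "SampleRateError",
    "preprocess_emg",
    "mav",
    "zero_crossings",
    "slope_sign_changes",
    "waveform_length",
    "ar_coefficients",
    "extract_emg_features",
]

#: Default channel set: adductor magnus, biceps femoris, rectus femoris,
#: vastus lateralis, tensor fascia latae, medial gastrocnemius, tibialis
#: anterior, soleus.
EMG_CHANNELS = ("AM", "BF", "RF", "VL", "TFL", "MG", "TA", "SOL")

#: Per-channel feature order within the output matrix.
FEATURE_NAMES = ("MAV", "ZC", "SSC", "WL", "AR1", "AR2")

#: Band-pass corners for surface EMG conditioning, Hz.
BAND_HZ = (20.0, 450.0)


class SampleRateError(ValueError):
    """Sampling rate too low for the requested filter band."""


@dataclass
class EMGRecording:
    """Multi-channel surface EMG time series on a uniform clock.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Voltage samples in arbitrary units.
    sample_rate_hz : float
        Must exceed twice the 450 Hz band edge.
    channel_names : tuple of str
    t0 : float
        Time of the first sample, seconds.
    """

    data: np.ndarray
    sample_rate_hz: float = 1200.0
    channel_names: tuple = EMG_CHANNELS
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match data columns")
        if self.sample_rate_hz <= 2 * BAND_HZ[1]:
            raise SampleRateError(
                f"sample rate {self.sample_rate_hz} Hz below Nyquist for "
                f"{BAND_HZ[1]} Hz band edge"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate_hz

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.channel_names))
        df.insert(0, "time_s", self.times)
        return df


@dataclass
class EMGFeatureStream:
    """Windowed EMG features on a uniform clock (window-end timestamps)."""

    timestamps: np.ndarray
    values: np.ndarray
    columns: list
    rate_hz: float

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValueError("timestamps and values row counts differ")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column names do not match value columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "time_s", self.timestamps)
        return df


def _design_bandpass(sample_rate_hz: float, order: int = 4):
    if sample_rate_hz <= 2 * BAND_HZ[1]:
        raise SampleRateError(
            f"sample rate {sample_rate_hz} Hz cannot support a "
            f"{BAND_HZ[1]} Hz high cut-off"
        )
    return signal.butter(
        order, BAND_HZ, btype="bandpass", fs=sample_rate_hz, output="sos"
    )


def preprocess_emg(rec: EMGRecording, order: int = 4) -> EMGRecording:
    """Remove baseline offset and band-pass 20-450 Hz (zero-phase).

    Each channel is mean-subtracted, then filtered forward-backward with a
    Butterworth band-pass of the given design order, and finally re-centred
    so the residual DC from filter edge effects is exactly zero.
    """
    sos = _design_bandpass(rec.sample_rate_hz, order=order)
    out = np.empty_like(rec.data)
    for j in range(rec.data.shape[1]):
        x = rec.data[:, j] - rec.data[:, j].mean()
        if np.ptp(x) == 0.0:
            out[:, j] = 0.0
            continue
        y = signal.sosfiltfilt(sos, x)
        out[:, j] = y - y.mean()
    return EMGRecording(out, rec.sample_rate_hz, rec.channel_names, rec.t0)


def mav(window: np.ndarray) -> float:
    """Mean absolute value of a window."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(w)))


def zero_crossings(window: np.ndarray, deadband: float = 0.0) -> int:
    """Count sign changes between adjacent samples exceeding a deadband."""
    if deadband < 0:
        raise ValueError("deadband must be non-negative")
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    a, b = w[:-1], w[1:]
    return int(np.count_nonzero((a * b < 0) & (np.abs(a - b) > deadband)))


def slope_sign_changes(window: np.ndarray, deadband: float = 0.0) -> int:
    """Count interior samples that are local extrema beyond a deadband."""
    if deadband < 0:
        raise ValueError("deadband must be non-negative")
    w = np.asarray(window, dtype=float)
    if w.size < 3:
        raise ValueError("window must contain at least 3 samples")
    d1 = w[1:-1] - w[:-2]
    d2 = w[1:-1] - w[2:]
    return int(np.count_nonzero(d1 * d2 > deadband))


def waveform_length(window: np.ndarray) -> float:
    """Cumulative length of the waveform: sum of |first differences|."""
    w = np.asarray(window, dtype=float)
    if w.size < 2:
        raise ValueError("window must contain at least 2 samples")
    return float(np.sum(np.abs(np.diff(w))))


def ar_coefficients(window: np.ndarray, order: int = 4) -> tuple:
    """First two coefficients of an order-`order` AR model (Burg method).

    Convention: x_t ~ sum_k a_k x_{t-k}; returns (a_1, a_2).  A constant
    window has no AR structure and returns (0.0, 0.0) with a warning.
    """
    w = np.asarray(window, dtype=float)
    if w.size <= 10 * order:
        raise ValueError(
            f"window of {w.size} samples too short for AR order {order}"
        )
    if np.ptp(w) == 0.0:
        warnings.warn("constant window: AR coefficients undefined, returning 0")
        return (0.0, 0.0)
    rho, _ = burg(w, order=order, demean=True)
    return (float(rho[0]), float(rho[1]))


def extract_emg_features(
    rec: EMGRecording,
    window_s: float = 0.200,
    step_s: float = 0.050,
    deadband: float = 0.0,
    ar_order: int = 4,
) -> EMGFeatureStream:
    """Slide a window over every channel and emit the six-feature battery.

    Windows of ``window_s`` advance by ``step_s`` (defaults give a 20 Hz
    stream from 200 ms windows).  Row ``i`` covers samples
    ``[i*step, i*step + n_window)`` and is stamped with the window-end time.
    """
    if window_s < step_s:
        raise ValueError("window_s must be >= step_s")
    n_w = int(round(window_s * rec.sample_rate_hz))
    n_s = int(round(step_s * rec.sample_rate_hz))
    if rec.n_samples < n_w:
        raise ValueError("recording shorter than one analysis window")
    n_rows = (rec.n_samples - n_w) // n_s + 1
    n_ch = rec.data.shape[1]
    out = np.empty((n_rows, n_ch * len(FEATURE_NAMES)))
    for i in range(n_rows):
        start = i * n_s
        for j in range(n_ch):
            w = rec.data[start : start + n_w, j]
            col = j * len(FEATURE_NAMES)
            if np.ptp(w) == 0.0 and w[0] == 0.0:
                out[i, col : col + 6] = 0.0
                continue
            a1, a2 = ar_coefficients(w, order=ar_order)
            out[i, col : col + 6] = (
                mav(w),
                zero_crossings(w, deadband),
                slope_sign_changes(w, deadband),
                waveform_length(w),
                a1,
                a2,
            )
    timestamps = rec.t0 + (np.arange(n_rows) * n_s + n_w) / rec.sample_rate_hz
    columns = [
        f"{ch}_{feat}" for ch in rec.channel_names for feat in FEATURE_NAMES
    ]
    return EMGFeatureStream(timestamps, out, columns, rate_hz=1.0 / step_s)
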