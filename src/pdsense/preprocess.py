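"""Signal preparation for inertial recordings.

All filters are 4th-order Butterworth applied forward-backward
(zero-phase). Gravity removal (0.1 Hz high-pass) is meant for
accelerometer channels; the 20 Hz low-pass denoises every channel. The
magnitude signal sqrt(x^2 + y^2 + z^2) summarizes motion independent of
device orientation, and the band decomposition splits a channel into the
0-3, 3-9 and 9-14 Hz bands that carry slow voluntary movement / sway,
parkinsonian tremor, and higher-frequency content respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

FILTER_ORDER = 4
HIGHPASS_CUTOFF_HZ = 0.1
LOWPASS_CUTOFF_HZ = 20.0
BAND_EDGES = {"0-3 Hz": (None, 3.0), "3-9 Hz": (3.0, 9.0), "9-14 Hz": (9.0, 14.0)}

# Welch / STFT segmentation: 4 s Hann windows with 50% overlap.
WELCH_SEGMENT_S = 4.0
WELCH_OVERLAP = 0.5

_MIN_LEN = 3 * (2 * FILTER_ORDER + 1)  # default sosfiltfilt padding


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided power spectral density on a frequency grid up to Nyquist."""

    frequencies: np.ndarray
    psd: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.frequencies.size

    def band(self, lo: float | None, hi: float | None) -> "SpectrumEstimate":
        """Restrict the estimate to frequency bins in (lo, hi]."""
        f = self.frequencies
        mask = np.ones_like(f, dtype=bool)
        if lo is not None:
            mask &= f > lo
        if hi is not None:
            mask &= f <= hi
        return SpectrumEstimate(f[mask], self.psd[mask])


def _check_length(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D channel sequence")
    if x.size < _MIN_LEN:
        raise ValueError(
            f"signal of length {x.size} too short for zero-phase filtering "
            f"(need >= {_MIN_LEN} samples)"
        )
    return x


def highpass_gravity_removal(x: np.ndarray, fs: float = 50.0) -> np.ndarray:
    """Remove the gravitational (DC) component with a 0.1 Hz high-pass."""
    x = _check_length(x)
    sos = _sig.butter(FILTER_ORDER, HIGHPASS_CUTOFF_HZ, "highpass", fs=fs,
                      output="sos")
    # the 0.1 Hz corner has a multi-second impulse response; extend the
    # reflect padding so edge transients stay small on 30 s records
    return _sig.sosfiltfilt(sos, x, padlen=x.size - 1)


def lowpass_denoise(x: np.ndarray, fs: float = 50.0) -> np.ndarray:
    """Suppress content above 20 Hz (sensor noise, not PD motor activity)."""
    x = _check_length(x)
    sos = _sig.butter(FILTER_ORDER, LOWPASS_CUTOFF_HZ, "lowpass", fs=fs,
                      output="sos")
    return _sig.sosfiltfilt(sos, x)


def magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three axes, M = sqrt(x²+y²+z²)."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y, z must have equal lengths")
    return np.sqrt(x**2 + y**2 + z**2)


def band_decompose(x: np.ndarray, fs: float = 50.0) -> dict:
    """Split a channel into the 0-3, 3-9 and 9-14 Hz bands.

    The 0-3 Hz band is a 3 Hz low-pass (gravity already removed upstream);
    the others are band-passes. Output keys match ``BAND_EDGES``.
    """
    x = _check_length(x)
    out = {}
    for name, (lo, hi) in BAND_EDGES.items():
        if lo is None:
            sos = _sig.butter(FILTER_ORDER, hi, "lowpass", fs=fs, output="sos")
        else:
            sos = _sig.butter(FILTER_ORDER, (lo, hi), "bandpass", fs=fs,
                              output="sos")
        out[name] = _sig.sosfiltfilt(sos, x)
    return out


def estimate_psd(x: np.ndarray, fs: float = 50.0) -> SpectrumEstimate:
    """Welch PSD with 4 s Hann segments and 50% overlap.

    Satisfies Parseval approximately: the integrated density matches the
    signal variance for stationary input.
    """
    x = np.asarray(x, dtype=float)
    nperseg = min(int(WELCH_SEGMENT_S * fs), x.size)
    freqs, psd = _sig.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * WELCH_OVERLAP), detrend="constant",
    )
    return SpectrumEstimate(freqs, psd)


def preprocess_recording(rec) -> dict:
    """Filter a recording's channels and derive the magnitude signal.

    Returns ``{"X": ..., "Y": ..., "Z": ..., "M": ...}``. Accelerometer
    channels get the gravity high-pass; all channels get the 20 Hz
    low-pass. The magnitude is computed from the filtered axes.
    """
    channels = {}
    for name, raw in (("X", rec.x), ("Y", rec.y), ("Z", rec.z)):
        sig = np.asarray(raw, dtype=float)
        if rec.sensor == "accelerometer":
            sig = highpass_gravity_removal(sig, rec.sampling_rate)
        channels[name] = lowpass_denoise(sig, rec.sampling_rate)
    channels["M"] = magnitude(channels["X"], channels["Y"], channels["Z"])
    return channels
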