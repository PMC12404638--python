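"""Feature frontends: ERB cochleagram, rate resampling, low-pass filtering.

The cochleagram is the STRF frontend — a bank of gammatone-shaped
magnitude filters with center frequencies spaced on the ERB-rate scale,
applied to short-time spectra and logarithmically compressed.  The same
resampling and low-pass operations prepare any feature matrix (a network
layer or the cochleagram itself) for regression against binned spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import FeatureMatrix

__all__ = [
    "erb_rate",
    "erb_rate_inverse",
    "erb_center_frequencies",
    "Cochleagram",
    "cochleagram",
    "mel_spectrogram",
    "resample_features",
    "lowpass",
]


def erb_rate(freq_hz):
    """ERB-rate (Cams) at a frequency in Hz (Glasberg & Moore)."""
    return 21.4 * np.log10(1.0 + 4.37e-3 * np.asarray(freq_hz, dtype=float))


def erb_rate_inverse(cams):
    """Frequency in Hz at a given ERB-rate."""
    return (10.0 ** (np.asarray(cams, dtype=float) / 21.4) - 1.0) / 4.37e-3


def erb_bandwidth(freq_hz):
    """Equivalent rectangular bandwidth in Hz at a center frequency."""
    return 24.7 * (1.0 + 4.37e-3 * np.asarray(freq_hz, dtype=float))


def erb_center_frequencies(n_filters: int, fmin: float, fmax: float) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-rate scale, ascending."""
    return erb_rate_inverse(np.linspace(erb_rate(fmin), erb_rate(fmax), n_filters))


@dataclass
class Cochleagram:
    """Log filterbank amplitudes: (frames x filters) at a fixed frame rate."""

    center_frequencies: np.ndarray
    frame_times: np.ndarray
    log_amplitudes: np.ndarray
    frame_rate: float

    def as_feature_matrix(self) -> FeatureMatrix:
        return FeatureMatrix(self.log_amplitudes, self.frame_rate)


def _gammatone_gains(freqs: np.ndarray, cfs: np.ndarray, order: int = 4) -> np.ndarray:
    """(filters x freq-bins) magnitude response of a gammatone bank.

    |H(f)| = [1 + ((f - fc)/b)^2]^(-order/2), b the 1.019-scaled ERB.
    """
    b = 1.019 * erb_bandwidth(cfs)
    rel = (freqs[None, :] - cfs[:, None]) / b[:, None]
    return (1.0 + rel**2) ** (-order / 2.0)


def cochleagram(
    waveform: np.ndarray,
    sample_rate: float,
    n_filters: int = 211,
    fmin: float = 50.0,
    fmax: float = 8000.0,
    overlap: float = 0.875,
    frame_rate: float = 20.0,
    log_floor_ratio: float = 1e-5,
) -> Cochleagram:
    """ERB-spaced gammatone filterbank amplitudes, log-compressed.

    Frames hop at ``1/frame_rate`` seconds; the analysis window length is
    ``hop / (1 - overlap)`` so adjacent windows overlap by the stated
    fraction.  Filter amplitudes are root-summed gammatone-weighted
    spectral power, floor-clipped at ``log_floor_ratio`` times the global
    maximum before the log (silence maps to the log floor).
    """
    if fmin >= fmax:
        raise ValueError("fmin must be below fmax")
    if sample_rate < 2 * fmax:
        raise ValueError("sample_rate must be at least 2*fmax (Nyquist)")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    waveform = np.asarray(waveform, dtype=float).ravel()
    hop = int(round(sample_rate / frame_rate))
    win_len = int(round(hop / (1.0 - overlap)))
    window = np.hanning(win_len)
    pad = win_len // 2
    padded = np.concatenate([np.zeros(pad), waveform, np.zeros(win_len)])
    n_frames = max(1, int(np.ceil(len(waveform) / hop)))
    starts = np.arange(n_frames) * hop
    frames = np.stack([padded[s : s + win_len] for s in starts]) * window
    spec = np.abs(np.fft.rfft(frames, axis=1))
    freqs = np.fft.rfftfreq(win_len, d=1.0 / sample_rate)
    cfs = erb_center_frequencies(n_filters, fmin, fmax)
    gains = _gammatone_gains(freqs, cfs)
    amps = np.sqrt((spec**2) @ (gains.T**2))
    peak = amps.max()
    floor = log_floor_ratio * peak if peak > 0 else 1.0
    log_amps = np.log(np.maximum(amps, floor))
    times = starts / sample_rate
    return Cochleagram(cfs, times, log_amps, frame_rate)


def mel_frequencies(n_filters: int, fmin: float, fmax: float) -> np.ndarray:
    """Center frequencies equally spaced on the mel scale (HTK formula)."""
    mel = lambda f: 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)
    inv = lambda m: 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)
    return inv(np.linspace(mel(fmin), mel(fmax), n_filters))


def mel_spectrogram(
    waveform: np.ndarray,
    sample_rate: float,
    n_filters: int = 64,
    fmin: float = 50.0,
    fmax: float = 8000.0,
    overlap: float = 0.875,
    frame_rate: float = 20.0,
    log_floor_ratio: float = 1e-5,
) -> Cochleagram:
    """Alternative frontend: log mel-filterbank amplitudes.

    Same interface and framing as :func:`cochleagram` (which remains the
    default STRF frontend), but with triangular filters on mel-spaced
    center frequencies.
    """
    if fmin >= fmax:
        raise ValueError("fmin must be below fmax")
    if sample_rate < 2 * fmax:
        raise ValueError("sample_rate must be at least 2*fmax (Nyquist)")
    waveform = np.asarray(waveform, dtype=float).ravel()
    hop = int(round(sample_rate / frame_rate))
    win_len = int(round(hop / (1.0 - overlap)))
    window = np.hanning(win_len)
    pad = win_len // 2
    padded = np.concatenate([np.zeros(pad), waveform, np.zeros(win_len)])
    n_frames = max(1, int(np.ceil(len(waveform) / hop)))
    starts = np.arange(n_frames) * hop
    frames = np.stack([padded[s : s + win_len] for s in starts]) * window
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    freqs = np.fft.rfftfreq(win_len, d=1.0 / sample_rate)
    edges = mel_frequencies(n_filters + 2, fmin, fmax)
    gains = np.zeros((n_filters, freqs.size))
    for i in range(n_filters):
        lo, c, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs - lo) / max(c - lo, 1e-9)
        down = (hi - freqs) / max(hi - c, 1e-9)
        gains[i] = np.clip(np.minimum(up, down), 0, None)
    amps = np.sqrt(power @ gains.T)
    peak = amps.max()
    floor = log_floor_ratio * peak if peak > 0 else 1.0
    log_amps = np.log(np.maximum(amps, floor))
    return Cochleagram(edges[1:-1], starts / sample_rate, log_amps, frame_rate)


def resample_features(fm: FeatureMatrix, target_rate: float) -> FeatureMatrix:
    """Band-limited rational-factor resampling along time, per dimension.

    Output length is ``round(n * target / source)``.  Edge behavior uses
    linear padding so constant inputs stay constant.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if abs(target_rate - fm.sampling_rate) < 1e-12 * fm.sampling_rate:
        return FeatureMatrix(fm.values.copy(), target_rate)
    frac = Fraction(target_rate / fm.sampling_rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(fm.values, up, down, axis=0, padtype="line")
    n_out = int(round(fm.n_frames * target_rate / fm.sampling_rate))
    n_out = max(n_out, 1)
    if out.shape[0] >= n_out:
        out = out[:n_out]
    else:
        out = np.vstack([out, np.repeat(out[-1:], n_out - out.shape[0], axis=0)])
    return FeatureMatrix(out, target_rate)


def lowpass(fm: FeatureMatrix, cutoff: float, order: int = 4) -> FeatureMatrix:
    """Zero-phase Butterworth low-pass along time.

    A cutoff exactly at the Nyquist frequency returns the input unchanged
    (pass-through convention); above Nyquist is rejected.
    """
    nyquist = fm.sampling_rate / 2.0
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff > nyquist * (1 + 1e-9):
        raise ValueError(f"cutoff {cutoff} Hz exceeds Nyquist {nyquist} Hz")
    if cutoff >= nyquist * (1 - 1e-9):
        return FeatureMatrix(fm.values.copy(), fm.sampling_rate)
    sos = signal.butter(order, cutoff / nyquist, btype="low", output="sos")
    padlen = min(fm.n_frames - 1, 3 * (2 * order + 1))
    out = signal.sosfiltfilt(sos, fm.values, axis=0, padlen=padlen)
    return FeatureMatrix(out, fm.sampling_rate)
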