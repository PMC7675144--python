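"""Cochlear front end: waveform -> log-compressed gammatone spectrogram.

A bank of second-order gammatone filters with log-spaced centers (default
18 channels, 200 Hz - 20 kHz) filters the waveform; each channel's envelope
is extracted by half-wave rectification and low-pass smoothing, averaged
into 10-ms bins (100 Hz), and log-compressed with a fixed floor.

The compression is ``level = log10(x / x0 + 1)`` with ``x0`` a fixed
fraction (1e-3) of the full-scale RMS, so digital silence maps exactly to
the floor value 0 and amplitude scaling becomes an additive shift for bins
well above the floor.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .models import Spectrogram

__all__ = ["gammatone_spectrogram", "gammatone_center_frequencies", "read_wav"]

#: envelope smoothing: 4th-order Butterworth low-pass cutoff (Hz)
_ENV_LP_HZ = 30.0
#: compression floor as a fraction of full-scale RMS
_FLOOR_FRACTION = 1e-3


def gammatone_center_frequencies(n_channels: int = 18, f_low: float = 200.0,
                                 f_high: float = 20000.0) -> np.ndarray:
    """Logarithmically spaced center frequencies from ``f_low`` to ``f_high``."""
    return np.geomspace(f_low, f_high, n_channels)


def _erb(fc: float) -> float:
    # Glasberg & Moore equivalent rectangular bandwidth (Hz)
    return 24.7 * (4.37 * fc / 1000.0 + 1.0)


def _gammatone_kernel(fc: float, fs: float, order: int = 2) -> np.ndarray:
    """Unit-peak-gain gammatone impulse response for one channel."""
    b = 1.019 * _erb(fc)
    # length: envelope decayed to ~1e-4 of peak, at least 10 ms
    dur = max(0.010, 9.0 / (2.0 * np.pi * b))
    t = np.arange(1, int(round(dur * fs)) + 1) / fs
    g = t ** (order - 1) * np.exp(-2.0 * np.pi * b * t) * np.cos(2.0 * np.pi * fc * t)
    # normalize to unit magnitude response at fc
    H = np.fft.rfft(g, n=max(4096, 2 * g.size))
    freqs = np.fft.rfftfreq(max(4096, 2 * g.size), 1.0 / fs)
    peak = np.abs(H[np.argmin(np.abs(freqs - fc))])
    return g / peak


def gammatone_magnitude(f: np.ndarray, fc: float, order: int = 2) -> np.ndarray:
    """Analytic normalized magnitude response of a gammatone filter.

    ``|H(f)| = [1 + ((f - fc)/b)^2]^(-order/2)`` with ``b = 1.019 ERB(fc)``,
    normalized to 1 at the center frequency.  Useful as an independent
    check of the filterbank's tuning.
    """
    b = 1.019 * _erb(fc)
    return (1.0 + ((np.asarray(f, float) - fc) / b) ** 2) ** (-order / 2.0)


def gammatone_spectrogram(waveform: np.ndarray, fs: float, n_channels: int = 18,
                          f_low: float = 200.0, f_high: float = 20000.0,
                          bin_s: float = 0.01, order: int = 2,
                          full_scale: float | None = None) -> Spectrogram:
    """Convert a mono waveform to the model-input log spectrogram.

    Parameters
    ----------
    waveform : array
        Mono PCM samples.  Integer input is rescaled to [-1, 1].
    fs : float
        Sample rate in Hz; must be at least ``2 * f_high``.
    full_scale : float, optional
        Amplitude treated as digital full scale (default: 1.0 for float
        input, the dtype maximum for integer input).  Sets the fixed
        compression floor.
    """
    waveform = np.asarray(waveform)
    if waveform.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if fs < 2.0 * f_high:
        raise ValueError(
            f"sample rate {fs} Hz violates the Nyquist requirement for "
            f"f_high={f_high} Hz (need >= {2 * f_high} Hz)"
        )
    if np.issubdtype(waveform.dtype, np.integer):
        scale = float(np.iinfo(waveform.dtype).max)
        waveform = waveform.astype(float) / scale
        if full_scale is None:
            full_scale = 1.0
    else:
        waveform = waveform.astype(float)
        if full_scale is None:
            full_scale = 1.0

    centers = gammatone_center_frequencies(n_channels, f_low, f_high)
    n_bins = int(np.ceil(waveform.size / fs / bin_s))
    samples_per_bin = fs * bin_s

    sos = sps.butter(4, _ENV_LP_HZ, btype="low", fs=fs, output="sos")
    x0 = _FLOOR_FRACTION * full_scale / np.sqrt(2.0)

    levels = np.empty((n_channels, n_bins))
    edges = (np.arange(n_bins + 1) * samples_per_bin).round().astype(int)
    edges = np.minimum(edges, waveform.size)
    for ch, fc in enumerate(centers):
        kern = _gammatone_kernel(fc, fs, order=order)
        filtered = sps.fftconvolve(waveform, kern, mode="full")[: waveform.size]
        env = sps.sosfilt(sos, np.maximum(filtered, 0.0))
        env = np.maximum(env, 0.0)
        # mean envelope within each 10-ms bin
        cs = np.concatenate([[0.0], np.cumsum(env)])
        counts = np.maximum(np.diff(edges), 1)
        binned = (cs[edges[1:]] - cs[edges[:-1]]) / counts
        levels[ch] = np.log10(binned / x0 + 1.0)
    return Spectrogram(levels=levels, channel_centers_hz=centers, bin_s=bin_s)


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a mono PCM WAV file, returning (samples, sample_rate)."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    return data, float(fs)


def write_wav(path, samples: np.ndarray, fs: float) -> None:
    """Write mono float samples in [-1, 1] as a 16-bit PCM WAV file."""
    samples = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(fs), (samples * 32767).astype(np.int16))
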