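"""Normalization and low-pass filtering of PPG segments.

Records are first min-max normalized to [0, 1] and then low-pass filtered
to strip high-frequency noise.  Four interchangeable filter families are
provided — 7th-order Butterworth (default), centered moving average,
linear-phase FIR, and wavelet (DWT) denoising — all applied so that
landmark *times* are preserved: the IIR path runs forward-backward
(zero phase), the moving-average and FIR kernels are symmetric, and the
DWT reconstruction is time-aligned.

The default cutoff is 12 Hz: the PPG-BP acquisition hardware band-passed
at 0.5-12 Hz, so nothing physiological lives above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .ingest import PPGRecord

__all__ = ["FilterSpec", "normalize", "filter_signal", "preprocess_record"]

_METHODS = ("butterworth", "moving_average", "fir", "dwt")


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter configuration.

    Parameters
    ----------
    method : str
        One of ``butterworth`` (IIR, zero-phase), ``moving_average``
        (centered boxcar), ``fir`` (windowed-sinc, symmetric), ``dwt``
        (db4 soft-threshold denoising).
    cutoff : float
        Low-pass cutoff in Hz (must be below Nyquist).  For the moving
        average the window length is chosen so the first response null
        sits at the cutoff; for DWT the detail levels covering
        frequencies above the cutoff are thresholded.
    order : int
        Butterworth order (default 7).
    numtaps : int
        FIR tap count (odd; symmetric kernel).
    wavelet : str
        Wavelet name for the DWT path.
    """

    method: str = "butterworth"
    cutoff: float = 12.0
    order: int = 7
    numtaps: int = 101
    wavelet: str = "db4"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.numtaps < 3 or self.numtaps % 2 == 0:
            raise ValueError("numtaps must be odd and >= 3")


def normalize(samples: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]: ``(s - min) / (max - min)``.

    Raises
    ------
    ValueError
        For a constant signal (zero denominator).
    """
    samples = np.asarray(samples, dtype=float)
    lo, hi = samples.min(), samples.max()
    if hi == lo:
        raise ValueError("cannot normalize a constant signal (max == min)")
    return (samples - lo) / (hi - lo)


def _moving_average_window(cutoff: float, fs: float) -> int:
    # First spectral null of a length-w boxcar sits at fs/w; put it at the
    # cutoff, forced odd so the kernel is symmetric (zero phase).
    w = max(3, int(round(fs / cutoff)))
    return w + 1 if w % 2 == 0 else w


def filter_signal(samples: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply the configured low-pass filter; output length equals input length."""
    x = np.asarray(samples, dtype=float)
    nyq = fs / 2.0
    if spec.method != "dwt" and spec.cutoff >= nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz >= Nyquist {nyq} Hz")

    if spec.method == "butterworth":
        sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=fs, output="sos")
        return sps.sosfiltfilt(sos, x, padtype="even", padlen=min(x.size - 1, 3 * (2 * spec.order + 1)))

    if spec.method == "moving_average":
        w = _moving_average_window(spec.cutoff, fs)
        kernel = np.full(w, 1.0 / w)
        padded = np.pad(x, w // 2, mode="reflect")
        return np.convolve(padded, kernel, mode="valid")

    if spec.method == "fir":
        taps = sps.firwin(spec.numtaps, spec.cutoff, fs=fs)
        half = spec.numtaps // 2
        padded = np.pad(x, half, mode="reflect")
        return np.convolve(padded, taps, mode="valid")

    # DWT denoising: soft universal threshold on the detail levels whose
    # frequency band lies above the cutoff (level j covers ~[fs/2^(j+1), fs/2^j]).
    n_above = max(1, int(np.floor(np.log2(nyq / spec.cutoff))))
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(spec.wavelet).dec_len)
    n_above = min(n_above, max_level)
    coeffs = pywt.wavedec(x, spec.wavelet, level=max_level)
    # universal threshold from the finest detail level's noise estimate
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if coeffs[-1].size else 0.0
    thresh = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))
    for lvl in range(1, n_above + 1):
        coeffs[-lvl] = pywt.threshold(coeffs[-lvl], thresh, mode="soft")
    return pywt.waverec(coeffs, spec.wavelet)[: x.size]


def preprocess_record(record: PPGRecord, spec: FilterSpec = FilterSpec()) -> PPGRecord:
    """Normalize to [0, 1] then low-pass filter; provenance stored in meta."""
    filtered = filter_signal(normalize(record.samples), record.fs, spec)
    meta = dict(record.meta)
    meta["preprocessed"] = True
    meta["filter_spec"] = spec
    return PPGRecord(filtered, record.fs, record.subject_id, record.segment_id, meta)
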