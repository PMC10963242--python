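"""Beat detection, cycle segmentation and best-cycle selection.

A preprocessed record is scanned for systolic peaks (prominence- and
distance-gated local maxima), segmented into valley-to-valley single-beat
cycles, and the cycle with the largest systolic amplitude above its own
onset baseline is selected as the "best" beat for feature extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .ingest import PPGRecord

__all__ = [
    "PPGCycle",
    "detect_systolic_peaks",
    "segment_cycles",
    "select_best_cycle",
    "best_cycle_from_record",
    "DEFAULT_PROMINENCE",
    "MAX_HEART_RATE",
]

#: Minimum peak prominence on the [0, 1]-normalized amplitude scale.
DEFAULT_PROMINENCE = 0.1
#: Physiological ceiling used for the minimum peak separation (beats/min).
MAX_HEART_RATE = 180.0


@dataclass
class PPGCycle:
    """One complete beat, onset-to-onset, cut from a parent record."""

    samples: np.ndarray
    onset_index: int
    fs: float
    subject_id: str = ""
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 5:
            raise ValueError("a cycle needs at least 5 samples")

    @property
    def tpi(self) -> float:
        """Cycle duration (pulse interval) in seconds."""
        return self.samples.size / self.fs

    @property
    def peak_index(self) -> int:
        """Index of the systolic peak within the cycle."""
        return int(np.argmax(self.samples))

    @property
    def systolic_amplitude(self) -> float:
        """Peak height above the cycle-onset baseline."""
        return float(self.samples.max() - self.samples[0])


def detect_systolic_peaks(
    record: PPGRecord,
    prominence: float = DEFAULT_PROMINENCE,
    max_heart_rate: float = MAX_HEART_RATE,
) -> np.ndarray:
    """Indices of systolic peaks, sorted ascending.

    Local maxima with prominence >= ``prominence`` and pairwise separation
    >= ``fs * 60/max_heart_rate`` samples.  Returns an empty array (with a
    warning) when no peak qualifies.
    """
    d_min = max(1, int(round(record.fs * 60.0 / max_heart_rate)))
    peaks, _ = sps.find_peaks(record.samples, prominence=prominence, distance=d_min)
    if peaks.size == 0:
        warnings.warn(
            f"no systolic peak found in record {record.subject_id}_{record.segment_id}",
            stacklevel=2,
        )
    return peaks


def _onset_between(samples: np.ndarray, lo: int, hi: int) -> int:
    return lo + int(np.argmin(samples[lo : hi + 1]))


def segment_cycles(
    record: PPGRecord,
    peak_indices: np.ndarray,
) -> list[PPGCycle]:
    """Cut the record into onset-to-onset single-beat cycles.

    Onsets are the minima (valleys) between consecutive systolic peaks, so
    a complete cycle is one bounded by an in-record valley on each side;
    the leading and trailing partial beats are dropped.  Concatenating the
    returned cycles reproduces the record between the first and last onset
    exactly.
    """
    peaks = np.asarray(peak_indices, dtype=int)
    x = record.samples
    if peaks.size == 0:
        return []
    if peaks.size < 3:
        warnings.warn(
            "fewer than 3 systolic peaks: no valley-bounded complete cycle",
            stacklevel=2,
        )
        return []

    onsets = [
        _onset_between(x, peaks[i], peaks[i + 1]) for i in range(peaks.size - 1)
    ]

    cycles = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        if b - a < 5:
            continue
        interior = x[a : b + 1]
        if np.argmax(interior) in (0, interior.size - 1):
            continue  # no interior systolic peak: not a complete beat
        cycles.append(
            PPGCycle(x[a:b], a, record.fs, record.subject_id, record.segment_id)
        )
    return cycles


def select_best_cycle(cycles: list[PPGCycle]) -> PPGCycle:
    """The cycle with maximum systolic amplitude; ties go to the earliest onset.

    Amplitude is measured above the cycle's own onset value, which makes the
    choice robust to residual baseline drift.
    """
    if not cycles:
        raise ValueError("no complete cycles: record unusable")
    best = cycles[0]
    for c in cycles[1:]:
        if c.systolic_amplitude > best.systolic_amplitude:
            best = c
    return best


def best_cycle_from_record(
    record: PPGRecord,
    prominence: float = DEFAULT_PROMINENCE,
    max_heart_rate: float = MAX_HEART_RATE,
) -> PPGCycle:
    """Convenience: detect peaks, segment, and return the best cycle."""
    peaks = detect_systolic_peaks(record, prominence, max_heart_rate)
    cycles = segment_cycles(record, peaks)
    return select_best_cycle(cycles)
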