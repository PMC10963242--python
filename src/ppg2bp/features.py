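"""Fiducial-point location and the 48-slot PPG feature vector.

From the selected best cycle the module locates the classic PPG landmarks
(systolic peak ``x``/``t1``, dicrotic notch ``z``/``t2``, diastolic peak
``y``/``t3``), the first-derivative landmarks (``a1``, ``b1``, ``e1``,
``l1``) and the acceleration-plethysmogram (second-derivative) waves
(``a2``, ``b2``, ``e2`` relative to the cycle-start reference ``l2``),
plus three spectral peaks of the full segment.  These are combined into a
canonical 48-slot feature vector: 21 PPG-waveform features, 8 from the
first derivative, 11 from the second derivative, 6 from the FFT magnitude
spectrum, and the subject's age and gender.

Conventions (documented because the literature's symbols are loose):
``ta1``/``tb1``/``te1``/``tl1`` and ``ta2``/``tb2`` are absolute times
from the cycle onset; the named feature ``tb1`` (slot 23, "elapsed time
between a1 and b1") is the difference ``tb1 - ta1`` while the ratio slot
27 uses the absolute valley time.  ``l1`` is the last downward
zero-crossing of the first derivative (the landmark closing the cycle),
``l2`` is the cycle start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cycles import PPGCycle
from .ingest import PPGRecord, SubjectRecord

__all__ = [
    "Fiducials",
    "DerivativeFiducials",
    "SpectralPeaks",
    "FeatureVector",
    "FeatureError",
    "NoNotchError",
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "differentiate",
    "locate_fiducials",
    "width_and_areas",
    "locate_derivative_fiducials",
    "spectral_features",
    "assemble_feature_vector",
    "extract_features",
    "build_feature_matrix",
]

#: Canonical 48 feature names, in table order: slots 1-21 PPG waveform,
#: 22-29 first derivative, 30-40 second derivative, 41-46 spectrum,
#: 47-48 demographics.
FEATURE_NAMES: tuple[str, ...] = (
    "x", "y", "z", "tpi",
    "y/x", "(x-y)/x", "z/x", "(y-x)/x",
    "t1", "t2", "t3", "dT", "w",
    "A3/(A1+A2)", "(A2+A3)/A1",
    "t1/x", "y/(tpi-t3)",
    "t1/tpi", "t2/tpi", "t3/tpi", "dT/tpi",
    "ta1", "tb1", "te1", "tl1",
    "ta1/tpi", "tb1/tpi", "te1/tpi", "tl1/tpi",
    "b2/a2", "e2/a2", "(b2+e2)/a2",
    "ta2", "tb2", "ta2/tpi", "tb2/tpi",
    "(ta1+ta2)/tpi", "(tb1+tb2)/tpi", "(te1+t2)/tpi", "(tl1+t3)/tpi",
    "f_base", "|s_base|", "f_2nd", "|s_2nd|", "f_3rd", "|s_3rd|",
    "age", "gender",
)

FEATURE_GROUPS = {
    "ppg": FEATURE_NAMES[0:21],
    "d1": FEATURE_NAMES[21:29],
    "d2": FEATURE_NAMES[29:40],
    "fft": FEATURE_NAMES[40:46],
    "demographic": FEATURE_NAMES[46:48],
}

#: Auxiliary named feature: some selection tables refer to slot 14 as the
#: simple area ratio A2/A1 rather than the inflection-point area ratio.
AUX_FEATURE_NAMES = ("A2/A1",)

#: Smoothing window (samples) applied to the second derivative before
#: landmark detection and amplitude read-out.
D2_SMOOTH_WINDOW = 11

#: Cycles whose diastolic peak falls within this many seconds of the cycle
#: end are rejected (slot 17's denominator tpi - t3 would blow up).
MIN_TAIL = 0.005


class FeatureError(ValueError):
    """A feature could not be computed for this cycle/record."""


class NoNotchError(FeatureError):
    """The dicrotic notch (or a dependent landmark) is undetectable."""


@dataclass(frozen=True)
class Fiducials:
    """PPG-waveform landmarks of one cycle (times in s from cycle onset,
    amplitudes above the cycle-onset baseline)."""

    x: float
    y: float
    z: float
    t1: float
    t2: float
    t3: float
    tpi: float
    w: float
    A1: float
    A2: float
    A3: float

    def __post_init__(self) -> None:
        if not (0 < self.t1 < self.t2 < self.t3 < self.tpi):
            raise FeatureError(
                f"landmark times must satisfy 0 < t1 < t2 < t3 < tpi, got "
                f"t1={self.t1:.4f} t2={self.t2:.4f} t3={self.t3:.4f} tpi={self.tpi:.4f}"
            )
        if self.x < self.z or self.x < self.y:
            raise FeatureError("systolic amplitude must dominate notch and diastolic")


@dataclass(frozen=True)
class DerivativeFiducials:
    """First/second-derivative landmarks (absolute times from cycle onset)."""

    a1: float
    b1: float
    e1: float
    ta1: float
    tb1: float
    te1: float
    tl1: float
    a2: float
    b2: float
    e2: float
    ta2: float
    tb2: float

    def __post_init__(self) -> None:
        if not (0 < self.ta1 < self.tb1):
            raise FeatureError("require 0 < ta1 < tb1")
        if not (0 < self.ta2 < self.tb2):
            raise FeatureError("require 0 < ta2 < tb2")


@dataclass(frozen=True)
class SpectralPeaks:
    """The three leading spectral components of a segment (Hz, magnitude)."""

    f_base: float
    s_base: float
    f_2nd: float
    s_2nd: float
    f_3rd: float
    s_3rd: float

    def __post_init__(self) -> None:
        if not (self.f_base < self.f_2nd < self.f_3rd):
            raise FeatureError("spectral peak frequencies must be increasing")


@dataclass
class FeatureVector:
    """The 48 ordered named feature values for one (subject, segment)."""

    values: np.ndarray
    subject_id: str = ""
    segment_id: str = ""
    aux: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} values")
        if not np.all(np.isfinite(self.values)):
            bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(self.values))]
            raise FeatureError(f"non-finite feature values: {bad}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES))

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def differentiate(
    cycle: PPGCycle | np.ndarray,
    order: int = 1,
    fs: float | None = None,
    smooth: int = 0,
) -> np.ndarray:
    """Central-difference derivative scaled to physical units (s^-1, s^-2).

    Same length as the input (one-sided at the ends).  ``smooth`` applies a
    centered moving average of that many samples to the *result*; it is used
    identically for landmark detection and feature computation.
    """
    if isinstance(cycle, PPGCycle):
        x, fs = cycle.samples, cycle.fs
    else:
        x = np.asarray(cycle, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if x.size < 5:
        raise FeatureError("cycle too short to differentiate")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    d = np.gradient(x) * fs
    if order == 2:
        d = np.gradient(d) * fs
    if smooth and smooth > 1:
        k = np.full(smooth, 1.0 / smooth)
        d = np.convolve(np.pad(d, smooth // 2, mode="edge"), k, mode="valid")[: x.size]
    return d


# ---------------------------------------------------------------------------
# PPG-waveform landmarks
# ---------------------------------------------------------------------------

def locate_fiducials(
    cycle: PPGCycle,
    notch_window_fraction: float = 0.6,
) -> Fiducials:
    """Locate systolic peak, dicrotic notch and diastolic peak on a cycle.

    The systolic peak is the global maximum.  The notch is the most
    prominent local minimum in the window ``(t1, t1 + f*(tpi - t1))``
    (default f=0.6, keeping end-of-cycle troughs out of reach); if no local
    minimum qualifies, the maximum of the smoothed second derivative in
    that window is used as a fallback.  The diastolic peak is the first
    local maximum after the notch, falling back to the strongest inflection
    (second-derivative minimum) after the notch.  Raises
    :class:`NoNotchError` when the chain fails — mirroring the screening
    observation that unfit waveforms lack dicrotic notches.
    """
    s = cycle.samples
    fs = cycle.fs
    baseline = float(s[0])
    i1 = cycle.peak_index
    if i1 == 0 or i1 == s.size - 1:
        raise FeatureError("systolic peak must be interior to the cycle")
    t1 = i1 / fs
    tpi = cycle.tpi
    x = float(s[i1]) - baseline

    lo = i1 + 1
    hi = min(s.size - 2, i1 + int(round(notch_window_fraction * (s.size - i1))))
    if hi <= lo + 1:
        raise NoNotchError("no room after the systolic peak for a notch")
    window = s[lo : hi + 1]
    minima, props = sps.find_peaks(-window, prominence=0.0)
    if minima.size:
        i2 = lo + int(minima[np.argmax(props["prominences"])])
    else:
        d2 = differentiate(cycle, order=2, smooth=D2_SMOOTH_WINDOW)
        i2 = lo + int(np.argmax(d2[lo : hi + 1]))
        # the fallback must still sit below the systolic peak level
        if s[i2] >= s[i1]:
            raise NoNotchError("dicrotic notch undetectable")
    t2 = i2 / fs
    z = float(s[i2]) - baseline

    # prominence gate keeps residual filter ripple from masquerading as
    # the diastolic wave; 2% of the cycle's amplitude range
    after = s[i2:]
    maxima, _ = sps.find_peaks(after, prominence=0.02 * float(np.ptp(s)))
    if maxima.size:
        i3 = i2 + int(maxima[0])
    else:
        d2 = differentiate(cycle, order=2, smooth=D2_SMOOTH_WINDOW)
        seg = d2[i2 + 1 : s.size - 1]
        if seg.size == 0:
            raise NoNotchError("diastolic peak undetectable")
        i3 = i2 + 1 + int(np.argmin(seg))
    t3 = i3 / fs
    y = float(s[i3]) - baseline

    # plausibility: a real dicrotic notch is a trough with the diastolic
    # wave rising above it; fallback hits on notch-less decaying flanks
    # produce y < z and are rejected
    if y < z:
        raise NoNotchError("no diastolic wave above the notch candidate")

    if tpi - t3 < MIN_TAIL:
        raise FeatureError(
            f"diastolic peak within {MIN_TAIL*1e3:.0f} ms of cycle end "
            "(slot 17 denominator would diverge)"
        )

    w, A1, A2, A3 = _width_and_areas_raw(s, fs, baseline, i1, i2)
    return Fiducials(x=x, y=y, z=z, t1=t1, t2=t2, t3=t3, tpi=tpi, w=w, A1=A1, A2=A2, A3=A3)


def _width_and_areas_raw(
    s: np.ndarray, fs: float, baseline: float, i1: int, i2: int
) -> tuple[float, float, float, float]:
    corrected = s - baseline
    half = corrected[i1] / 2.0

    # rising crossing
    rise = np.flatnonzero(corrected[: i1 + 1] >= half)
    if rise.size == 0 or rise[0] == 0:
        raise FeatureError("half-amplitude not crossed on the rising flank")
    r = rise[0]
    frac = (half - corrected[r - 1]) / (corrected[r] - corrected[r - 1])
    t_rise = (r - 1 + frac) / fs

    # falling crossing (first time the signal drops below half after the peak)
    fall = np.flatnonzero(corrected[i1:] <= half)
    if fall.size == 0:
        raise FeatureError("half-amplitude not crossed on the falling flank")
    f = i1 + fall[0]
    frac = (corrected[f - 1] - half) / (corrected[f - 1] - corrected[f])
    t_fall = (f - 1 + frac) / fs

    w = t_fall - t_rise
    t = np.arange(s.size) / fs
    A1 = float(np.trapezoid(corrected[: i1 + 1], t[: i1 + 1]))
    A2 = float(np.trapezoid(corrected[i1 : i2 + 1], t[i1 : i2 + 1]))
    A3 = float(np.trapezoid(corrected[i2:], t[i2:]))
    return float(w), A1, A2, A3


def width_and_areas(cycle: PPGCycle, fiducials: Fiducials) -> tuple[float, float, float, float]:
    """Full width at half systolic amplitude and the three pulse areas.

    ``w`` is the time between the two half-amplitude crossings (linear
    interpolation between samples, onset-baseline corrected); ``A1``/``A2``/
    ``A3`` are trapezoidal areas of the baseline-corrected waveform from
    onset to ``t1``, ``t1`` to ``t2``, and ``t2`` to the cycle end.
    """
    i1 = int(round(fiducials.t1 * cycle.fs))
    i2 = int(round(fiducials.t2 * cycle.fs))
    return _width_and_areas_raw(cycle.samples, cycle.fs, float(cycle.samples[0]), i1, i2)


# ---------------------------------------------------------------------------
# derivative landmarks
# ---------------------------------------------------------------------------

def locate_derivative_fiducials(
    cycle: PPGCycle,
    smooth_d2: int = D2_SMOOTH_WINDOW,
) -> DerivativeFiducials:
    """Locate a1/b1/e1/l1 on the first derivative and a2/b2/e2 on the second.

    First derivative: ``a1`` is the global maximum (steepest upstroke),
    ``b1`` the global minimum after it, ``e1`` the most prominent local
    maximum after ``b1`` (diastolic upswing), ``l1`` the last downward
    zero-crossing (the landmark closing the cycle).  Second derivative
    (smoothed): ``a2`` is the first prominent maximum (the APG a-wave),
    ``b2`` the following minimum, ``e2`` the largest maximum after ``b2``;
    ``ta2``/``tb2`` are measured from the cycle start (the ``l2``
    reference).  Any missing landmark raises :class:`FeatureError`.
    """
    fs = cycle.fs
    d1 = differentiate(cycle, order=1)
    d2 = differentiate(cycle, order=2, smooth=smooth_d2)

    ia1 = int(np.argmax(d1))
    if ia1 == 0:
        raise FeatureError("first-derivative peak at cycle boundary")
    a1 = float(d1[ia1])
    rest = d1[ia1 + 1 :]
    if rest.size == 0:
        raise FeatureError("no room after a1")
    ib1 = ia1 + 1 + int(np.argmin(rest))
    b1 = float(d1[ib1])

    seg = d1[ib1 + 1 : d1.size - 1]
    maxima, props = sps.find_peaks(seg, prominence=0.0)
    if maxima.size == 0:
        raise FeatureError("e1 (post-b1 first-derivative maximum) undetectable")
    ie1 = ib1 + 1 + int(maxima[np.argmax(props["prominences"])])
    e1 = float(d1[ie1])

    # l1: last downward zero-crossing of PPG' in the cycle
    sign = np.signbit(d1)
    down = np.flatnonzero(~sign[:-1] & sign[1:])
    if down.size == 0:
        raise FeatureError("l1 (closing zero-crossing of PPG') undetectable")
    il1 = int(down[-1])
    # linear interpolation of the crossing instant
    tl1 = (il1 + d1[il1] / (d1[il1] - d1[il1 + 1])) / fs

    # second-derivative (APG) waves
    prom = 0.05 * float(np.max(np.abs(d2))) if np.any(d2) else 0.0
    pk, _ = sps.find_peaks(d2, prominence=prom)
    pk = pk[pk > 0]
    if pk.size == 0:
        raise FeatureError("a2 (APG a-wave) undetectable")
    ia2 = int(pk[0])
    a2 = float(d2[ia2])
    rest2 = d2[ia2 + 1 :]
    if rest2.size == 0:
        raise FeatureError("no room after a2")
    ib2 = ia2 + 1 + int(np.argmin(rest2))
    b2 = float(d2[ib2])
    seg2 = d2[ib2 + 1 : d2.size - 1]
    maxima2, props2 = sps.find_peaks(seg2, prominence=0.0)
    if maxima2.size == 0:
        raise FeatureError("e2 (APG e-wave) undetectable")
    ie2 = ib2 + 1 + int(maxima2[np.argmax(props2["prominences"])])
    e2 = float(d2[ie2])

    return DerivativeFiducials(
        a1=a1, b1=b1, e1=e1,
        ta1=ia1 / fs, tb1=ib1 / fs, te1=ie1 / fs, tl1=float(tl1),
        a2=a2, b2=b2, e2=e2,
        ta2=ia2 / fs, tb2=ib2 / fs,
    )


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------

def spectral_features(
    record: PPGRecord,
    f_min: float = 0.5,
    f_max: float = 12.0,
) -> SpectralPeaks:
    """The three leading components of the segment's magnitude spectrum.

    The FFT (length = next power of two >= record length, mean removed, no
    window) is scanned in ``[f_min, f_max]`` Hz: ``f_base`` is the largest
    local magnitude maximum; the 2nd/3rd components are the next two local
    maxima above ``f_base`` in ascending frequency.  The spectrum is taken
    over the full segment, not the single cycle, so the harmonic structure
    at ~0.5 Hz resolution is resolvable.
    """
    x = record.samples - record.samples.mean()
    nfft = 1 << (x.size - 1).bit_length()
    mag = np.abs(np.fft.rfft(x, nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / record.fs)
    band = (freqs >= f_min) & (freqs <= f_max)
    idx = np.flatnonzero(band)
    if idx.size < 5:
        raise FeatureError("spectral band too narrow at this record length")
    peaks, props = sps.find_peaks(mag[idx], prominence=0.0)
    if peaks.size == 0:
        raise FeatureError("no spectral peak in band")
    base_pos = peaks[np.argmax(mag[idx][peaks])]
    # harmonic components must stand clear of zero-padding ripple: keep
    # peaks whose prominence is at least 5% of the fundamental's magnitude
    keep = props["prominences"] >= 0.05 * mag[idx][base_pos]
    peaks = idx[peaks[keep]]
    if peaks.size == 0:
        raise FeatureError("no prominent spectral peak in band")
    base = peaks[np.argmax(mag[peaks])]
    above = peaks[peaks > base]
    if above.size < 2:
        raise FeatureError(
            f"fewer than three spectral peaks in [{f_min}, {f_max}] Hz"
        )
    p2, p3 = above[0], above[1]
    return SpectralPeaks(
        f_base=float(freqs[base]), s_base=float(mag[base]),
        f_2nd=float(freqs[p2]), s_2nd=float(mag[p2]),
        f_3rd=float(freqs[p3]), s_3rd=float(mag[p3]),
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_feature_vector(
    fiducials: Fiducials,
    derivative_fiducials: DerivativeFiducials,
    spectral: SpectralPeaks,
    subject: SubjectRecord,
    segment_id: str = "",
    slope_convention: str = "as-printed",
) -> FeatureVector:
    """Combine landmarks, spectrum and demographics into the 48-slot vector.

    Every ratio is computed exactly per its table definition.  Slot 16
    ("systolic peak rising slope") is ``t1/x`` as printed; pass
    ``slope_convention="physical"`` to use the physical slope ``x/t1``
    instead.  Zero denominators raise :class:`FeatureError` naming the slot.
    """
    f, d, sp = fiducials, derivative_fiducials, spectral
    tpi = f.tpi

    def div(num: float, den: float, name: str) -> float:
        if den == 0:
            raise FeatureError(f"zero denominator computing feature {name!r}")
        return num / den

    dT = f.t3 - f.t1
    slot16 = (
        div(f.t1, f.x, "t1/x")
        if slope_convention == "as-printed"
        else div(f.x, f.t1, "t1/x")
    )
    values = np.array(
        [
            f.x, f.y, f.z, tpi,
            div(f.y, f.x, "y/x"),
            div(f.x - f.y, f.x, "(x-y)/x"),
            div(f.z, f.x, "z/x"),
            div(f.y - f.x, f.x, "(y-x)/x"),
            f.t1, f.t2, f.t3, dT, f.w,
            div(f.A3, f.A1 + f.A2, "A3/(A1+A2)"),
            div(f.A2 + f.A3, f.A1, "(A2+A3)/A1"),
            slot16,
            div(f.y, tpi - f.t3, "y/(tpi-t3)"),
            div(f.t1, tpi, "t1/tpi"),
            div(f.t2, tpi, "t2/tpi"),
            div(f.t3, tpi, "t3/tpi"),
            div(dT, tpi, "dT/tpi"),
            d.ta1,
            d.tb1 - d.ta1,
            d.te1,
            d.tl1,
            div(d.ta1, tpi, "ta1/tpi"),
            div(d.tb1, tpi, "tb1/tpi"),
            div(d.te1, tpi, "te1/tpi"),
            div(d.tl1, tpi, "tl1/tpi"),
            div(d.b2, d.a2, "b2/a2"),
            div(d.e2, d.a2, "e2/a2"),
            div(d.b2 + d.e2, d.a2, "(b2+e2)/a2"),
            d.ta2, d.tb2,
            div(d.ta2, tpi, "ta2/tpi"),
            div(d.tb2, tpi, "tb2/tpi"),
            div(d.ta1 + d.ta2, tpi, "(ta1+ta2)/tpi"),
            div(d.tb1 + d.tb2, tpi, "(tb1+tb2)/tpi"),
            div(d.te1 + f.t2, tpi, "(te1+t2)/tpi"),
            div(d.tl1 + f.t3, tpi, "(tl1+t3)/tpi"),
            sp.f_base, sp.s_base, sp.f_2nd, sp.s_2nd, sp.f_3rd, sp.s_3rd,
            subject.age,
            subject.gender_code,
        ]
    )
    aux = {"A2/A1": div(f.A2, f.A1, "A2/A1")}
    return FeatureVector(values, subject.subject_id, segment_id, aux=aux)


def extract_features(
    record: PPGRecord,
    subject: SubjectRecord,
    cycle: PPGCycle | None = None,
    slope_convention: str = "as-printed",
) -> FeatureVector:
    """Full single-record pipeline: best cycle -> landmarks -> 48 features.

    ``record`` must already be preprocessed.  Raises :class:`FeatureError`
    (or a subclass) when the record is unusable.
    """
    from .cycles import best_cycle_from_record

    if cycle is None:
        cycle = best_cycle_from_record(record)
    fid = locate_fiducials(cycle)
    dfid = locate_derivative_fiducials(cycle)
    spec = spectral_features(record)
    return assemble_feature_vector(
        fid, dfid, spec, subject, record.segment_id, slope_convention
    )


def build_feature_matrix(
    records,
    subjects: dict[str, SubjectRecord] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature matrix for a cohort: one row per usable (subject, segment).

    ``subjects`` is either a mapping subject_id -> :class:`SubjectRecord`
    or a subject table DataFrame (as from ``ingest.read_subject_table`` /
    ``synthetic.generate_cohort``).  Returns ``(matrix, failures)`` where
    the matrix carries the 48 canonical columns plus ``subject_id``,
    ``segment_id`` and reference ``sbp``/``map``/``dbp``, and ``failures``
    logs each skipped record with the reason.
    """
    if isinstance(subjects, pd.DataFrame):
        df = subjects.reset_index() if subjects.index.name == "subject_id" else subjects
        subjects = {
            str(r["subject_id"]): SubjectRecord(
                subject_id=str(r["subject_id"]),
                age=float(r["age"]),
                gender=str(r["sex"]),
                sbp_ref=float(r["sbp"]),
                dbp_ref=float(r["dbp"]),
            )
            for _, r in df.iterrows()
        }
    rows, failures = [], []
    for rec in records:
        sub = subjects.get(rec.subject_id)
        if sub is None:
            failures.append(
                {"subject_id": rec.subject_id, "segment_id": rec.segment_id,
                 "reason": "subject not in table"}
            )
            continue
        try:
            fv = extract_features(rec, sub)
        except (FeatureError, ValueError) as err:
            failures.append(
                {"subject_id": rec.subject_id, "segment_id": rec.segment_id,
                 "reason": str(err)}
            )
            continue
        row = dict(zip(FEATURE_NAMES, fv.values))
        row.update(
            subject_id=rec.subject_id, segment_id=rec.segment_id,
            sbp=sub.sbp_ref, map=sub.map_ref, dbp=sub.dbp_ref,
        )
        rows.append(row)
    matrix = pd.DataFrame(rows)
    return matrix, pd.DataFrame(failures)
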