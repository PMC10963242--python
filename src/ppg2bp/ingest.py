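"""Reading PPG-BP-style records and screening them for quality.

The expected on-disk layout mirrors the public PPG-BP dataset
export: one plain-text file per 2.1-s fingertip PPG segment (one sample per
row, 1 kHz) named ``<subject>_<segment>.txt``, plus a subject table CSV with
columns ``subject_id, sex, age, height, weight, sbp, dbp``.

Quality screening uses the skewness signal-quality index (SQI): the third
standardized moment of the segment's amplitude distribution.  Clean PPG
pulses are right-skewed (a narrow systolic peak above a broad diastolic
tail), so segments with low or negative skewness — flat lines, inverted or
notch-less waveforms, motion-dominated traces — are flagged unfit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PPGRecord",
    "SubjectRecord",
    "QualityVerdict",
    "FormatError",
    "DEFAULT_SQI_THRESHOLD",
    "GENDER_ENCODING",
    "read_record",
    "write_record",
    "read_subject_table",
    "compute_map",
    "skewness_sqi",
    "screen_cohort",
]

#: Default cut-off for the skewness SQI.  Positive skew = fit; the PPG-BP
#: screening cut-off was never published, so 0.0 is a calibrated stand-in
#: (good pulses are right-skewed) and is configurable everywhere it is used.
DEFAULT_SQI_THRESHOLD = 0.0

#: Fixed gender encoding used in feature vectors.
GENDER_ENCODING = {"female": 0.0, "f": 0.0, "male": 1.0, "m": 1.0}


class FormatError(ValueError):
    """Raised when a record or table file does not parse."""


@dataclass
class PPGRecord:
    """One raw or preprocessed PPG segment.

    Attributes
    ----------
    samples : ndarray
        Amplitude values in file order (arbitrary units).
    fs : float
        Sampling rate in Hz.
    subject_id, segment_id : str
        Linkage back to the subject table.
    meta : dict
        Free-form provenance (filter spec, preprocessing flags, ...).
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    segment_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("a PPG record needs at least 2 samples in 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("PPG record contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate fs must be positive")

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from segment start."""
        return np.arange(self.samples.size) / self.fs


@dataclass
class SubjectRecord:
    """Demographics and reference blood pressure for one subject."""

    subject_id: str
    age: float
    gender: str
    sbp_ref: float
    dbp_ref: float
    height: float = float("nan")
    weight: float = float("nan")

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not (self.sbp_ref > self.dbp_ref > 0):
            raise ValueError(
                f"require sbp > dbp > 0, got sbp={self.sbp_ref}, dbp={self.dbp_ref}"
            )
        g = str(self.gender).strip().lower()
        if g not in GENDER_ENCODING:
            raise ValueError(f"unrecognized gender {self.gender!r}")
        self.gender = "male" if GENDER_ENCODING[g] == 1.0 else "female"

    @property
    def map_ref(self) -> float:
        """Mean arterial pressure derived from the stored SBP/DBP."""
        return compute_map(self.sbp_ref, self.dbp_ref)

    @property
    def gender_code(self) -> float:
        """Numeric gender encoding (female=0, male=1)."""
        return GENDER_ENCODING[self.gender]


@dataclass(frozen=True)
class QualityVerdict:
    """Outcome of skewness-SQI screening for one segment."""

    sqi_value: float
    fit: bool
    threshold: float
    reason: str = ""


def compute_map(sbp: float, dbp: float) -> float:
    """Mean arterial pressure ``(2*DBP + SBP)/3`` in mmHg.

    Raises
    ------
    ValueError
        If ``sbp <= dbp`` or ``dbp <= 0`` (outside the formula's domain).
    """
    if not (sbp > dbp > 0):
        raise ValueError(f"require sbp > dbp > 0, got sbp={sbp}, dbp={dbp}")
    return (2.0 * dbp + sbp) / 3.0


def read_record(
    path: str | os.PathLike,
    fs: float,
    subject_id: str = "",
    segment_id: str = "",
) -> PPGRecord:
    """Read one plain-text PPG segment (one numeric sample per row).

    Lines are read in file order; no resampling is performed.  Empty files
    and non-numeric rows raise :class:`FormatError` naming the offending row.
    """
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {line!r} at row {lineno}"
                ) from None
    if len(values) < 2:
        raise FormatError(f"{path}: expected >= 2 samples, found {len(values)}")
    if not subject_id or not segment_id:
        stem = os.path.splitext(os.path.basename(path))[0]
        parts = stem.rsplit("_", 1)
        subject_id = subject_id or parts[0]
        segment_id = segment_id or (parts[1] if len(parts) == 2 else "1")
    return PPGRecord(np.array(values), fs, subject_id, segment_id)


def write_record(record: PPGRecord, path: str | os.PathLike) -> None:
    """Write a record in the same one-sample-per-row format ``read_record`` reads."""
    np.savetxt(path, record.samples, fmt="%.17g")


def read_subject_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the subject table CSV and derive the MAP column.

    Expects columns ``subject_id, sex, age, height, weight, sbp, dbp``;
    returns a DataFrame indexed by ``subject_id`` with an added ``map``
    column per MAP = (2*DBP + SBP)/3.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "sex", "age", "sbp", "dbp"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df[~(df["sbp"] > df["dbp"])]
    if len(bad):
        raise FormatError(
            f"{path}: sbp <= dbp for subjects {bad['subject_id'].tolist()}"
        )
    df = df.set_index("subject_id")
    df["map"] = (2.0 * df["dbp"] + df["sbp"]) / 3.0
    return df


def skewness_sqi(
    record: PPGRecord,
    threshold: float = DEFAULT_SQI_THRESHOLD,
    estimator: str = "population",
) -> QualityVerdict:
    """Skewness signal-quality index of a segment.

    The SQI is the third standardized moment of the amplitude distribution;
    ``estimator`` selects the population (biased, default) or sample
    (bias-corrected) form.  The verdict is ``fit`` iff SQI >= ``threshold``.
    A constant segment has no defined skewness and is flagged unfit with
    reason ``"zero-variance"``.
    """
    x = record.samples
    if np.ptp(x) == 0 or np.std(x) == 0:
        return QualityVerdict(float("nan"), False, threshold, reason="zero-variance")
    if estimator == "population":
        value = float(stats.skew(x, bias=True))
    elif estimator == "sample":
        value = float(stats.skew(x, bias=False))
    else:
        raise ValueError(f"unknown skewness estimator {estimator!r}")
    return QualityVerdict(value, value >= threshold, threshold)


def screen_cohort(
    records: Iterable[PPGRecord],
    threshold: float = DEFAULT_SQI_THRESHOLD,
) -> tuple[list[PPGRecord], pd.DataFrame]:
    """Partition records into fit and unfit by the skewness SQI.

    Returns the kept records and a rejection log (one row per *input*
    record, with the SQI value, verdict and reason) so that
    ``len(kept) + (log.fit == False).sum() == len(records)``.
    """
    records = list(records)
    if not records:
        raise ValueError("screen_cohort requires at least one record")
    kept: list[PPGRecord] = []
    rows = []
    for rec in records:
        verdict = skewness_sqi(rec, threshold)
        if verdict.fit:
            kept.append(rec)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "segment_id": rec.segment_id,
                "sqi": verdict.sqi_value,
                "fit": verdict.fit,
                "reason": verdict.reason,
            }
        )
    return kept, pd.DataFrame(rows)
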