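"""Synthetic fingertip-PPG generator with known ground truth.

Every beat is a sum of three Gaussian bumps — systolic peak, dicrotic
notch shoulder, diastolic peak — whose amplitudes are solved so that the
summed waveform passes exactly through the configured landmark values at
the configured landmark times.  Beats are tiled at the pulse interval
(60/heart-rate seconds) with the beat onset at the pre-systolic minimum,
and the configured noise (baseline drift, powerline tone, white noise)
is added on top.  Because every landmark position and amplitude is known
at generation time, the detection, segmentation and feature-extraction
stages can be tested for landmark recovery without any external data.

Cohort generation maps each subject's reference blood pressure to beat
morphology through a smooth, monotone, documented map (plus small
per-segment jitter), so that feature-to-BP regression has a recoverable
signal; reference SBP/DBP labels carry configurable measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import fsolve

from .ingest import PPGRecord, compute_map

__all__ = [
    "SyntheticBeatConfig",
    "NoiseConfig",
    "BeatLandmarks",
    "GroundTruth",
    "DEFAULT_NOISE",
    "generate_record",
    "generate_cohort",
    "default_bp_sampler",
    "default_morphology_map",
    "make_unfit",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticBeatConfig:
    """Morphology of one synthetic PPG beat.

    Amplitudes are in arbitrary units; all landmark times are fractions of
    the pulse interval ``tpi = 60/heart_rate``.  Ratios are relative to the
    systolic amplitude ``x``: ``diastolic_amplitude_ratio = y/x`` and
    ``notch_depth_ratio = z/x``.  Widths are Gaussian sigmas as fractions
    of ``tpi``.
    """

    heart_rate: float = 72.0
    systolic_amplitude: float = 1.0
    diastolic_amplitude_ratio: float = 0.45
    notch_depth_ratio: float = 0.30
    systolic_time_fraction: float = 0.20
    notch_time_fraction: float = 0.42
    diastolic_time_fraction: float = 0.55
    systolic_width_fraction: float = 0.090
    notch_width_fraction: float = 0.060
    diastolic_width_fraction: float = 0.140

    def __post_init__(self) -> None:
        if not 40.0 <= self.heart_rate <= 180.0:
            raise ValueError(
                f"heart_rate must lie in [40, 180] bpm, got {self.heart_rate}"
            )
        if not self.systolic_amplitude > 0:
            raise ValueError("systolic_amplitude must be positive")
        if not (
            0.0
            < self.systolic_time_fraction
            < self.notch_time_fraction
            < self.diastolic_time_fraction
            < 1.0
        ):
            raise ValueError(
                "require 0 < systolic_time_fraction < notch_time_fraction"
                " < diastolic_time_fraction < 1"
            )
        if not 0.0 < self.notch_depth_ratio < 1.0:
            raise ValueError("notch_depth_ratio must lie in (0, 1)")
        if not 0.0 < self.diastolic_amplitude_ratio < 1.0:
            raise ValueError("diastolic_amplitude_ratio must lie in (0, 1)")
        if not self.notch_depth_ratio < self.diastolic_amplitude_ratio:
            raise ValueError(
                "notch_depth_ratio must be below diastolic_amplitude_ratio"
                " (the notch is a local minimum)"
            )
        for name in (
            "systolic_width_fraction",
            "notch_width_fraction",
            "diastolic_width_fraction",
        ):
            if not 0.0 < getattr(self, name) < 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5)")

    @property
    def tpi(self) -> float:
        """Pulse interval in seconds."""
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise components of a synthetic record.

    ``baseline_drift`` is a slow sinusoid (< 0.5 Hz), ``powerline`` a mains
    tone (e.g. 50 Hz); white noise is zero-mean Gaussian per sample.
    Amplitudes are in the same arbitrary units as the beat waveform.
    """

    baseline_drift_amplitude: float = 0.0
    baseline_drift_frequency: float = 0.25
    powerline_amplitude: float = 0.0
    powerline_frequency: float = 50.0
    white_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "baseline_drift_amplitude",
            "powerline_amplitude",
            "white_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_drift_amplitude > 0 and not (
            0 < self.baseline_drift_frequency < 0.5
        ):
            raise ValueError("baseline_drift_frequency must lie in (0, 0.5) Hz")


#: Default noise model used by cohort generation: visible but mild drift,
#: mains pickup and sensor noise on the unit-amplitude beat waveform.
DEFAULT_NOISE = NoiseConfig(
    baseline_drift_amplitude=0.05,
    baseline_drift_frequency=0.25,
    powerline_amplitude=0.02,
    powerline_frequency=50.0,
    white_noise_sd=0.01,
)


@dataclass(frozen=True)
class BeatLandmarks:
    """True landmark positions of one complete synthetic beat.

    Times are absolute seconds from record start; amplitudes are waveform
    values (before noise).  ``onset`` is the pre-systolic minimum (valley)
    opening the beat and ``tpi`` the valley-to-valley duration;
    ``t1/t2/t3`` are systolic peak, dicrotic notch and diastolic peak
    times, with amplitudes ``x``, ``z``, ``y``.
    """

    onset: float
    t1: float
    t2: float
    t3: float
    x: float
    z: float
    y: float
    tpi: float


@dataclass
class GroundTruth:
    """Everything the generator knows about a record."""

    beats: list[BeatLandmarks]
    sbp: float = float("nan")
    dbp: float = float("nan")
    config: SyntheticBeatConfig | None = None
    noise: NoiseConfig | None = None
    bp_map_coefficients: dict = field(default_factory=dict)

    @property
    def map(self) -> float:
        """Mean arterial pressure of the stored reference SBP/DBP."""
        return compute_map(self.sbp, self.dbp)


@lru_cache(maxsize=4096)
def _beat_bumps(cfg: SyntheticBeatConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centers, sigmas and amplitudes of one beat's three Gaussians.

    The six free parameters (three amplitudes, three centers) are solved so
    that the summed waveform has value *and* zero slope at each configured
    landmark: the systolic and diastolic peaks are true local maxima at
    (t1, x) and (t3, y) and the dicrotic notch a true local minimum at
    (t2, z).  Falls back to the value-only linear solve (nominal centers)
    if the root find does not converge for an extreme configuration.
    """
    tpi = cfg.tpi
    nominal = tpi * np.array(
        [
            cfg.systolic_time_fraction,
            cfg.notch_time_fraction,
            cfg.diastolic_time_fraction,
        ]
    )
    sigmas = tpi * np.array(
        [
            cfg.systolic_width_fraction,
            cfg.notch_width_fraction,
            cfg.diastolic_width_fraction,
        ]
    )
    x = cfg.systolic_amplitude
    targets = np.array(
        [x, x * cfg.notch_depth_ratio, x * cfg.diastolic_amplitude_ratio]
    )

    def linear_amps(centers: np.ndarray) -> np.ndarray:
        # G[i, j] = value of bump j at landmark time i
        G = np.exp(
            -0.5 * ((nominal[:, None] - centers[None, :]) / sigmas[None, :]) ** 2
        )
        return np.linalg.solve(G, targets)

    def residual(p: np.ndarray) -> np.ndarray:
        amps, centers = p[:3], p[3:]
        d = nominal[:, None] - centers[None, :]
        g = np.exp(-0.5 * (d / sigmas[None, :]) ** 2)
        value = g @ amps - targets
        slope = (g * (-d / sigmas[None, :] ** 2)) @ amps
        return np.concatenate([value, slope])

    p0 = np.concatenate([linear_amps(nominal), nominal])
    sol, info, ier, _ = fsolve(residual, p0, full_output=True)
    if ier == 1 and sol[0] > 0:
        amplitudes, centers = sol[:3].copy(), sol[3:].copy()
    else:  # pragma: no cover - extreme configurations only
        centers = nominal.copy()
        amplitudes = linear_amps(centers)
    return centers, sigmas, amplitudes


def _render_beats(
    t: np.ndarray, onsets: Sequence[float], configs: Sequence[SyntheticBeatConfig]
) -> np.ndarray:
    wave = np.zeros_like(t)
    for onset, cfg in zip(onsets, configs):
        centers, sigmas, amps = _beat_bumps(cfg)
        for c, s, a in zip(centers, sigmas, amps):
            wave += a * np.exp(-0.5 * ((t - onset - c) / s) ** 2)
    return wave


def _refine_extremum(
    wave: np.ndarray, fs: float, t_nominal: float, half_window: float, kind: str
) -> tuple[float, float]:
    """Locate the extremum of ``wave`` nearest ``t_nominal`` (seconds)."""
    lo = max(0, int(round((t_nominal - half_window) * fs)))
    hi = min(wave.size, int(round((t_nominal + half_window) * fs)) + 1)
    window = wave[lo:hi]
    idx = lo + (np.argmax(window) if kind == "max" else np.argmin(window))
    return idx / fs, float(wave[idx])


def generate_record(
    beat_config: SyntheticBeatConfig | Sequence[SyntheticBeatConfig] = SyntheticBeatConfig(),
    noise_config: NoiseConfig = NoiseConfig(),
    fs: float = 1000.0,
    duration: float = 2.1,
    seed: int | np.random.Generator | None = 0,
    subject_id: str = "synthetic",
    segment_id: str = "1",
) -> tuple[PPGRecord, GroundTruth]:
    """Generate one PPG segment plus its ground truth.

    ``beat_config`` may be a single configuration (all beats identical) or a
    sequence, one per beat in order (cycled if the record holds more beats);
    each beat's period is its own config's ``60/heart_rate``.  The record has
    exactly ``round(fs * duration)`` samples.  Beats are tiled at their pulse
    intervals starting at time zero, with one virtual beat rendered before
    the record start and after its end, so the segment is a window into a
    continuous beat train (the way a 2.1-s clip is cut from an acquisition).

    Ground truth lists only the *complete* beats: those bounded by an
    in-record pre-systolic minimum (valley) on both sides.  Landmark times
    and amplitudes are refined to the actual extrema of the noiseless
    waveform, since the Gaussian tails of neighboring bumps shift them
    slightly from their nominal positions; the stored ``onset`` is the left
    valley and ``tpi`` the valley-to-valley duration, matching what the
    cycle-segmentation stage measures.
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if isinstance(beat_config, SyntheticBeatConfig):
        base_configs = [beat_config]
    else:
        base_configs = list(beat_config)
        if not base_configs:
            raise ValueError("beat_config sequence must be nonempty")

    n = int(round(fs * duration))
    t = np.arange(n) / fs

    # Tile beats from one virtual beat before the record through one past
    # its end, so edge beats have realistic decay/rise tails.
    lead_cfg = base_configs[-1 % len(base_configs)]
    onsets: list[float] = [-lead_cfg.tpi]
    configs: list[SyntheticBeatConfig] = [lead_cfg]
    onset = 0.0
    k = 0
    while onset < duration + base_configs[k % len(base_configs)].tpi:
        cfg = base_configs[k % len(base_configs)]
        onsets.append(onset)
        configs.append(cfg)
        onset += cfg.tpi
        k += 1

    clean = _render_beats(t, onsets, configs)

    # Refine the systolic peak of every beat whose nominal peak lies
    # in-record, then take valleys between consecutive refined peaks.
    peak_info = []  # (peak_time, onset, cfg)
    for onset, cfg in zip(onsets, configs):
        tpi = cfg.tpi
        p_nom = onset + cfg.systolic_time_fraction * tpi
        if not (0.01 * tpi < p_nom < duration - 1.0 / fs):
            continue
        win = 0.5 * tpi * (cfg.notch_time_fraction - cfg.systolic_time_fraction)
        t1, x = _refine_extremum(clean, fs, p_nom, win, "max")
        peak_info.append((t1, onset, cfg))

    valley_times = []
    for (pa, _, _), (pb, _, _) in zip(peak_info[:-1], peak_info[1:]):
        ia, ib = int(round(pa * fs)), int(round(pb * fs))
        iv = ia + int(np.argmin(clean[ia : ib + 1]))
        valley_times.append(iv / fs)

    beats: list[BeatLandmarks] = []
    for j in range(1, len(peak_info) - 1):
        t1, onset_nom, cfg = peak_info[j]
        tpi = cfg.tpi
        v_left, v_right = valley_times[j - 1], valley_times[j]
        win = min(
            0.5 * tpi * (cfg.notch_time_fraction - cfg.systolic_time_fraction),
            0.5 * tpi * (cfg.diastolic_time_fraction - cfg.notch_time_fraction),
        )
        x = float(clean[int(round(t1 * fs))])
        t2, z = _refine_extremum(
            clean, fs, onset_nom + cfg.notch_time_fraction * tpi, win, "min"
        )
        t3, y = _refine_extremum(
            clean, fs, onset_nom + cfg.diastolic_time_fraction * tpi, win, "max"
        )
        beats.append(
            BeatLandmarks(v_left, t1, t2, t3, x, z, y, v_right - v_left)
        )

    noise = np.zeros(n)
    nc = noise_config
    if nc.baseline_drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        noise += nc.baseline_drift_amplitude * np.sin(
            2 * np.pi * nc.baseline_drift_frequency * t + phase
        )
    if nc.powerline_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        noise += nc.powerline_amplitude * np.sin(
            2 * np.pi * nc.powerline_frequency * t + phase
        )
    if nc.white_noise_sd > 0:
        noise += rng.normal(0.0, nc.white_noise_sd, n)

    record = PPGRecord(clean + noise, fs, subject_id, segment_id, meta={"synthetic": True})
    truth = GroundTruth(beats=beats, config=base_configs[0], noise=nc)
    return record, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def default_bp_sampler(rng: np.random.Generator) -> tuple[float, float, float, str]:
    """Sample one subject's (SBP, DBP, age, gender).

    Matches the study population's reported moments: age 57 +/- 15 years,
    ~48% male, SBP ~ N(127, 20) clipped to [80, 174] mmHg, DBP ~ N(71, 11)
    clipped to [42, 104] mmHg.  SBP is partially driven by age, and a
    minimum pulse pressure of 20 mmHg is enforced so SBP > DBP always.
    """
    age = float(np.clip(rng.normal(57.0, 15.0), 21.0, 85.0))
    gender = "male" if rng.random() < 0.48 else "female"
    sbp = float(np.clip(rng.normal(127.0 + 0.4 * (age - 57.0), 18.0), 80.0, 174.0))
    dbp = float(np.clip(rng.normal(71.0, 11.0), 42.0, 104.0))
    dbp = min(dbp, sbp - 20.0)
    dbp = max(dbp, 42.0)
    if sbp <= dbp:  # can only happen at the extreme low end of SBP
        sbp = dbp + 20.0
    return sbp, dbp, age, gender


#: Slopes of the default BP -> morphology map (per mmHg); these make every
#: morphology parameter a monotone function of SBP or DBP so BP can be
#: recovered from extracted features.  heart_rate rises with SBP;
#: y/x (augmentation) rises with SBP; systolic time fraction falls with
#: SBP; notch depth and timing track DBP.
BP_MAP_COEFFICIENTS = {
    "hr_per_sbp": 0.18,
    "yx_per_sbp": 0.0022,
    "sysfrac_per_sbp": -0.0007,
    "zx_per_dbp": 0.0022,
    "notchfrac_per_dbp": -0.0009,
}


def default_morphology_map(
    sbp: float,
    dbp: float,
    rng: np.random.Generator | None = None,
    jitter_scale: float = 1.0,
) -> SyntheticBeatConfig:
    """Map reference BP to beat morphology (monotone, plus optional jitter).

    The jitter models beat-to-beat/segment-to-segment physiological
    variability around the subject's deterministic morphology; at
    ``jitter_scale=0`` the map is exact.
    """
    c = BP_MAP_COEFFICIENTS
    j = (lambda s: rng.normal(0.0, s) * jitter_scale) if rng is not None and jitter_scale > 0 else (lambda s: 0.0)
    # the floor of 68 bpm keeps >= 3 systolic peaks (hence >= 1 complete
    # valley-to-valley cycle) inside a 2.1-s segment for every morphology
    hr = np.clip(72.0 + c["hr_per_sbp"] * (sbp - 127.0) + j(1.2), 68.0, 150.0)
    yx = np.clip(0.45 + c["yx_per_sbp"] * (sbp - 127.0) + j(0.006), 0.22, 0.70)
    sys_frac = np.clip(
        0.20 + c["sysfrac_per_sbp"] * (sbp - 127.0) + j(0.003), 0.12, 0.30
    )
    zx = np.clip(0.30 + c["zx_per_dbp"] * (dbp - 71.0) + j(0.006), 0.10, yx - 0.05)
    notch_frac = np.clip(
        0.42 + c["notchfrac_per_dbp"] * (dbp - 71.0) + j(0.003),
        sys_frac + 0.10,
        0.55,
    )
    dia_frac = notch_frac + 0.13
    return SyntheticBeatConfig(
        heart_rate=float(hr),
        systolic_amplitude=1.0,
        diastolic_amplitude_ratio=float(yx),
        notch_depth_ratio=float(zx),
        systolic_time_fraction=float(sys_frac),
        notch_time_fraction=float(notch_frac),
        diastolic_time_fraction=float(dia_frac),
    )


def make_unfit(record: PPGRecord) -> PPGRecord:
    """Turn a segment into an unfit one by inverting it about its mean.

    An inverted fingertip PPG (a common probe/contact artifact) has its
    narrow systolic peaks pointing down, so the amplitude skewness flips
    sign exactly and the skewness SQI flags the segment.
    """
    flipped = 2.0 * record.samples.mean() - record.samples
    return PPGRecord(flipped, record.fs, record.subject_id, record.segment_id,
                     dict(record.meta, unfit=True))


def generate_cohort(
    n_subjects: int,
    segments_per_subject: int = 3,
    bp_sampler: Callable[[np.random.Generator], tuple[float, float, float, str]] | None = None,
    feature_bp_map: Callable[..., SyntheticBeatConfig] | None = None,
    seed: int = 0,
    noise_config: NoiseConfig = DEFAULT_NOISE,
    label_noise_sd: float = 3.0,
    jitter_scale: float = 1.0,
    unfit_segments: int = 0,
    fs: float = 1000.0,
    duration: float = 2.1,
) -> tuple[list[PPGRecord], pd.DataFrame, dict[tuple[str, str], GroundTruth]]:
    """Generate a study-shaped cohort of PPG segments with a subject table.

    Each subject gets ``segments_per_subject`` 2.1-s segments whose beat
    morphology is the deterministic monotone image of the subject's latent
    BP (``default_morphology_map``) plus per-segment jitter.  The subject
    table stores reference SBP/DBP = latent BP plus N(0, label_noise_sd)
    measurement noise (SBP > DBP enforced), along with age, gender and MAP.
    ``unfit_segments`` segments (chosen at random across the cohort) are
    inverted about their mean — a probe-contact artifact — so that
    skewness-SQI screening rejects them.

    Returns (records, subject_table, truths) where ``truths`` maps
    (subject_id, segment_id) to the segment's :class:`GroundTruth`.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if segments_per_subject < 1:
        raise ValueError("segments_per_subject must be >= 1")
    total = n_subjects * segments_per_subject
    if not 0 <= unfit_segments <= total:
        raise ValueError("unfit_segments must lie in [0, total segments]")
    sampler = bp_sampler or default_bp_sampler
    morph = feature_bp_map or default_morphology_map
    rng = np.random.default_rng(seed)
    unfit_idx = set(
        rng.choice(total, size=unfit_segments, replace=False).tolist()
        if unfit_segments
        else []
    )

    records: list[PPGRecord] = []
    truths: dict[tuple[str, str], GroundTruth] = {}
    rows = []
    flat = 0
    for i in range(n_subjects):
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        sid = f"S{i + 1:04d}"
        sbp, dbp, age, gender = sampler(sub_rng)
        if not sbp > dbp:
            raise ValueError(
                f"bp_sampler produced SBP <= DBP for subject {sid}: {sbp} <= {dbp}"
            )
        sbp_ref = sbp + sub_rng.normal(0.0, label_noise_sd)
        dbp_ref = dbp + sub_rng.normal(0.0, label_noise_sd)
        if sbp_ref <= dbp_ref:
            sbp_ref = dbp_ref + 1.0
        for s in range(segments_per_subject):
            seg = str(s + 1)
            cfg = morph(sbp, dbp, rng=sub_rng, jitter_scale=jitter_scale)
            record, truth = generate_record(
                cfg,
                noise_config,
                fs=fs,
                duration=duration,
                seed=sub_rng,
                subject_id=sid,
                segment_id=seg,
            )
            if flat in unfit_idx:
                record = make_unfit(record)
                truth.beats = []  # landmarks no longer valid
            truth.sbp = sbp_ref
            truth.dbp = dbp_ref
            truth.bp_map_coefficients = dict(BP_MAP_COEFFICIENTS)
            records.append(record)
            truths[(sid, seg)] = truth
            flat += 1
        rows.append(
            {
                "subject_id": sid,
                "sex": gender,
                "age": round(age, 1),
                "height": round(float(np.clip(sub_rng.normal(161, 8), 140, 190)), 1),
                "weight": round(float(np.clip(sub_rng.normal(60, 11), 35, 110)), 1),
                "sbp": round(sbp_ref, 2),
                "dbp": round(dbp_ref, 2),
            }
        )
    table = pd.DataFrame(rows)
    table["map"] = (2.0 * table["dbp"] + table["sbp"]) / 3.0
    return records, table, truths


def write_cohort(records: Sequence[PPGRecord], table: pd.DataFrame, out_dir) -> None:
    """Write segments as ``<subject>_<segment>.txt`` plus ``subjects.csv``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    from .ingest import write_record

    for rec in records:
        write_record(rec, os.path.join(out_dir, f"{rec.subject_id}_{rec.segment_id}.txt"))
    table.drop(columns=["map"], errors="ignore").to_csv(
        os.path.join(out_dir, "subjects.csv"), index=False
    )
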