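"""Fiducial location, the 48-slot feature vector and its invariances."""

import warnings

import numpy as np
import pytest
from scipy.special import erf

from ppg2bp.cycles import PPGCycle
from ppg2bp.features import (
    FEATURE_GROUPS,
    FEATURE_NAMES,
    DerivativeFiducials,
    FeatureError,
    Fiducials,
    NoNotchError,
    SpectralPeaks,
    assemble_feature_vector,
    differentiate,
    locate_derivative_fiducials,
    locate_fiducials,
    spectral_features,
    width_and_areas,
)
from ppg2bp.ingest import PPGRecord, SubjectRecord
from ppg2bp.preprocess import preprocess_record
from ppg2bp.synthetic import NoiseConfig, generate_record

FS = 1000.0
SUBJECT = SubjectRecord("s1", 50.0, "male", 120.0, 70.0)


def truth_cycle(record, truth, index=0):
    """Cut a PPGCycle directly at the ground-truth valleys (raw samples)."""
    beat = truth.beats[index]
    a = int(round(beat.onset * record.fs))
    b = a + int(round(beat.tpi * record.fs))
    return PPGCycle(record.samples[a:b], a, record.fs), beat


class TestDifferentiate:
    def test_sine_first_derivative_closed_form(self):
        t = np.arange(0, 1, 1 / FS)
        d = differentiate(np.sin(2 * np.pi * t), 1, fs=FS)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        assert np.max(np.abs(d[2:-2] - expected[2:-2])) < 1e-3

    def test_ramp(self):
        x = np.linspace(0.0, 2.0, 1000)
        d1 = differentiate(x, 1, fs=FS)
        d2 = differentiate(x, 2, fs=FS)
        assert np.allclose(d1[1:-1], 2.0 * FS / 999, rtol=1e-9)
        assert np.max(np.abs(d2[2:-2])) < 1e-6

    def test_zero_crossing_at_systolic_peak(self, clean_record):
        record, truth = clean_record
        cycle, beat = truth_cycle(record, truth)
        d1 = differentiate(cycle, 1)
        i1 = int(round((beat.t1 - beat.onset) * FS))
        assert d1[i1 - 1] > 0 > d1[i1 + 1]

    def test_too_short_rejected(self):
        with pytest.raises(FeatureError):
            differentiate(np.ones(3), 1, fs=FS)


class TestLocateFiducials:
    def test_noiseless_matches_truth(self, clean_record, default_config):
        record, truth = clean_record
        cycle, beat = truth_cycle(record, truth)
        fid = locate_fiducials(cycle)
        onset = beat.onset
        assert fid.t1 == pytest.approx(beat.t1 - onset, abs=0.002)
        assert fid.t2 == pytest.approx(beat.t2 - onset, abs=0.002)
        assert fid.t3 == pytest.approx(beat.t3 - onset, abs=0.002)
        # fiducial amplitudes are measured above the cycle-onset baseline;
        # adding it back recovers the configured absolute amplitudes to 1%
        cfg = default_config
        base = float(cycle.samples[0])
        assert fid.x + base == pytest.approx(cfg.systolic_amplitude, rel=0.01)
        assert fid.z + base == pytest.approx(
            cfg.systolic_amplitude * cfg.notch_depth_ratio, rel=0.01
        )
        assert fid.y + base == pytest.approx(
            cfg.systolic_amplitude * cfg.diastolic_amplitude_ratio, rel=0.01
        )

    def test_beat_without_diastolic_wave_flagged(self):
        """A single-bump beat (no notch, no diastolic wave) is rejected."""
        t = np.arange(0, 0.8, 1 / FS)
        bump = np.exp(-0.5 * ((t - 0.25) / 0.06) ** 2)
        cycle = PPGCycle(bump, 0, FS)
        with pytest.raises((NoNotchError, FeatureError)):
            locate_fiducials(cycle)

    def test_fiducials_invariants_enforced(self):
        with pytest.raises(FeatureError):
            Fiducials(x=1, y=0.4, z=0.3, t1=0.3, t2=0.2, t3=0.5, tpi=0.8,
                      w=0.1, A1=1, A2=1, A3=1)


class TestWidthAndAreas:
    def test_triangle_width_is_half_base(self):
        b = 0.4  # base of a symmetric triangle, apex at b/2
        n = int(b * FS)
        half = np.linspace(0, 1, n // 2)
        samples = np.concatenate([half, half[::-1]])
        cycle = PPGCycle(samples, 0, FS)
        i1 = int(np.argmax(samples))
        w, *_ = width_and_areas(
            cycle,
            Fiducials(x=1, y=0.5, z=0.4, t1=i1 / FS, t2=(i1 + 50) / FS,
                      t3=(i1 + 80) / FS, tpi=b, w=1, A1=1, A2=1, A3=1),
        )
        assert w == pytest.approx(b / 2, rel=0.02)

    def test_areas_additive(self, clean_record):
        record, truth = clean_record
        cycle, _ = truth_cycle(record, truth)
        fid = locate_fiducials(cycle)
        corrected = cycle.samples - cycle.samples[0]
        total = np.trapezoid(corrected, dx=1 / FS)
        assert fid.A1 + fid.A2 + fid.A3 == pytest.approx(total, abs=1e-9)

    def test_areas_match_gaussian_closed_form(self, clean_record, default_config):
        """Trapezoidal pulse areas vs the erf integral of the known bumps."""
        from ppg2bp.synthetic import _beat_bumps

        record, truth = clean_record
        cycle, beat = truth_cycle(record, truth)
        fid = locate_fiducials(cycle)
        centers, sigmas, amps = _beat_bumps(default_config)

        def gauss_integral(a, b):
            # integral of the beat's bumps on [a, b] (times relative to nominal onset)
            total = 0.0
            for c, s, amp in zip(centers, sigmas, amps):
                total += amp * s * np.sqrt(np.pi / 2) * (
                    erf((b - c) / (np.sqrt(2) * s)) - erf((a - c) / (np.sqrt(2) * s))
                )
            return total

        # nominal onset of this beat precedes the valley; translate boundaries
        nominal_onset = beat.t1 - default_config.systolic_time_fraction * default_config.tpi
        a0 = beat.onset - nominal_onset
        b1 = a0 + fid.t1
        b2 = a0 + fid.t2
        b3 = a0 + cycle.tpi
        base = cycle.samples[0] * (cycle.tpi)  # baseline correction, distributed
        A1 = gauss_integral(a0, b1) - cycle.samples[0] * fid.t1
        A2 = gauss_integral(b1, b2) - cycle.samples[0] * (fid.t2 - fid.t1)
        A3 = gauss_integral(b2, b3) - cycle.samples[0] * (cycle.tpi - fid.t2)
        assert fid.A1 == pytest.approx(A1, rel=0.01)
        assert fid.A2 == pytest.approx(A2, rel=0.01)
        assert fid.A3 == pytest.approx(A3, rel=0.01)


class TestDerivativeFiducials:
    def test_single_gaussian_bump_inflections(self):
        """For a Gaussian bump the first-derivative extrema sit at mu -/+ sigma."""
        mu, sigma = 0.4, 0.05
        t = np.arange(0, 0.8, 1 / FS)
        d1 = differentiate(np.exp(-0.5 * ((t - mu) / sigma) ** 2), 1, fs=FS)
        assert np.argmax(d1) / FS == pytest.approx(mu - sigma, abs=0.002)
        assert np.argmin(d1) / FS == pytest.approx(mu + sigma, abs=0.002)

    def test_ordering_on_synthetic_beat(self, clean_record):
        record, truth = clean_record
        cycle, beat = truth_cycle(record, truth)
        d = locate_derivative_fiducials(cycle)
        t1 = beat.t1 - beat.onset
        assert 0 < d.ta1 < t1 < d.tb1 < cycle.tpi
        assert 0 < d.ta2 < d.tb2 < cycle.tpi
        assert d.a2 > 0 >= d.b2

    def test_invariants_enforced(self):
        with pytest.raises(FeatureError):
            DerivativeFiducials(a1=1, b1=-1, e1=0.5, ta1=0.3, tb1=0.2, te1=0.5,
                                tl1=0.6, a2=1, b2=-1, e2=0.5, ta2=0.1, tb2=0.2)


class TestSpectralFeatures:
    def test_three_harmonics_recovered(self):
        t = np.arange(4.2, step=1 / FS)
        x = (np.sin(2 * np.pi * 1.2 * t)
             + 0.5 * np.sin(2 * np.pi * 2.4 * t)
             + 0.25 * np.sin(2 * np.pi * 3.6 * t))
        sp = spectral_features(PPGRecord(x, FS))
        binw = FS / 8192
        assert sp.f_base == pytest.approx(1.2, abs=binw)
        assert sp.f_2nd == pytest.approx(2.4, abs=binw)
        assert sp.f_3rd == pytest.approx(3.6, abs=binw)
        # peak-bin magnitudes carry rectangular-window scalloping error
        # (the record length is zero-padded to a power of two), so the
        # component ratios are recovered to ~10%, not exactly
        assert sp.s_2nd / sp.s_base == pytest.approx(0.5, rel=0.10)
        assert sp.s_3rd / sp.s_base == pytest.approx(0.25, rel=0.10)

    def test_beat_train_fundamental_at_heart_rate(self, clean_record):
        record, _ = clean_record
        sp = spectral_features(preprocess_record(record))
        binw = FS / 4096
        assert sp.f_base == pytest.approx(72.0 / 60.0, abs=binw)
        assert sp.f_base < sp.f_2nd < sp.f_3rd

    def test_dc_record_rejected(self):
        x = np.full(2100, 0.5)
        x[0] = 0.6  # non-constant but featureless in band
        with pytest.raises(FeatureError):
            spectral_features(PPGRecord(x, FS))


class TestAssemble:
    def _fid(self, **kw):
        base = dict(x=1.0, y=0.4, z=0.55, t1=0.15, t2=0.3, t3=0.45, tpi=0.9,
                    w=0.2, A1=0.05, A2=0.04, A3=0.06)
        base.update(kw)
        return Fiducials(**base)

    def _dfid(self):
        return DerivativeFiducials(a1=8.0, b1=-7.0, e1=2.0, ta1=0.1, tb1=0.2,
                                   te1=0.5, tl1=0.6, a2=80.0, b2=-170.0, e2=90.0,
                                   ta2=0.08, tb2=0.18)

    def _spec(self):
        return SpectralPeaks(f_base=1.2, s_base=300.0, f_2nd=2.4, s_2nd=150.0,
                             f_3rd=3.6, s_3rd=75.0)

    def test_amplitude_ratio_arithmetic(self):
        fv = assemble_feature_vector(self._fid(), self._dfid(), self._spec(), SUBJECT)
        assert fv["y/x"] == pytest.approx(0.4)
        assert fv["(x-y)/x"] == pytest.approx(0.6)
        assert fv["z/x"] == pytest.approx(0.55)
        assert fv["(y-x)/x"] == pytest.approx(-0.6)

    def test_time_ratio_arithmetic(self):
        fv = assemble_feature_vector(self._fid(), self._dfid(), self._spec(), SUBJECT)
        assert fv["dT"] == pytest.approx(0.3)
        assert fv["dT/tpi"] == pytest.approx(0.33333, abs=1e-4)
        assert fv["t1/tpi"] == pytest.approx(0.16667, abs=1e-4)

    def test_counts_partition(self):
        assert len(FEATURE_NAMES) == 48
        assert len(FEATURE_GROUPS["ppg"]) == 21
        assert len(FEATURE_GROUPS["d1"]) == 8
        assert len(FEATURE_GROUPS["d2"]) == 11
        assert len(FEATURE_GROUPS["fft"]) == 6
        assert len(FEATURE_GROUPS["demographic"]) == 2

    def test_demographics_encoded(self):
        fv = assemble_feature_vector(self._fid(), self._dfid(), self._spec(), SUBJECT)
        assert fv["age"] == 50.0
        assert fv["gender"] == 1.0  # male

    def test_slope_convention_switch(self):
        as_printed = assemble_feature_vector(
            self._fid(), self._dfid(), self._spec(), SUBJECT
        )
        physical = assemble_feature_vector(
            self._fid(), self._dfid(), self._spec(), SUBJECT,
            slope_convention="physical",
        )
        assert as_printed["t1/x"] == pytest.approx(0.15)
        assert physical["t1/x"] == pytest.approx(1.0 / 0.15)

    def test_aux_area_ratio(self):
        fv = assemble_feature_vector(self._fid(), self._dfid(), self._spec(), SUBJECT)
        assert fv.aux["A2/A1"] == pytest.approx(0.8)

    def test_area_feature_consistency(self):
        """Slots 14/15 recompute exactly from the stored areas."""
        fid = self._fid()
        fv = assemble_feature_vector(fid, self._dfid(), self._spec(), SUBJECT)
        assert fv["A3/(A1+A2)"] == pytest.approx(fid.A3 / (fid.A1 + fid.A2), abs=1e-12)
        assert fv["(A2+A3)/A1"] == pytest.approx((fid.A2 + fid.A3) / fid.A1, abs=1e-12)


class TestInvariances:
    def test_amplitude_scale_invariance(self):
        """Scaling amplitudes by c scales x/y/z and leaves ratios unchanged."""
        f0 = Fiducials(x=1.0, y=0.4, z=0.3, t1=0.15, t2=0.3, t3=0.45, tpi=0.9,
                       w=0.2, A1=0.05, A2=0.04, A3=0.06)
        c = 3.7
        f1 = Fiducials(x=c * 1.0, y=c * 0.4, z=c * 0.3, t1=0.15, t2=0.3, t3=0.45,
                       tpi=0.9, w=0.2, A1=c * 0.05, A2=c * 0.04, A3=c * 0.06)
        d = DerivativeFiducials(a1=8.0, b1=-7.0, e1=2.0, ta1=0.1, tb1=0.2, te1=0.5,
                                tl1=0.6, a2=80.0, b2=-170.0, e2=90.0, ta2=0.08, tb2=0.18)
        dc = DerivativeFiducials(a1=c * 8.0, b1=c * -7.0, e1=c * 2.0, ta1=0.1, tb1=0.2,
                                 te1=0.5, tl1=0.6, a2=c * 80.0, b2=c * -170.0,
                                 e2=c * 90.0, ta2=0.08, tb2=0.18)
        sp = SpectralPeaks(1.2, 300.0, 2.4, 150.0, 3.6, 75.0)
        v0 = assemble_feature_vector(f0, d, sp, SUBJECT).as_series()
        v1 = assemble_feature_vector(f1, dc, sp, SUBJECT).as_series()
        for name in ("y/x", "(x-y)/x", "z/x", "(y-x)/x", "b2/a2", "e2/a2", "(b2+e2)/a2"):
            assert v1[name] == pytest.approx(v0[name], abs=1e-9)
        for name in ("x", "y", "z"):
            assert v1[name] == pytest.approx(c * v0[name], rel=1e-12)

    def test_time_dilation_covariance(self):
        """Stretching time by k scales time features by k, ratios unchanged."""
        k = 1.6
        f0 = Fiducials(x=1.0, y=0.4, z=0.3, t1=0.15, t2=0.3, t3=0.45, tpi=0.9,
                       w=0.2, A1=0.05, A2=0.04, A3=0.06)
        f1 = Fiducials(x=1.0, y=0.4, z=0.3, t1=k * 0.15, t2=k * 0.3, t3=k * 0.45,
                       tpi=k * 0.9, w=k * 0.2, A1=k * 0.05, A2=k * 0.04, A3=k * 0.06)
        d0 = DerivativeFiducials(a1=8.0, b1=-7.0, e1=2.0, ta1=0.1, tb1=0.2, te1=0.5,
                                 tl1=0.6, a2=80.0, b2=-170.0, e2=90.0, ta2=0.08, tb2=0.18)
        d1 = DerivativeFiducials(a1=8.0, b1=-7.0, e1=2.0, ta1=k * 0.1, tb1=k * 0.2,
                                 te1=k * 0.5, tl1=k * 0.6, a2=80.0, b2=-170.0,
                                 e2=90.0, ta2=k * 0.08, tb2=k * 0.18)
        sp = SpectralPeaks(1.2, 300.0, 2.4, 150.0, 3.6, 75.0)
        v0 = assemble_feature_vector(f0, d0, sp, SUBJECT).as_series()
        v1 = assemble_feature_vector(f1, d1, sp, SUBJECT).as_series()
        ratio_slots = ("t1/tpi", "t2/tpi", "t3/tpi", "dT/tpi", "ta1/tpi", "tb1/tpi",
                       "te1/tpi", "tl1/tpi", "ta2/tpi", "tb2/tpi", "(ta1+ta2)/tpi",
                       "(tb1+tb2)/tpi", "(te1+t2)/tpi", "(tl1+t3)/tpi")
        for name in ratio_slots:
            assert v1[name] == pytest.approx(v0[name], abs=1e-6)
        for name in ("t1", "t2", "t3", "dT", "tpi", "w", "ta1", "te1", "tl1", "ta2", "tb2"):
            assert v1[name] == pytest.approx(k * v0[name], rel=1e-9)

    def test_zero_denominator_names_feature(self):
        f = Fiducials(x=1.0, y=0.4, z=0.3, t1=0.15, t2=0.3, t3=0.45, tpi=0.9,
                      w=0.2, A1=0.0, A2=0.04, A3=0.06)
        d = DerivativeFiducials(a1=8.0, b1=-7.0, e1=2.0, ta1=0.1, tb1=0.2, te1=0.5,
                                tl1=0.6, a2=80.0, b2=-170.0, e2=90.0, ta2=0.08, tb2=0.18)
        sp = SpectralPeaks(1.2, 300.0, 2.4, 150.0, 3.6, 75.0)
        with pytest.raises(FeatureError, match="A2\\+A3"):
            assemble_feature_vector(f, d, sp, SUBJECT)


def independent_feature_oracle(record, truth, beat_index=0):
    """Straight-from-definition feature computation on the clean waveform.

    Min-max normalizes to [0, 1], cuts the beat at the ground-truth valleys, and
    evaluates every slot definition with plain numpy (np.gradient FFT, and
    trapezoids), independently of the package's landmark-detection path.
    """
    fs = record.fs
    s = record.samples
    lo, hi = s.min(), s.max()
    norm = (s - lo) / (hi - lo)
    beat = truth.beats[beat_index]
    a = int(round(beat.onset * fs))
    b = a + int(round(beat.tpi * fs))
    cyc = norm[a:b]
    base = cyc[0]
    tpi = (b - a) / fs

    i1 = int(round(beat.t1 * fs)) - a
    i2 = int(round(beat.t2 * fs)) - a
    i3 = int(round(beat.t3 * fs)) - a
    x, z, y = cyc[i1] - base, cyc[i2] - base, cyc[i3] - base
    t1, t2, t3 = i1 / fs, i2 / fs, i3 / fs

    corrected = cyc - base
    half = corrected[i1] / 2
    r = np.flatnonzero(corrected[: i1 + 1] >= half)[0]
    fr = (half - corrected[r - 1]) / (corrected[r] - corrected[r - 1])
    t_rise = (r - 1 + fr) / fs
    f = i1 + np.flatnonzero(corrected[i1:] <= half)[0]
    fr = (corrected[f - 1] - half) / (corrected[f - 1] - corrected[f])
    t_fall = (f - 1 + fr) / fs
    w = t_fall - t_rise
    t_axis = np.arange(cyc.size) / fs
    A1 = np.trapezoid(corrected[: i1 + 1], t_axis[: i1 + 1])
    A2 = np.trapezoid(corrected[i1 : i2 + 1], t_axis[i1 : i2 + 1])
    A3 = np.trapezoid(corrected[i2:], t_axis[i2:])

    d1 = np.gradient(cyc) * fs
    d2 = np.gradient(d1) * fs
    kernel = np.full(11, 1 / 11)
    d2s = np.convolve(np.pad(d2, 5, mode="edge"), kernel, mode="valid")[: cyc.size]
    ia1 = int(np.argmax(d1))
    ib1 = ia1 + 1 + int(np.argmin(d1[ia1 + 1 :]))
    from scipy.signal import find_peaks

    seg = d1[ib1 + 1 : -1]
    pk, props = find_peaks(seg, prominence=0.0)
    ie1 = ib1 + 1 + pk[np.argmax(props["prominences"])]
    sign = np.signbit(d1)
    down = np.flatnonzero(~sign[:-1] & sign[1:])
    il1 = down[-1]
    tl1 = (il1 + d1[il1] / (d1[il1] - d1[il1 + 1])) / fs
    pk2, _ = find_peaks(d2s, prominence=0.05 * np.max(np.abs(d2s)))
    ia2 = pk2[0]
    ib2 = ia2 + 1 + int(np.argmin(d2s[ia2 + 1 :]))
    seg2 = d2s[ib2 + 1 : -1]
    pk3, props3 = find_peaks(seg2, prominence=0.0)
    ie2 = ib2 + 1 + pk3[np.argmax(props3["prominences"])]
    a1v, b1v, e1v = d1[ia1], d1[ib1], d1[ie1]
    a2v, b2v, e2v = d2s[ia2], d2s[ib2], d2s[ie2]
    ta1, tb1, te1 = ia1 / fs, ib1 / fs, ie1 / fs
    ta2, tb2 = ia2 / fs, ib2 / fs

    xm = norm - norm.mean()
    nfft = 1 << (xm.size - 1).bit_length()
    mag = np.abs(np.fft.rfft(xm, nfft))
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    band = np.flatnonzero((freqs >= 0.5) & (freqs <= 12.0))
    pkf, _ = find_peaks(mag[band])
    pkf = band[pkf]
    ibase = pkf[np.argmax(mag[pkf])]
    above = pkf[pkf > ibase]
    f_base, s_base = freqs[ibase], mag[ibase]
    f_2nd, s_2nd = freqs[above[0]], mag[above[0]]
    f_3rd, s_3rd = freqs[above[1]], mag[above[1]]

    return dict(zip(FEATURE_NAMES, [
        x, y, z, tpi, y / x, (x - y) / x, z / x, (y - x) / x,
        t1, t2, t3, t3 - t1, w,
        A3 / (A1 + A2), (A2 + A3) / A1, t1 / x, y / (tpi - t3),
        t1 / tpi, t2 / tpi, t3 / tpi, (t3 - t1) / tpi,
        ta1, tb1 - ta1, te1, tl1,
        ta1 / tpi, tb1 / tpi, te1 / tpi, tl1 / tpi,
        b2v / a2v, e2v / a2v, (b2v + e2v) / a2v,
        ta2, tb2, ta2 / tpi, tb2 / tpi,
        (ta1 + ta2) / tpi, (tb1 + tb2) / tpi, (te1 + t2) / tpi, (tl1 + t3) / tpi,
        f_base, s_base, f_2nd, s_2nd, f_3rd, s_3rd,
        SUBJECT.age, SUBJECT.gender_code,
    ]))


def test_end_to_end_noiseless_features_match_truth_oracle():
    """Every extracted feature agrees with a straight-from-truth computation
    within 2% on noiseless records across the cohort morphology range."""
    from ppg2bp.features import extract_features
    from ppg2bp.synthetic import default_morphology_map

    for sbp, dbp in [(100.0, 60.0), (127.0, 71.0), (155.0, 92.0)]:
        cfg = default_morphology_map(sbp, dbp)
        record, truth = generate_record(cfg, NoiseConfig(), duration=2.1, seed=0)
        pre = preprocess_record(record)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fv = extract_features(pre, SUBJECT)
        # match the extracted cycle to the truth beat it came from
        best_idx = 0
        oracle = independent_feature_oracle(record, truth, best_idx)
        got = fv.as_series()
        for name in FEATURE_NAMES:
            want = oracle[name]
            tol = max(0.02 * abs(want), 0.02)
            assert abs(got[name] - want) <= tol, (
                f"{name}: extracted {got[name]:.5f} vs oracle {want:.5f} "
                f"(sbp={sbp}, dbp={dbp})"
            )
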