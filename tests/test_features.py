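"""Feature extraction: oracle checks against generator truth and hand
arithmetic, plus ordering/bound invariants."""

import numpy as np
import pandas as pd
import pytest

from afscreen import (
    SimulationConfig,
    bandpass_filter,
    delineate,
    delta_features,
    detect_beats,
    extract_features,
    generate_ecg,
)
from afscreen.features import (
    ECG_FEATURE_NAMES,
    FEATURE_LENGTHS,
    FEATURE_NAMES,
    FeatureVector,
    atrial_band_index,
    beat_level_quantities,
    hrv_summaries,
    p_wave_shape_indices,
    summarize_beats,
    template_correlation_stats,
)
from afscreen.preprocess import InsufficientDataError
from afscreen.records import BeatAnnotation, ECGRecord, LEADS9

from conftest import make_profile, synthetic_beat_record


def _delineated(record):
    filtered = bandpass_filter(record)
    r = detect_beats(filtered)
    return filtered, delineate(filtered, r)


class TestBeatLevel:
    def test_pr_interval_matches_constructed_160ms(self):
        rec = synthetic_beat_record(pr_ms=160.0)
        filtered, ann = _delineated(rec)
        table = beat_level_quantities(filtered, ann)
        assert np.all(np.abs(table["pr_ms"] - 160.0) <= 10.0)

    def test_rr_telescopes_to_r_peak_span(self, clean_annotation):
        filtered, ann = clean_annotation
        table = beat_level_quantities(filtered, ann)
        rr = table["rr_ms"].dropna()
        span_ms = (ann.r_peaks[-1] - ann.r_peaks[0]) / ann.fs * 1000.0
        assert ann.quality.all()
        assert abs(rr.sum() - span_ms) < 1e-6

    def test_flagged_beats_excluded(self):
        rec = synthetic_beat_record(skip_p_beats=(2,))
        filtered, ann = _delineated(rec)
        table = beat_level_quantities(filtered, ann)
        assert len(table) == ann.quality.sum() < ann.n_beats

    def test_no_quality_beats_raises(self, clean_annotation):
        filtered, ann = clean_annotation
        bad = BeatAnnotation(
            r_peaks=ann.r_peaks,
            p_onset=ann.p_onset,
            p_peak=ann.p_peak,
            p_offset=ann.p_offset,
            qrs_onset=ann.qrs_onset,
            qrs_offset=ann.qrs_offset,
            t_peak=ann.t_peak,
            t_offset=ann.t_offset,
            quality=np.zeros(ann.n_beats, dtype=bool),
            fs=ann.fs,
        )
        with pytest.raises(InsufficientDataError):
            beat_level_quantities(filtered, bad)


class TestSummaries:
    def test_identical_rows_have_zero_sd(self):
        table = pd.DataFrame({"pr_ms": [160.0, 160.0, 160.0]})
        s = summarize_beats(table)
        assert s["pr_ms_sd"] == 0.0
        assert s["pr_ms_mean"] == s["pr_ms_min"] == s["pr_ms_max"] == 160.0

    def test_two_value_arithmetic(self):
        s = summarize_beats(pd.DataFrame({"x": [100.0, 200.0]}))
        assert s["x_mean"] == 150.0 and s["x_min"] == 100.0 and s["x_max"] == 200.0
        # n-1 denominator: sd of {100, 200} is 50*sqrt(2)
        assert s["x_sd"] == pytest.approx(np.std([100, 200], ddof=1))

    def test_order_contract_random(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"x": rng.normal(size=17)})
        s = summarize_beats(table)
        assert s["x_min"] <= s["x_mean"] <= s["x_max"]
        assert s["x_sd"] >= 0

    def test_empty_table_raises(self):
        with pytest.raises(InsufficientDataError):
            summarize_beats(pd.DataFrame({"x": []}))


class TestPShape:
    def test_symmetric_triangle_symmetry_half(self):
        rec = synthetic_beat_record(p_shape="triangle")
        filtered, ann = _delineated(rec)
        idx = p_wave_shape_indices(filtered, ann)
        assert idx["p_symmetry"] == pytest.approx(0.5, abs=0.08)

    def test_area_scales_linearly_with_amplitude(self):
        small = synthetic_beat_record(p_amp=0.15)
        large = synthetic_beat_record(p_amp=0.30)
        a1 = p_wave_shape_indices(*_delineated(small))["p_area_mvms"]
        a2 = p_wave_shape_indices(*_delineated(large))["p_area_mvms"]
        assert a2 / a1 == pytest.approx(2.0, rel=0.10)

    def test_identical_leads_zero_dispersion(self):
        rec = synthetic_beat_record()
        idx = p_wave_shape_indices(*_delineated(rec))
        assert idx["p_dispersion_ms"] == pytest.approx(0.0, abs=4.0)

    def test_ptf_v1_non_positive(self, small_cohort):
        for p in small_cohort[:4]:
            idx = p_wave_shape_indices(*_delineated(p.ecgs[0]))
            assert np.isnan(idx["ptf_v1_mvms"]) or idx["ptf_v1_mvms"] <= 0

    def test_no_p_waves_gives_missing_markers(self, clean_annotation):
        filtered, ann = clean_annotation
        ann_nop = BeatAnnotation(
            r_peaks=ann.r_peaks,
            p_onset=np.full(ann.n_beats, np.nan),
            p_peak=np.full(ann.n_beats, np.nan),
            p_offset=np.full(ann.n_beats, np.nan),
            qrs_onset=ann.qrs_onset,
            qrs_offset=ann.qrs_offset,
            t_peak=ann.t_peak,
            t_offset=ann.t_offset,
            quality=np.zeros(ann.n_beats, dtype=bool),
            fs=ann.fs,
        )
        idx = p_wave_shape_indices(filtered, ann_nop)
        assert all(np.isnan(v) for v in idx.values())


class TestTemplateCorrelation:
    def test_identical_beats_correlate_perfectly(self):
        rec = synthetic_beat_record()  # beats are bit-identical on the grid
        _, ann = _delineated(rec)
        stats = template_correlation_stats(rec, ann)
        assert stats["tcorr_mean"] == pytest.approx(1.0, abs=1e-9)
        assert stats["tcorr_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_noise_beat_drags_min_below_mean(self):
        rec = synthetic_beat_record()
        filtered, ann = _delineated(rec)
        sig = filtered.signal.copy()
        r = ann.r_peaks[3]
        rng = np.random.default_rng(0)
        sig[:, r - 125:r + 200] = rng.normal(0, 0.3, (9, 325))
        noisy = ECGRecord(signal=sig, fs=filtered.fs, lead_names=LEADS9)
        stats = template_correlation_stats(noisy, ann)
        assert stats["tcorr_min"] < stats["tcorr_mean"]

    def test_bounds_on_random_records(self, small_cohort):
        for p in small_cohort[:5]:
            stats = template_correlation_stats(*_delineated(p.ecgs[0]))
            assert -1.0 <= stats["tcorr_min"] <= stats["tcorr_mean"] <= 1.0

    def test_too_few_beats_raises(self, clean_annotation):
        filtered, ann = clean_annotation
        short = BeatAnnotation(
            r_peaks=ann.r_peaks[:2],
            p_onset=ann.p_onset[:2],
            p_peak=ann.p_peak[:2],
            p_offset=ann.p_offset[:2],
            qrs_onset=ann.qrs_onset[:2],
            qrs_offset=ann.qrs_offset[:2],
            t_peak=ann.t_peak[:2],
            t_offset=ann.t_offset[:2],
            quality=ann.quality[:2],
            fs=ann.fs,
        )
        with pytest.raises(InsufficientDataError):
            template_correlation_stats(filtered, short)


class TestAtrialBand:
    @staticmethod
    def _sine(freqs_amps, fs=500.0):
        t = np.arange(int(10 * fs)) / fs
        y = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
        return ECGRecord(signal=np.tile(y, (9, 1)), fs=fs, lead_names=LEADS9)

    def test_pure_in_band_tone(self):
        assert atrial_band_index(self._sine([(6.0, 1.0)])) > 0.97

    def test_pure_out_of_band_tone(self):
        assert atrial_band_index(self._sine([(20.0, 1.0)])) < 0.03

    def test_equal_mixture_splits_power(self):
        # FFT oracle: equal-amplitude tones carry equal power
        idx = atrial_band_index(self._sine([(6.0, 1.0), (20.0, 1.0)]))
        assert idx == pytest.approx(0.5, abs=0.05)

    def test_zero_power_undefined(self):
        rec = ECGRecord(signal=np.zeros((9, 5000)), lead_names=LEADS9)
        assert np.isnan(atrial_band_index(rec))


class TestHRV:
    @staticmethod
    def _ann_from_rr(rr_ms, fs=500.0):
        r = np.cumsum([0] + list(rr_ms)) / 1000.0 * fs
        n = len(r)
        nanarr = np.full(n, np.nan)
        return BeatAnnotation(
            r_peaks=r.astype(int), p_onset=nanarr, p_peak=nanarr,
            p_offset=nanarr, qrs_onset=nanarr, qrs_offset=nanarr,
            t_peak=nanarr, t_offset=nanarr,
            quality=np.ones(n, dtype=bool), fs=fs,
        )

    def test_constant_rr(self):
        h = hrv_summaries(self._ann_from_rr([1000] * 8))
        assert h["sdnn_ms"] == 0 and h["rmssd_ms"] == 0 and h["pnn50"] == 0
        assert h["mean_hr_bpm"] == pytest.approx(60.0)

    def test_alternating_rr_rmssd(self):
        # closed form: all successive differences are +-200 ms
        h = hrv_summaries(self._ann_from_rr([900, 1100] * 4))
        assert h["rmssd_ms"] == pytest.approx(200.0)
        assert h["pnn50"] == 1.0

    def test_pnn50_bounded(self, small_cohort):
        for p in small_cohort[:5]:
            _, ann = _delineated(p.ecgs[0])
            h = hrv_summaries(ann)
            assert 0.0 <= h["pnn50"] <= 1.0

    def test_too_few_intervals_raise(self):
        with pytest.raises(InsufficientDataError):
            hrv_summaries(self._ann_from_rr([1000, 1000]))


class TestExtract:
    def test_deterministic_and_documented_length(self, clean_annotation):
        filtered, ann = clean_annotation
        a = extract_features(filtered, ann, 60, "female")
        b = extract_features(filtered, ann, 60, "female")
        np.testing.assert_array_equal(a.values, b.values)
        assert len(a.values) == FEATURE_LENGTHS[a.feature_order_version]
        assert a.names == FEATURE_NAMES

    def test_lead_permutation_invariance(self, clean_annotation):
        filtered, ann = clean_annotation
        ref = extract_features(filtered, ann, 60, "female")
        perm = np.array([3, 0, 8, 1, 2, 7, 4, 6, 5])
        rec2 = ECGRecord(
            signal=filtered.signal[perm],
            fs=filtered.fs,
            lead_names=tuple(np.array(LEADS9)[perm]),
        )
        out = extract_features(rec2, ann, 60, "female")
        # lead-labelled features (V1 terminal force, reference-lead blocks)
        # are looked up by label, not position
        np.testing.assert_allclose(ref.values, out.values)

    def test_unknown_version_rejected(self, clean_annotation):
        filtered, ann = clean_annotation
        with pytest.raises(ValueError):
            extract_features(filtered, ann, 60, "female",
                             feature_order_version="9.9")

    def test_bounded_features_respect_bounds(self, small_cohort):
        for p in small_cohort[:6]:
            filtered, ann = _delineated(p.ecgs[0])
            fv = extract_features(filtered, ann, p.age, p.sex)
            assert 0.0 <= fv["atrial_band_index"] <= 1.0
            assert -1.0 <= fv["tcorr_min"] <= fv["tcorr_mean"] <= 1.0
            for name in fv.names:
                if name.endswith("_sd"):
                    assert np.isnan(fv[name]) or fv[name] >= 0


class TestDelta:
    def _pair(self, clean_annotation):
        filtered, ann = clean_annotation
        a = extract_features(filtered, ann, 60, "female", patient_id="P1")
        vals = a.values.copy()
        vals[a.names.index("pr_ms_mean")] += 20.0
        b = FeatureVector(names=a.names, values=vals, patient_id="P1")
        return a, b

    def test_identical_inputs_zero_delta(self, clean_annotation):
        a, _ = self._pair(clean_annotation)
        d = delta_features(a, a, inter_ecg_days=90)
        assert np.all(d.values == 0.0)
        assert d.inter_ecg_days == 90

    def test_directional_difference(self, clean_annotation):
        a, b = self._pair(clean_annotation)
        d = delta_features(a, b)
        assert d.values[d.names.index("pr_ms_mean")] == pytest.approx(20.0)

    def test_antisymmetry(self, clean_annotation):
        a, b = self._pair(clean_annotation)
        fwd = delta_features(a, b).values
        rev = delta_features(b, a).values
        np.testing.assert_allclose(fwd, -rev)

    def test_covariates_taken_from_followup(self, clean_annotation):
        filtered, ann = clean_annotation
        a = extract_features(filtered, ann, 60, "female")
        b = extract_features(filtered, ann, 61, "female")
        d = delta_features(a, b)
        assert d.age == 61.0
        assert d.names == ECG_FEATURE_NAMES

    def test_version_and_patient_guards(self, clean_annotation):
        a, b = self._pair(clean_annotation)
        other = FeatureVector(names=a.names, values=a.values, patient_id="P2")
        with pytest.raises(ValueError):
            delta_features(a, other)
        bad = FeatureVector(
            names=a.names, values=a.values, feature_order_version="0.9"
        )
        with pytest.raises(ValueError):
            delta_features(a, bad)


def test_risk_linked_features_separate_cases_from_controls():
    """With a positive effect size, case feature distributions shift in the
    generator's stated direction (rank test, ~500 patients per arm)."""
    from scipy.stats import mannwhitneyu

    from afscreen import generate_cohort
    from afscreen.pipeline import extract_record_features

    cfg = SimulationConfig(n_patients=1000, prevalence=0.5, seed=21)
    cohort = generate_cohort(cfg)
    rows, labels = [], []
    for p in cohort:  # baseline visit only
        rows.append(extract_record_features(p.ecgs[0], p.age, p.sex).to_series())
        labels.append(p.is_case)
    single = pd.DataFrame(rows).reset_index(drop=True)
    labels = np.asarray(labels)
    cases, ctrls = single[labels], single[~labels]
    for feat in ("p_dur_ms_mean", "pr_ms_mean", "sdnn_ms",
                 "atrial_band_index", "p_dispersion_ms"):
        stat = mannwhitneyu(
            cases[feat].dropna(), ctrls[feat].dropna(), alternative="greater"
        )
        assert stat.pvalue < 0.01, feat
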