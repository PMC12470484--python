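"""Engineered ECG features for AF risk screening.

The single-ECG model consumes a fixed-length, fixed-order vector of
morphology and timing descriptors: beat-level peak amplitudes, conventional
intervals, segment levels and durations (each summarized across beats by
mean / min / max / SD), compact P-wave shape indices, beat-wise correlation
statistics against a per-record median template, a narrow-band (4-9 Hz)
atrial-activity power index computed after ventricular-complex suppression,
concise heart-rate-variability summaries, and age / sex covariates.

The serial model consumes the element-wise difference (follow-up minus
baseline) of the ECG-derived part of the same vector; covariates enter as
their follow-up values, and the inter-ECG interval is carried alongside.

Conventions fixed here for reproducibility: SD uses the n-1 denominator;
missing quantities are encoded as NaN (handled natively by the tree
learner, never silently imputed); times are ms, amplitudes mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import InsufficientDataError, _p_wave
from .records import BeatAnnotation, ECGRecord

FEATURE_ORDER_VERSION = "1.0"

_BEAT_QUANTITIES = (
    # amplitudes (mV)
    "p_amp_mv", "r_amp_mv", "t_amp_mv",
    # conventional intervals (ms)
    "pr_ms", "qrs_ms", "qt_ms", "rr_ms",
    # segment levels (mV)
    "pr_seg_mv", "st_seg_mv",
    # durations (ms)
    "p_dur_ms", "t_dur_ms",
)
_STATS = ("mean", "min", "max", "sd")

_SHAPE_NAMES = ("p_area_mvms", "p_symmetry", "p_dispersion_ms", "ptf_v1_mvms")
_TCORR_NAMES = ("tcorr_mean", "tcorr_min", "tcorr_sd")
_HRV_NAMES = ("sdnn_ms", "rmssd_ms", "pnn50", "mean_hr_bpm")

ECG_FEATURE_NAMES: tuple = tuple(
    f"{q}_{s}" for q in _BEAT_QUANTITIES for s in _STATS
) + _SHAPE_NAMES + _TCORR_NAMES + ("atrial_band_index",) + _HRV_NAMES
COVARIATE_NAMES = ("age", "sex")
FEATURE_NAMES: tuple = ECG_FEATURE_NAMES + COVARIATE_NAMES

#: documented vector length per feature-order version
FEATURE_LENGTHS = {"1.0": len(FEATURE_NAMES)}


@dataclass
class FeatureVector:
    """Fixed-order engineered feature vector for one ECG."""

    names: tuple
    values: np.ndarray
    feature_order_version: str = FEATURE_ORDER_VERSION
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


@dataclass
class DeltaFeatureVector:
    """Follow-up minus baseline differences of the ECG-derived features."""

    names: tuple
    values: np.ndarray
    age: float
    sex: float
    inter_ecg_days: float
    feature_order_version: str = FEATURE_ORDER_VERSION
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")

    def to_series(self) -> pd.Series:
        s = pd.Series(self.values, index=[f"d_{n}" for n in self.names])
        s["age"] = self.age
        s["sex"] = self.sex
        s["inter_ecg_days"] = self.inter_ecg_days
        return s


def _ms(samples: float, fs: float) -> float:
    return 1000.0 * samples / fs


def beat_level_quantities(
    record: ECGRecord, annotation: BeatAnnotation, lead: str = "II"
) -> pd.DataFrame:
    """Per-quality-beat table of amplitudes, intervals, segments, durations.

    One row per beat whose P wave was delineated (``quality=True``); RR is
    the interval to the next detected beat (NaN for the last beat).
    """
    if not annotation.quality.any():
        raise InsufficientDataError("no quality beats to tabulate")
    x = record.lead(lead)
    fs = record.fs
    r = annotation.r_peaks
    rr_all = np.full(len(r), np.nan)
    if len(r) > 1:
        rr_all[:-1] = np.diff(r) / fs * 1000.0

    rows = []
    for i in np.flatnonzero(annotation.quality):
        p_on, p_pk, p_off = annotation.p_onset[i], annotation.p_peak[i], annotation.p_offset[i]
        q_on, q_off = annotation.qrs_onset[i], annotation.qrs_offset[i]
        t_pk, t_off = annotation.t_peak[i], annotation.t_offset[i]
        seg_pr = x[int(p_off):int(q_on)] if q_on > p_off else np.array([np.nan])
        st_hi = min(len(x), int(q_off) + int(0.040 * fs))
        seg_st = x[int(q_off):st_hi] if st_hi > q_off else np.array([np.nan])
        rows.append(
            {
                "p_amp_mv": x[int(p_pk)] if not np.isnan(p_pk) else np.nan,
                "r_amp_mv": x[int(r[i])],
                "t_amp_mv": x[int(t_pk)] if not np.isnan(t_pk) else np.nan,
                "pr_ms": _ms(q_on - p_on, fs),
                "qrs_ms": _ms(q_off - q_on, fs),
                "qt_ms": _ms(t_off - q_on, fs) if not np.isnan(t_off) else np.nan,
                "rr_ms": rr_all[i],
                "pr_seg_mv": float(np.mean(seg_pr)),
                "st_seg_mv": float(np.mean(seg_st)),
                "p_dur_ms": _ms(p_off - p_on, fs),
                "t_dur_ms": (
                    2.0 * _ms(t_off - t_pk, fs)
                    if not (np.isnan(t_off) or np.isnan(t_pk))
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows, columns=list(_BEAT_QUANTITIES))


def summarize_beats(table: pd.DataFrame) -> dict:
    """Summarize each beat-level quantity by mean, min, max and SD (n-1).

    A single observation gives SD = 0; a quantity with no valid
    observations yields NaN for all four summaries.
    """
    if len(table) == 0:
        raise InsufficientDataError("empty beat table")
    out = {}
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            m = mn = mx = sd = np.nan
        else:
            m, mn, mx = float(np.mean(vals)), float(np.min(vals)), float(np.max(vals))
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out[f"{col}_mean"] = m
        out[f"{col}_min"] = mn
        out[f"{col}_max"] = mx
        out[f"{col}_sd"] = sd
    return out


def _mean_beat(x: np.ndarray, r_peaks: np.ndarray, lo_ms: float, hi_ms: float,
               fs: float) -> np.ndarray | None:
    lo = int(round(lo_ms / 1000.0 * fs))
    hi = int(round(hi_ms / 1000.0 * fs))
    wins = [
        x[r + lo:r + hi]
        for r in r_peaks
        if r + lo >= 0 and r + hi <= len(x)
    ]
    if not wins:
        return None
    return np.mean(np.stack(wins), axis=0)


def p_wave_shape_indices(
    record: ECGRecord, annotation: BeatAnnotation, lead: str = "II"
) -> dict:
    """Compact P-wave shape indices.

    * ``p_area_mvms`` — mean rectified area under the P wave (mV*ms);
    * ``p_symmetry`` — peak position as a fraction of P duration (0.5 for a
      symmetric wave);
    * ``p_dispersion_ms`` — spread (max - min) of P duration across leads,
      measured on each lead's R-aligned mean beat;
    * ``ptf_v1_mvms`` — P terminal force in V1: the (negative) area of the
      terminal negative P deflection, <= 0 by convention.

    When no P wave was delineated all indices are NaN (missing marker).
    """
    out = {k: np.nan for k in _SHAPE_NAMES}
    good = np.flatnonzero(annotation.quality)
    if good.size == 0:
        return out
    x = record.lead(lead)
    fs = record.fs

    areas, syms = [], []
    for i in good:
        lo, pk, hi = (int(annotation.p_onset[i]), int(annotation.p_peak[i]),
                      int(annotation.p_offset[i]))
        if hi <= lo:
            continue
        seg = x[lo:hi]
        # local baseline: the wave's own boundary level, so the area is
        # linear in P amplitude and insensitive to record-wide offsets
        base = 0.5 * (seg[0] + seg[-1])
        areas.append(float(np.trapezoid(np.abs(seg - base))) / fs * 1000.0)
        syms.append((pk - lo) / (hi - lo))
    if areas:
        out["p_area_mvms"] = float(np.mean(areas))
        out["p_symmetry"] = float(np.mean(syms))

    # Inter-lead P duration dispersion on R-aligned mean beats.
    durs = []
    for name in record.lead_names:
        mb = _mean_beat(record.lead(name), annotation.r_peaks[good], -300.0,
                        -50.0, fs)
        if mb is None:
            continue
        found = _p_wave(np.abs(mb - np.median(mb)), 0, len(mb), fs, 0.04)
        if found is not None:
            on, _, off, _ = found
            durs.append(_ms(off - on, fs))
    if len(durs) >= 2:
        out["p_dispersion_ms"] = float(np.max(durs) - np.min(durs))

    # P terminal force in V1 (negative area of the terminal deflection).
    if "V1" in record.lead_names:
        mb = _mean_beat(record.lead("V1"), annotation.r_peaks[good], -300.0,
                        -50.0, fs)
        if mb is not None:
            rel = mb - np.median(mb)
            neg = np.minimum(rel, 0.0)
            out["ptf_v1_mvms"] = float(np.trapezoid(neg)) / fs * 1000.0
    return out


def template_correlation_stats(
    record: ECGRecord, annotation: BeatAnnotation, lead: str = "II"
) -> dict:
    """Beat-wise Pearson correlation against the per-record median template.

    Beat windows span [R-250 ms, R+400 ms]; the template is the sample-wise
    median across aligned windows.  Requires >= 3 fully in-bounds beats.
    """
    x = record.lead(lead)
    fs = record.fs
    lo = -int(0.250 * fs)
    hi = int(0.400 * fs)
    wins = [
        x[r + lo:r + hi]
        for r in annotation.r_peaks
        if r + lo >= 0 and r + hi <= len(x)
    ]
    if len(wins) < 3:
        raise InsufficientDataError(
            f"template correlation needs >=3 in-bounds beats, got {len(wins)}"
        )
    mat = np.stack(wins)
    template = np.median(mat, axis=0)
    tc = template - template.mean()
    tnorm = float(np.sqrt(np.sum(tc * tc)))
    corrs = []
    for w in mat:
        wc = w - w.mean()
        denom = tnorm * float(np.sqrt(np.sum(wc * wc)))
        corrs.append(float(np.dot(wc, tc) / denom) if denom > 0 else np.nan)
    corrs = np.asarray(corrs)
    corrs = corrs[~np.isnan(corrs)]
    if corrs.size == 0:
        return {k: np.nan for k in _TCORR_NAMES}
    return {
        "tcorr_mean": float(np.mean(corrs)),
        "tcorr_min": float(np.min(corrs)),
        "tcorr_sd": float(np.std(corrs, ddof=1)) if corrs.size > 1 else 0.0,
    }


def atrial_band_index(
    record: ECGRecord,
    annotation: BeatAnnotation | None = None,
    band: tuple = (4.0, 9.0),
    total_band: tuple = (0.5, 40.0),
    lead: str = "II",
) -> float:
    """Fraction of spectral power in the atrial band (default 4-9 Hz).

    The ventricular complexes are first suppressed by subtracting the
    R-aligned median beat at each beat position (when an annotation with
    >= 3 beats is available), so that the residual spectrum reflects atrial
    rather than ventricular activity.  Welch power in ``band`` is divided
    by power in ``total_band``; NaN if the record carries no power at all.
    """
    x = record.lead(lead).astype(float).copy()
    fs = record.fs
    if annotation is not None and annotation.n_beats >= 3:
        lo = -int(0.350 * fs)
        hi = int(0.450 * fs)
        full = [
            r for r in annotation.r_peaks if r + lo >= 0 and r + hi <= len(x)
        ]
        if len(full) >= 3:
            med = np.median(np.stack([x[r + lo:r + hi] for r in full]), axis=0)
            for r in full:
                x[r + lo:r + hi] -= med
    nper = min(len(x), 2048)
    f, pxx = sps.welch(x, fs=fs, nperseg=nper)
    total = float(np.sum(pxx[(f >= total_band[0]) & (f <= total_band[1])]))
    if total <= 0:
        return np.nan
    in_band = float(np.sum(pxx[(f >= band[0]) & (f <= band[1])]))
    return in_band / total


def hrv_summaries(annotation: BeatAnnotation) -> dict:
    """Concise HRV block: SDNN, RMSSD, pNN50 and mean heart rate."""
    rr = np.diff(annotation.r_peaks) / annotation.fs * 1000.0
    if rr.size < 3:
        raise InsufficientDataError(f"HRV needs >=3 RR intervals, got {rr.size}")
    drr = np.diff(rr)
    return {
        "sdnn_ms": float(np.std(rr, ddof=1)),
        "rmssd_ms": float(np.sqrt(np.mean(drr * drr))),
        "pnn50": float(np.mean(np.abs(drr) > 50.0)),
        "mean_hr_bpm": float(60000.0 / np.mean(rr)),
    }


def extract_features(
    record: ECGRecord,
    annotation: BeatAnnotation,
    age: float,
    sex: str | float,
    feature_order_version: str = FEATURE_ORDER_VERSION,
    patient_id: str = "",
) -> FeatureVector:
    """Assemble the full fixed-order feature vector for one ECG.

    Blocks that cannot be computed (too few beats, no P waves, ...) are
    filled with NaN missing markers rather than imputed.  Lead access is by
    label, so permuting the storage order of leads leaves the vector
    unchanged.
    """
    if feature_order_version not in FEATURE_LENGTHS:
        raise ValueError(
            f"unknown feature_order_version {feature_order_version!r}"
        )
    blocks: dict = {}
    try:
        table = beat_level_quantities(record, annotation)
        blocks.update(summarize_beats(table))
    except InsufficientDataError:
        pass
    blocks.update(p_wave_shape_indices(record, annotation))
    try:
        blocks.update(template_correlation_stats(record, annotation))
    except InsufficientDataError:
        pass
    blocks["atrial_band_index"] = atrial_band_index(record, annotation)
    try:
        blocks.update(hrv_summaries(annotation))
    except InsufficientDataError:
        pass
    sex_code = {"male": 1.0, "female": 0.0}.get(sex, sex)
    blocks["age"] = float(age)
    blocks["sex"] = float(sex_code)
    values = np.array([blocks.get(n, np.nan) for n in FEATURE_NAMES])
    return FeatureVector(
        names=FEATURE_NAMES,
        values=values,
        feature_order_version=feature_order_version,
        patient_id=patient_id,
    )


def delta_features(
    baseline: FeatureVector,
    followup: FeatureVector,
    inter_ecg_days: float | None = None,
) -> DeltaFeatureVector:
    """Element-wise follow-up minus baseline differences of ECG features.

    Covariates (age, sex) are taken from the follow-up visit, not
    differenced.  Both vectors must share the feature-order version and,
    when patient ids are present, the patient.
    """
    if baseline.feature_order_version != followup.feature_order_version:
        raise ValueError(
            "feature_order_version mismatch: "
            f"{baseline.feature_order_version!r} vs "
            f"{followup.feature_order_version!r}"
        )
    if (
        baseline.patient_id
        and followup.patient_id
        and baseline.patient_id != followup.patient_id
    ):
        raise ValueError(
            f"cross-patient pair: {baseline.patient_id!r} vs "
            f"{followup.patient_id!r}"
        )
    if baseline.names != followup.names:
        raise ValueError("feature name mismatch")
    ecg_idx = [baseline.names.index(n) for n in ECG_FEATURE_NAMES]
    diff = followup.values[ecg_idx] - baseline.values[ecg_idx]
    return DeltaFeatureVector(
        names=ECG_FEATURE_NAMES,
        values=diff,
        age=followup["age"],
        sex=followup["sex"],
        inter_ecg_days=float(inter_ecg_days) if inter_ecg_days is not None else np.nan,
        feature_order_version=followup.feature_order_version,
        patient_id=followup.patient_id,
    )
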