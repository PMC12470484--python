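"""Synthetic patient cohorts with paired baseline / follow-up ECG waveforms.

The generator emulates the data a sinus-rhythm AF-risk screen consumes: each
patient carries a latent atrial-remodeling burden (``latent_risk``) that is,
on average, higher in patients who will go on to develop atrial fibrillation
than in controls.  The waveforms themselves are built from an additive
template model — Gaussian bumps for the P, Q, R, S and T deflections placed
beat by beat on a baseline-wandered, noise-added trace — rather than a
dynamical ODE model, so that the per-beat ground-truth fiducials and every
generative parameter are known exactly and can serve as oracles in tests.

Risk-linked parameters (all non-decreasing in ``latent_risk``):

* P-wave duration (atrial conduction slowing),
* inter-lead P duration and amplitude dispersion (heterogeneous conduction),
* PR interval,
* RR variability (SDNN),
* narrow-band 4-9 Hz atrial activity power.

Cases drift further along the same axis between the baseline and follow-up
visit (``progression_rate``), which is the signal the serial-ECG model is
designed to pick up.  Setting ``effect_size`` and ``progression_rate`` to
zero removes all label information from the waveforms, giving a null regime
in which any downstream discrimination must be at chance.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import DEFAULT_FS, LEADS9, ECGRecord, write_record_csv

# Per-lead scaling of the main deflections.  V1 has a biphasic P wave
# (positive then negative terminal portion), which is what makes the
# P-terminal-force-in-V1 feature non-trivial.
_LEAD_R_AMP = {
    "I": 0.65, "II": 1.0, "III": 0.45,
    "V1": 0.35, "V2": 0.7, "V3": 0.95, "V4": 1.1, "V5": 0.95, "V6": 0.8,
}
_LEAD_P_AMP = {
    "I": 0.7, "II": 1.0, "III": 0.5,
    "V1": 0.55, "V2": 0.6, "V3": 0.65, "V4": 0.7, "V5": 0.75, "V6": 0.7,
}
_LEAD_T_AMP = {
    "I": 0.7, "II": 1.0, "III": 0.4,
    "V1": 0.3, "V2": 0.9, "V3": 1.1, "V4": 1.0, "V5": 0.8, "V6": 0.6,
}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Parameters
    ----------
    n_patients : int
        Cohort size (>= 2).
    prevalence : float
        Fraction of patients labelled ``future_AF``, in (0, 1).
    follow_up_days : int
        Days between baseline and follow-up ECG (default 90, i.e. the
        three-month re-screening visit).
    effect_size : float
        Shift of risk-linked generative parameters per unit latent risk, in
        multiples of the within-group between-subject SD.  0 = null regime.
    progression_rate : float
        Additional per-visit drift of risk-linked parameters in cases, in
        the same SD units (applied at the follow-up visit).
    noise_sd : float
        White measurement noise on the waveform, mV.
    stroke_fraction_in_cases : float
        Fraction of cases carrying a prior embolic-stroke history.
    seed : int
        Master seed; identical configs give bit-identical cohorts.
    """

    n_patients: int = 2000
    prevalence: float = 0.10
    follow_up_days: int = 90
    effect_size: float = 1.0
    progression_rate: float = 0.6
    noise_sd: float = 0.02
    stroke_fraction_in_cases: float = 0.51
    seed: int = 0
    fs: float = DEFAULT_FS
    duration_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.n_patients < 2:
            raise ValueError(f"n_patients must be >= 2, got {self.n_patients}")
        if self.follow_up_days <= 0:
            raise ValueError("follow_up_days must be > 0")
        if not (0.0 <= self.stroke_fraction_in_cases <= 1.0):
            raise ValueError("stroke_fraction_in_cases must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PatientProfile:
    """One synthetic patient with longitudinal visit structure."""

    patient_id: str
    age: float
    sex: str  # {"male", "female"}
    latent_risk: float
    label: str  # {"future_AF", "no_AF"}
    stroke_history: bool
    visit_dates: list
    index_af_date: datetime.date | None = None
    ecgs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(
            b <= a for a, b in zip(self.visit_dates[:-1], self.visit_dates[1:])
        ):
            raise ValueError("visit_dates must be strictly increasing")
        if self.stroke_history and self.label != "future_AF":
            raise ValueError("stroke_history requires label == 'future_AF'")

    @property
    def is_case(self) -> bool:
        return self.label == "future_AF"


def _subject_rng(seed: int, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1, patient_index]))


def _visit_rng(seed: int, patient_index: int, visit_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, 2, patient_index, visit_index])
    )


def _patient_index(patient_id: str) -> int:
    return int(patient_id.lstrip("P"))


def risk_linked_params(rng: np.random.Generator, drive: float) -> dict:
    """Draw one visit's generative parameters given the risk drive.

    ``drive`` is the dimensionless risk input (effect_size * latent_risk,
    plus progression in cases at follow-up).  Each risk-linked parameter is
    base + between-subject scatter + slope * drive with a non-negative
    slope, so every parameter is non-decreasing in latent risk when the
    scatter is held fixed.
    """
    z = rng.standard_normal(8)
    return {
        "rr_mean_ms": float(np.clip(1000.0 * 60.0 / (62.0 + 9.0 * z[0]), 600, 1400)),
        "rr_jitter_sd_ms": float(np.clip(22.0 + 7.0 * z[1] + 14.0 * drive, 4.0, 120.0)),
        "pr_ms": float(np.clip(155.0 + 10.0 * z[2] + 12.0 * drive, 110.0, 260.0)),
        "p_dur_ms": float(np.clip(98.0 + 7.0 * z[3] + 11.0 * drive, 60.0, 180.0)),
        "p_amp_mv": float(np.clip(0.16 + 0.02 * z[4], 0.06, 0.30)),
        "p_lead_jitter_ms": float(np.clip(1.0 + 0.5 * z[5] + 4.0 * drive, 0.0, 30.0)),
        "p_amp_dispersion": float(np.clip(0.04 + 0.02 * z[6] + 0.10 * drive, 0.0, 0.8)),
        "atrial_band_amp_mv": float(np.clip(0.004 + 0.009 * drive, 0.0, 0.08)),
        "t_amp_mv": float(np.clip(0.30 + 0.05 * z[7], 0.10, 0.60)),
        "qt_ms": 390.0,
        "qrs_half_ms": 40.0,
        "drive": float(drive),
    }


def _gauss_add(y: np.ndarray, t: np.ndarray, center: float, sigma: float,
               amp: float, fs: float) -> None:
    """Add a Gaussian bump in place, restricted to +-4 sigma for speed."""
    lo = max(0, int((center - 4 * sigma) * fs))
    hi = min(len(t), int((center + 4 * sigma) * fs) + 1)
    if hi <= lo:
        return
    seg = t[lo:hi]
    y[lo:hi] += amp * np.exp(-0.5 * ((seg - center) / sigma) ** 2)


def generate_ecg(
    profile: PatientProfile, visit_index: int, config: SimulationConfig
) -> ECGRecord:
    """Synthesize one 9-lead, 10-s record for a patient visit.

    The record's ``meta`` carries the ground-truth fiducials (in samples)
    and the generative parameter values, which downstream tests use as
    delineation and feature oracles.
    """
    if visit_index >= len(profile.visit_dates):
        raise IndexError(
            f"visit_index {visit_index} out of range for "
            f"{len(profile.visit_dates)} visits"
        )
    pidx = _patient_index(profile.patient_id)
    fs = config.fs
    n = round(config.duration_s * fs)
    t = np.arange(n) / fs

    drive = config.effect_size * profile.latent_risk
    if profile.is_case and visit_index >= 1:
        drive += config.progression_rate * profile.latent_risk * visit_index

    # Subject-level scatter is seeded per patient so that it is identical
    # across visits; only the risk drive (and visit noise) changes.
    params = risk_linked_params(_subject_rng(config.seed, pidx), drive)
    rng = _visit_rng(config.seed, pidx, visit_index)

    # Beat train: jittered RR series covering the record.
    rr_ms = []
    pos_ms = 1000.0 * float(rng.uniform(0.25, 0.7))
    r_times = [pos_ms]
    while True:
        rr = params["rr_mean_ms"] + params["rr_jitter_sd_ms"] * float(
            np.clip(rng.standard_normal(), -2.8, 2.8)
        )
        rr = max(rr, 350.0)
        if r_times[-1] + rr > 1000.0 * config.duration_s - 450.0:
            break
        rr_ms.append(rr)
        r_times.append(r_times[-1] + rr)
    r_times_s = np.asarray(r_times) / 1000.0
    n_beats = len(r_times_s)

    pr_s = params["pr_ms"] / 1000.0
    p_dur_s = params["p_dur_ms"] / 1000.0
    qrs_half_s = params["qrs_half_ms"] / 1000.0

    # Per-lead P modifiers (dispersion of duration and amplitude).
    lead_p_jit = rng.standard_normal(len(LEADS9)) * params["p_lead_jitter_ms"] / 1000.0
    # log-normal multipliers keep every lead's P clearly present while the
    # inter-lead spread still grows with risk
    lead_p_amp = np.exp(
        params["p_amp_dispersion"] * rng.standard_normal(len(LEADS9))
    )
    lead_p_amp = np.clip(lead_p_amp, 0.45, 2.2)

    signal = np.zeros((len(LEADS9), n))

    # Narrow-band atrial activity (4-9 Hz), shared across leads.
    ab = np.zeros(n)
    if params["atrial_band_amp_mv"] > 0:
        freqs = np.linspace(4.5, 8.5, 5)
        phases = rng.uniform(0, 2 * np.pi, len(freqs))
        for f, ph in zip(freqs, phases):
            ab += np.sin(2 * np.pi * f * t + ph)
        ab *= params["atrial_band_amp_mv"] / max(np.std(ab), 1e-12)

    wander_phase = rng.uniform(0, 2 * np.pi)
    wander = 0.06 * np.sin(2 * np.pi * 0.22 * t + wander_phase)

    noise = rng.standard_normal((len(LEADS9), n)) * config.noise_sd

    for li, lead in enumerate(LEADS9):
        y = signal[li]
        ra = _LEAD_R_AMP[lead]
        pa = params["p_amp_mv"] * _LEAD_P_AMP[lead] * lead_p_amp[li]
        ta = params["t_amp_mv"] * _LEAD_T_AMP[lead]
        p_dur_lead = max(p_dur_s + lead_p_jit[li], 0.04)
        for rt in r_times_s:
            qrs_on = rt - qrs_half_s
            p_on = qrs_on - pr_s
            p_center = p_on + p_dur_lead / 2.0
            p_sigma = p_dur_lead / 5.0
            if lead == "V1":
                # Biphasic P: positive initial, negative terminal portion.
                _gauss_add(y, t, p_center - 0.6 * p_sigma, p_sigma * 0.8, pa, fs)
                _gauss_add(y, t, p_center + 1.1 * p_sigma, p_sigma * 0.8, -0.6 * pa, fs)
            else:
                _gauss_add(y, t, p_center, p_sigma, pa, fs)
            # QRS: Q, R, S bumps.
            _gauss_add(y, t, rt - 0.028, 0.005, -0.08 * ra, fs)
            _gauss_add(y, t, rt, 0.010, ra, fs)
            _gauss_add(y, t, rt + 0.028, 0.005, -0.15 * ra, fs)
            # T wave.
            t_center = rt - qrs_half_s + params["qt_ms"] / 1000.0 - 2 * 0.055
            _gauss_add(y, t, t_center, 0.055, ta, fs)
        y += wander + ab + noise[li]

    # Quantize to the acquisition resolution (5 uV).
    q = 0.005
    signal = np.round(signal / q) * q

    r_samp = np.round(r_times_s * fs).astype(int)
    qrs_on = r_times_s - qrs_half_s
    p_on = qrs_on - pr_s
    p_off = p_on + p_dur_s
    meta = {
        "ground_truth": {
            "r_peaks": r_samp,
            "p_onset": p_on * fs,
            "p_peak": (p_on + p_dur_s / 2.0) * fs,
            "p_offset": p_off * fs,
            "qrs_onset": qrs_on * fs,
            "qrs_offset": (r_times_s + qrs_half_s) * fs,
            "t_offset": (qrs_on + params["qt_ms"] / 1000.0) * fs,
            "rr_ms": np.asarray(rr_ms),
            "n_beats": n_beats,
        },
        "params": params,
        "patient_id": profile.patient_id,
        "visit_index": visit_index,
    }
    return ECGRecord(
        signal=signal,
        fs=fs,
        lead_names=LEADS9,
        record_id=f"{profile.patient_id}_v{visit_index}",
        meta=meta,
    )


def generate_cohort(
    config: SimulationConfig, with_ecg: bool = True
) -> list[PatientProfile]:
    """Generate the full synthetic cohort.

    Labels are Bernoulli(prevalence); case latent risk ~ Beta(5, 2) and
    control latent risk ~ Beta(2, 5), giving overlapping but separable risk
    distributions.  Case ages run higher than control ages and cases are
    more often male, mirroring the usual directionality of AF cohorts.
    Each patient gets a baseline visit and one follow-up
    ``follow_up_days`` later; with ``with_ecg=True`` both waveforms are
    synthesized and attached.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_patients
    labels = rng.random(n) < config.prevalence
    risks = np.where(
        labels, rng.beta(5.0, 2.0, size=n), rng.beta(2.0, 5.0, size=n)
    )
    ages = np.where(
        labels,
        rng.normal(65.7, 13.0, size=n),
        rng.normal(56.5, 13.5, size=n),
    )
    ages = np.clip(ages, 18.0, 95.0)
    male_p = np.where(labels, 0.539, 0.469)
    sexes = np.where(rng.random(n) < male_p, "male", "female")
    strokes = labels & (rng.random(n) < config.stroke_fraction_in_cases)

    base_day0 = datetime.date(2016, 1, 1)
    base_offsets = rng.integers(0, 4 * 365, size=n)
    af_gaps = rng.integers(60, 420, size=n)

    cohort: list[PatientProfile] = []
    for i in range(n):
        baseline = base_day0 + datetime.timedelta(days=int(base_offsets[i]))
        followup = baseline + datetime.timedelta(days=config.follow_up_days)
        index_af = None
        if labels[i]:
            index_af = followup + datetime.timedelta(days=int(af_gaps[i]))
        profile = PatientProfile(
            patient_id=f"P{i:06d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            latent_risk=float(risks[i]),
            label="future_AF" if labels[i] else "no_AF",
            stroke_history=bool(strokes[i]),
            visit_dates=[baseline, followup],
            index_af_date=index_af,
        )
        if with_ecg:
            profile.ecgs = [
                generate_ecg(profile, 0, config),
                generate_ecg(profile, 1, config),
            ]
        cohort.append(profile)
    return cohort


def write_cohort(
    cohort: list[PatientProfile], out_dir: str | Path
) -> pd.DataFrame:
    """Write per-record CSVs and a cohort manifest CSV; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort:
        for vi, record in enumerate(p.ecgs):
            path = out_dir / f"{record.record_id}.csv"
            write_record_csv(record, path)
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "age": p.age,
                    "sex": p.sex,
                    "label": p.label,
                    "stroke_history": p.stroke_history,
                    "visit_index": vi,
                    "date": p.visit_dates[vi].isoformat(),
                    "index_af_date": (
                        p.index_af_date.isoformat() if p.index_af_date else ""
                    ),
                    "record_path": path.name,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
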