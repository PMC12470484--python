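"""Shared fixtures: deterministic synthetic profiles, records and cohorts."""

import datetime

import numpy as np
import pytest

from afscreen import (
    ECGRecord,
    LEADS9,
    SimulationConfig,
    bandpass_filter,
    delineate,
    detect_beats,
    generate_cohort,
    generate_ecg,
)
from afscreen.sim import PatientProfile


def make_profile(risk: float = 0.2, patient_id: str = "P000042",
                 label: str = "no_AF", stroke: bool = False) -> PatientProfile:
    return PatientProfile(
        patient_id=patient_id,
        age=60.0,
        sex="female",
        latent_risk=risk,
        label=label,
        stroke_history=stroke,
        visit_dates=[datetime.date(2018, 1, 1), datetime.date(2018, 4, 1)],
        index_af_date=(
            datetime.date(2018, 10, 1) if label == "future_AF" else None
        ),
    )


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Noise-free config used for delineation/feature oracle checks."""
    return SimulationConfig(n_patients=2, seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_record(clean_config):
    """One noise-free moderate-risk record with ground-truth fiducials."""
    return generate_ecg(make_profile(risk=0.2), 0, clean_config)


@pytest.fixture(scope="session")
def clean_annotation(clean_config, clean_record):
    filtered = bandpass_filter(clean_record)
    r = detect_beats(filtered)
    return filtered, delineate(filtered, r)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort with waveforms attached."""
    return generate_cohort(SimulationConfig(n_patients=20, seed=11))


def synthetic_beat_record(
    fs: float = 500.0,
    duration_s: float = 10.0,
    rr_s: float = 1.0,
    pr_ms: float = 160.0,
    p_dur_ms: float = 100.0,
    p_amp: float = 0.2,
    r_amp: float = 1.0,
    t_amp: float = 0.3,
    skip_p_beats: tuple = (),
    p_shape: str = "gauss",
) -> ECGRecord:
    """Hand-built multi-beat record with exactly known timing.

    All nine leads are identical, which makes inter-lead dispersion zero by
    construction.  ``skip_p_beats`` omits the P wave of selected beats;
    ``p_shape='triangle'`` substitutes a symmetric triangular P wave.
    """
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    y = np.zeros(n)
    r_times = np.arange(0.5, duration_s - 0.5, rr_s)
    truth = {"r_peaks": [], "p_onset": [], "p_offset": [], "qrs_onset": []}
    for bi, rt in enumerate(r_times):
        qrs_on = rt - 0.040
        p_on = qrs_on - pr_ms / 1000.0
        p_dur = p_dur_ms / 1000.0
        if bi not in skip_p_beats:
            if p_shape == "triangle":
                tri = 1.0 - np.abs(t - (p_on + p_dur / 2)) / (p_dur / 2)
                y += p_amp * np.clip(tri, 0.0, None)
            else:
                sigma = p_dur / 5.0
                y += p_amp * np.exp(
                    -0.5 * ((t - (p_on + p_dur / 2)) / sigma) ** 2
                )
        y += -0.08 * r_amp * np.exp(-0.5 * ((t - (rt - 0.028)) / 0.005) ** 2)
        y += r_amp * np.exp(-0.5 * ((t - rt) / 0.010) ** 2)
        y += -0.15 * r_amp * np.exp(-0.5 * ((t - (rt + 0.028)) / 0.005) ** 2)
        y += t_amp * np.exp(-0.5 * ((t - (rt + 0.28)) / 0.055) ** 2)
        truth["r_peaks"].append(int(round(rt * fs)))
        truth["p_onset"].append(p_on * fs)
        truth["p_offset"].append((p_on + p_dur) * fs)
        truth["qrs_onset"].append(qrs_on * fs)
    signal = np.tile(y, (9, 1))
    return ECGRecord(
        signal=signal,
        fs=fs,
        lead_names=LEADS9,
        record_id="handmade",
        meta={"ground_truth": {k: np.asarray(v) for k, v in truth.items()}},
    )
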