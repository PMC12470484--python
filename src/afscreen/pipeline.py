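"""End-to-end synthetic screening study.

Wires every stage together: generate a synthetic cohort, preprocess and
delineate each waveform, extract single-ECG and serial delta features,
adjudicate and split at the patient level, train both LightGBM risk
models, select the two prespecified operating points on validation scores,
run the sequential protocol on the held-out test patients, and evaluate
the resulting screening classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    SplitAssignment,
    adjudicate,
    build_serial_pairs,
    patient_record_from_profile,
    split_patients,
)
from .evaluation import auroc, confusion, metrics_from_confusion, subgroup_metrics
from .features import (
    FEATURE_NAMES,
    FeatureVector,
    delta_features,
    extract_features,
)
from .models import AFRiskClassifier, TrainingConfig, train
from .preprocess import bandpass_filter, delineate, detect_beats
from .protocol import ProtocolResult, ScreeningProtocol, results_to_frame
from .sim import PatientProfile, SimulationConfig, generate_cohort
from .thresholds import (
    OperatingPoint,
    sensitivity_band_threshold,
    youden_threshold,
)


def extract_record_features(record, age, sex, patient_id="") -> FeatureVector:
    """Filter, detect, delineate and featurize one raw record."""
    filtered = bandpass_filter(record)
    r_peaks = detect_beats(filtered)
    if r_peaks.size < 2:
        return FeatureVector(
            names=FEATURE_NAMES,
            values=np.concatenate(
                [
                    np.full(len(FEATURE_NAMES) - 2, np.nan),
                    [float(age), 1.0 if sex == "male" else 0.0],
                ]
            ),
            patient_id=patient_id,
        )
    ann = delineate(filtered, r_peaks)
    return extract_features(filtered, ann, age, sex, patient_id=patient_id)


def extract_cohort_features(cohort: list[PatientProfile]):
    """Feature tables for a generated cohort.

    Returns ``(single, single_meta, delta, delta_meta)``: the single-ECG
    feature frame has one row per (patient, visit); the delta frame has
    one row per baseline/follow-up pair.
    """
    single_rows, single_meta = [], []
    delta_rows, delta_meta = [], []
    for p in cohort:
        fvs = []
        for vi, record in enumerate(p.ecgs):
            fv = extract_record_features(record, p.age, p.sex, p.patient_id)
            fvs.append(fv)
            single_rows.append(fv.to_series())
            single_meta.append(
                {
                    "patient_id": p.patient_id,
                    "visit_index": vi,
                    "label": int(p.is_case),
                    "stroke_history": p.stroke_history,
                    "latent_risk": p.latent_risk,
                }
            )
        if len(fvs) >= 2:
            days = (p.visit_dates[1] - p.visit_dates[0]).days
            d = delta_features(fvs[0], fvs[1], inter_ecg_days=days)
            delta_rows.append(d.to_series())
            delta_meta.append(
                {
                    "patient_id": p.patient_id,
                    "label": int(p.is_case),
                    "stroke_history": p.stroke_history,
                    "latent_risk": p.latent_risk,
                }
            )
    single = pd.DataFrame(single_rows).reset_index(drop=True)
    delta = pd.DataFrame(delta_rows).reset_index(drop=True)
    return (
        single,
        pd.DataFrame(single_meta),
        delta,
        pd.DataFrame(delta_meta),
    )


@dataclass
class StudyResult:
    """Everything a screening study produced."""

    sim_config: SimulationConfig
    split: SplitAssignment
    single_model: AFRiskClassifier
    serial_model: AFRiskClassifier
    stage1_point: OperatingPoint
    stage2_point: OperatingPoint
    features_single: pd.DataFrame
    meta_single: pd.DataFrame
    features_delta: pd.DataFrame
    meta_delta: pd.DataFrame
    protocol_results: list = field(default_factory=list)
    predictions: pd.Series | None = None
    labels: pd.Series | None = None
    stroke_mask: pd.Series | None = None
    metrics: dict = field(default_factory=dict)

    def results_frame(self) -> pd.DataFrame:
        return results_to_frame(self.protocol_results)


def run_screening_study(
    sim_config: SimulationConfig,
    training: TrainingConfig | None = None,
    blanking_days: int = 0,
    fractions: tuple = (0.5, 0.25, 0.25),
) -> StudyResult:
    """Run the full two-stage screening study on a synthetic cohort.

    All randomness (cohort, splits, model fitting, hyperparameter search)
    derives from ``sim_config.seed`` / ``training.seed``, so two runs with
    identical configs are bit-identical.
    """
    training = training or TrainingConfig(n_trials=0, seed=sim_config.seed)

    cohort = generate_cohort(sim_config)
    records = [patient_record_from_profile(p) for p in cohort]
    included, _excl = adjudicate(records)
    included_ids = {r.patient_id for r in included}
    has_pair = {
        r.patient_id
        for r in included
        if build_serial_pairs(r, blanking_days=blanking_days)
    }
    cohort = [p for p in cohort if p.patient_id in (included_ids & has_pair)]

    single, meta_s, delta, meta_d = extract_cohort_features(cohort)
    split = split_patients(cohort, fractions=fractions, seed=sim_config.seed)

    single_model = train(
        single, meta_s["label"], meta_s["patient_id"], split, training
    )
    serial_model = train(
        delta, meta_d["label"], meta_d["patient_id"], split, training
    )

    # Operating points on validation scores only; the stage-1 threshold is
    # selected on baseline-visit rows since that is how it is applied.
    val_ids = set(split.ids("validation"))
    base_mask = (
        meta_s["patient_id"].isin(val_ids) & (meta_s["visit_index"] == 0)
    ).to_numpy()
    s1_val = single_model.predict_score(single[base_mask])
    stage1_point = sensitivity_band_threshold(
        s1_val, meta_s["label"].to_numpy()[base_mask]
    )
    d_mask = meta_d["patient_id"].isin(val_ids).to_numpy()
    s2_val = serial_model.predict_score(delta[d_mask])
    stage2_point = youden_threshold(s2_val, meta_d["label"].to_numpy()[d_mask])

    protocol = ScreeningProtocol(
        single_model, serial_model, stage1_point, stage2_point
    )

    # Sequential screening of the held-out test patients.
    test_ids = set(split.ids("test"))
    test_patients = [p for p in cohort if p.patient_id in test_ids]
    base_idx = {
        m["patient_id"]: i
        for i, m in meta_s.iterrows()
        if m["visit_index"] == 0
    }
    # Stage 1 scores in bulk; the serial model is evaluated only for the
    # stage-1 negatives (short-circuit rule).
    base_rows = single.iloc[[base_idx[p.patient_id] for p in test_patients]]
    s1_scores = single_model.predict_score(base_rows)
    stage2_mask = s1_scores < stage1_point.threshold
    delta_idx = {m["patient_id"]: i for i, m in meta_d.iterrows()}
    s2_scores = np.full(len(test_patients), np.nan)
    if stage2_mask.any():
        d_rows = delta.iloc[
            [
                delta_idx[p.patient_id]
                for p, neg in zip(test_patients, stage2_mask)
                if neg
            ]
        ]
        s2_scores[stage2_mask] = serial_model.predict_score(d_rows)
        protocol.n_stage2_calls_ += int(stage2_mask.sum())

    results: list[ProtocolResult] = []
    for p, s1, s2 in zip(test_patients, s1_scores, s2_scores):
        if s1 >= stage1_point.threshold:
            results.append(
                ProtocolResult(
                    patient_id=p.patient_id,
                    stage1_score=float(s1),
                    stage1_decision="positive",
                    final_classification="AF_predicted",
                    disposition="intensive_monitoring",
                    baseline_date=p.visit_dates[0],
                    followup_date=p.visit_dates[1],
                )
            )
        else:
            pos = s2 >= stage2_point.threshold
            results.append(
                ProtocolResult(
                    patient_id=p.patient_id,
                    stage1_score=float(s1),
                    stage1_decision="negative",
                    stage2_score=float(s2),
                    stage2_decision="positive" if pos else "negative",
                    final_classification=(
                        "AF_predicted" if pos else "AF_not_predicted"
                    ),
                    disposition=(
                        "intensive_monitoring" if pos else "routine_screening_6mo"
                    ),
                    baseline_date=p.visit_dates[0],
                    followup_date=p.visit_dates[1],
                )
            )

    pred = pd.Series(
        [float(r.final_classification == "AF_predicted") for r in results],
        index=[r.patient_id for r in results],
    )
    labels = pd.Series(
        [int(p.is_case) for p in test_patients],
        index=[p.patient_id for p in test_patients],
    )
    stroke = pd.Series(
        [p.stroke_history for p in test_patients],
        index=[p.patient_id for p in test_patients],
    )

    cm = confusion(pred.to_numpy().astype(int), labels.to_numpy())
    metrics = {"confusion": cm, **metrics_from_confusion(cm)}

    # Discrimination summaries on the test partition.
    test_base_mask = (
        meta_s["patient_id"].isin(test_ids) & (meta_s["visit_index"] == 0)
    ).to_numpy()
    metrics["auroc_single_test"] = auroc(
        single_model.predict_score(single[test_base_mask]),
        meta_s["label"].to_numpy()[test_base_mask],
    )
    metrics["n_stage2"] = int(stage2_mask.sum())
    metrics["auroc_serial_stage2"] = auroc(
        s2_scores[stage2_mask], labels.to_numpy()[stage2_mask]
    )
    metrics["auroc_single_stage2"] = auroc(
        s1_scores[stage2_mask], labels.to_numpy()[stage2_mask]
    )
    metrics["stroke_subgroup"] = subgroup_metrics(
        pred.to_numpy().astype(int), labels.to_numpy(), stroke.to_numpy()
    )

    return StudyResult(
        sim_config=sim_config,
        split=split,
        single_model=single_model,
        serial_model=serial_model,
        stage1_point=stage1_point,
        stage2_point=stage2_point,
        features_single=single,
        meta_single=meta_s,
        features_delta=delta,
        meta_delta=meta_d,
        protocol_results=results,
        predictions=pred,
        labels=labels,
        stroke_mask=stroke,
        metrics=metrics,
    )
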