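"""Sequential two-visit AF screening decision logic.

Stage 1: the single-ECG model scores the baseline tracing at the
sensitivity-band threshold.  A positive screen refers the patient directly
to intensive (wearable) rhythm monitoring — the serial model is never
evaluated for stage-1 positives.  A negative screen schedules a follow-up
ECG after a short interval; stage 2 then scores the within-patient delta
features with the serial model at the Youden threshold.  A positive at
either stage yields ``AF_predicted`` and the intensive-monitoring
disposition; a double negative returns the patient to routine six-monthly
ECG screening.  Patients lacking the follow-up ECG after a negative stage 1
are flagged incomplete and receive no final classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import DeltaFeatureVector, FeatureVector, delta_features

DISPOSITION_MONITOR = "intensive_monitoring"
DISPOSITION_ROUTINE = "routine_screening_6mo"


@dataclass
class ProtocolResult:
    """Pathway and final classification for one screened patient."""

    patient_id: str
    stage1_score: float
    stage1_decision: str  # {"positive", "negative"}
    stage2_score: float | None = None
    stage2_decision: str | None = None
    final_classification: str | None = None  # {"AF_predicted", "AF_not_predicted"}
    disposition: str | None = None
    complete: bool = True
    baseline_date: object = None
    followup_date: object = None

    def __post_init__(self) -> None:
        stage2_expected = self.stage1_decision == "negative" and self.complete
        if (self.stage2_score is not None) != stage2_expected:
            raise ValueError("stage-2 fields present iff stage 1 negative "
                             "and follow-up available")
        if self.complete:
            positive = self.stage1_decision == "positive" or (
                self.stage2_decision == "positive"
            )
            want = "AF_predicted" if positive else "AF_not_predicted"
            if self.final_classification != want:
                raise ValueError("final classification inconsistent with stages")
            want_disp = DISPOSITION_MONITOR if positive else DISPOSITION_ROUTINE
            if self.disposition != want_disp:
                raise ValueError("disposition inconsistent with classification")


class ScreeningProtocol:
    """Configured two-stage screening engine.

    Parameters
    ----------
    single_model, serial_model
        Fitted :class:`~afscreen.models.AFRiskClassifier` instances (or any
        object with ``predict_score``).
    stage1_point
        Sensitivity-band operating point for the baseline single-ECG stage.
    stage2_point
        Youden operating point for the serial stage.

    The engine is interval-agnostic: it scores whatever baseline/follow-up
    pair the cohort supplies and records the visit dates as metadata.
    ``n_stage2_calls_`` counts serial-model evaluations, which lets the
    short-circuit property (no stage-2 call for stage-1 positives) be
    asserted externally.
    """

    def __init__(self, single_model, serial_model, stage1_point, stage2_point):
        self.single_model = single_model
        self.serial_model = serial_model
        self.stage1_point = stage1_point
        self.stage2_point = stage2_point
        self.n_stage2_calls_ = 0

    # -- single patient --------------------------------------------------
    def run_patient(
        self,
        patient_id: str,
        baseline: FeatureVector,
        followup: FeatureVector | None = None,
        delta: DeltaFeatureVector | None = None,
        baseline_date=None,
        followup_date=None,
        inter_ecg_days: float | None = None,
    ) -> ProtocolResult:
        """Run the sequential decision logic for one patient."""
        x1 = pd.DataFrame([baseline.to_series()])
        s1 = float(self.single_model.predict_score(x1)[0])
        if s1 >= self.stage1_point.threshold:
            return ProtocolResult(
                patient_id=patient_id,
                stage1_score=s1,
                stage1_decision="positive",
                final_classification="AF_predicted",
                disposition=DISPOSITION_MONITOR,
                baseline_date=baseline_date,
                followup_date=followup_date,
            )
        if delta is None:
            if followup is None:
                return ProtocolResult(
                    patient_id=patient_id,
                    stage1_score=s1,
                    stage1_decision="negative",
                    complete=False,
                    baseline_date=baseline_date,
                )
            delta = delta_features(baseline, followup, inter_ecg_days)
        x2 = pd.DataFrame([delta.to_series()])
        s2 = float(self.serial_model.predict_score(x2)[0])
        self.n_stage2_calls_ += 1
        positive = s2 >= self.stage2_point.threshold
        return ProtocolResult(
            patient_id=patient_id,
            stage1_score=s1,
            stage1_decision="negative",
            stage2_score=s2,
            stage2_decision="positive" if positive else "negative",
            final_classification=(
                "AF_predicted" if positive else "AF_not_predicted"
            ),
            disposition=DISPOSITION_MONITOR if positive else DISPOSITION_ROUTINE,
            baseline_date=baseline_date,
            followup_date=followup_date,
        )

    # -- whole cohort ----------------------------------------------------
    def run_cohort(self, patients: list[dict]):
        """Screen a cohort; returns (results, prediction vector).

        ``patients`` is a list of dicts with keys ``patient_id``,
        ``baseline`` (FeatureVector) and optionally ``followup`` /
        ``delta`` / dates.  The prediction vector is a pandas Series
        indexed by patient_id: 1 for ``AF_predicted``, 0 for
        ``AF_not_predicted``, NaN for incomplete pathways.
        """
        ids = [p["patient_id"] for p in patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated patient_id in protocol cohort")
        results = [self.run_patient(**p) for p in patients]
        pred = pd.Series(
            [
                np.nan
                if not r.complete
                else float(r.final_classification == "AF_predicted")
                for r in results
            ],
            index=ids,
            dtype=float,
        )
        return results, pred


def results_to_frame(results: list[ProtocolResult]) -> pd.DataFrame:
    """Tabulate protocol results, one row per patient."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "stage1_score": r.stage1_score,
                "stage1_decision": r.stage1_decision,
                "stage2_score": r.stage2_score,
                "stage2_decision": r.stage2_decision,
                "final_classification": r.final_classification,
                "disposition": r.disposition,
                "complete": r.complete,
                "baseline_date": r.baseline_date,
                "followup_date": r.followup_date,
            }
            for r in results
        ]
    )
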