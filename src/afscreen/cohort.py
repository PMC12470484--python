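"""Cohort assembly: label adjudication, serial-pair construction, splits.

A patient is a case (``future_AF``) when AF was documented on a 12-lead ECG
or Holter and confirmed; the earliest confirmed AF date is the *index AF
date*.  Controls have adjudicated sinus-rhythm ECGs and no AF
documentation.  Exclusion criteria are applied in a fixed order and the
first matching criterion is recorded per excluded patient:

(i)    prior AF diagnosis before the index (earliest) NSR ECG;
(ii)   no NSR ECG before the index AF date;
(iii)  only one NSR ECG available;
(iv)   an AF indication without a positive AF ECG;
(v)    incomplete records preventing adjudication;
(vi)   ECGs that could not be classified as NSR.

Serial pairs are adjacent consecutive NSR ECGs; for cases, both members of
a pair must precede the index AF date by at least the (configurable)
blanking window, so that peri-event tracings never enter the serial model.
All data splits are at the patient level — every ECG of a patient lands in
the same partition — to prevent leakage; a temporal mode assigns patients
by first-ECG date against calendar boundaries.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np

EXCLUSION_REASONS = ("i", "ii", "iii", "iv", "v", "vi")


@dataclass
class ECGMeta:
    """Metadata for one recorded ECG (no waveform)."""

    record_id: str
    date: datetime.date
    rhythm: str | None  # {"NSR", "AF", "other"} or None when unclassifiable


@dataclass
class PatientRecord:
    """Longitudinal patient container used for adjudication and pairing."""

    patient_id: str
    ecgs: list
    af_dates: list = field(default_factory=list)
    age: float | None = None
    sex: str | None = None
    stroke_history: bool = False
    af_indication: bool = False
    complete: bool = True

    @property
    def index_af_date(self) -> datetime.date | None:
        """Earliest documented AF date (None for controls)."""
        return min(self.af_dates) if self.af_dates else None

    @property
    def label(self) -> str:
        return "future_AF" if self.af_dates else "no_AF"

    def nsr_ecgs(self) -> list:
        return sorted(
            (e for e in self.ecgs if e.rhythm == "NSR"), key=lambda e: e.date
        )


def _exclusion_reason(p: PatientRecord) -> str | None:
    nsr = p.nsr_ecgs()
    index_af = p.index_af_date
    # (i) prior AF diagnosis before the index NSR ECG
    if index_af is not None and nsr and index_af < nsr[0].date:
        return "i"
    # (ii) no NSR ECG before the index date
    if index_af is not None and not any(e.date < index_af for e in nsr):
        return "ii"
    # (iii) only one NSR ECG available
    if len(nsr) < 2:
        return "iii"
    # (iv) an AF indication without a positive AF ECG
    if p.af_indication and not any(e.rhythm == "AF" for e in p.ecgs):
        return "iv"
    # (v) incomplete records
    if not p.complete or p.age is None or p.sex is None:
        return "v"
    # (vi) unclassifiable rhythms
    if any(e.rhythm not in ("NSR", "AF", "other") for e in p.ecgs):
        return "vi"
    return None


def adjudicate(patients: list) -> tuple[list, dict]:
    """Apply the exclusion criteria in order.

    Returns ``(included, exclusions)`` where ``exclusions`` maps each
    excluded patient_id to its first matching criterion in {i..vi}.
    A missing rhythm call is an exclusion (criterion vi via the rhythm
    check, or ii/iii when it starves the NSR count), never an exception.
    The decision for each patient depends only on that patient's record,
    so input order cannot change inclusion.
    """
    included: list = []
    exclusions: dict = {}
    for p in patients:
        reason = _exclusion_reason(p)
        if reason is None:
            included.append(p)
        else:
            exclusions[p.patient_id] = reason
    return included, exclusions


def build_serial_pairs(
    patient: PatientRecord, blanking_days: int = 0
) -> list[tuple]:
    """Adjacent consecutive NSR ECG pairs eligible for the serial stage.

    Each pair is ``(baseline: ECGMeta, followup: ECGMeta, interval_days)``
    with baseline date strictly before follow-up date.  For cases, both
    ECGs must precede ``index_af_date`` minus ``blanking_days``.
    """
    nsr = patient.nsr_ecgs()
    index_af = patient.index_af_date
    cutoff = None
    if index_af is not None:
        cutoff = index_af - datetime.timedelta(days=blanking_days)
    pairs = []
    for a, b in zip(nsr[:-1], nsr[1:]):
        if b.date <= a.date:
            continue
        if cutoff is not None and not (a.date < cutoff and b.date < cutoff):
            continue
        pairs.append((a, b, (b.date - a.date).days))
    return pairs


@dataclass
class SplitAssignment:
    """Patient-level partition into train / validation / test."""

    assignment: dict  # patient_id -> {"train", "validation", "test"}
    split_mode: str
    seed: int | None = None
    boundaries: tuple | None = None

    def ids(self, partition: str) -> list:
        return [p for p, s in self.assignment.items() if s == partition]

    def check_no_leakage(self) -> None:
        parts = {"train": set(), "validation": set(), "test": set()}
        for pid, part in self.assignment.items():
            parts[part].add(pid)
        for a in parts:
            for b in parts:
                if a < b and parts[a] & parts[b]:
                    raise AssertionError(f"patient ids shared between {a} and {b}")


def split_patients(
    patients: list,
    mode: str = "random_patient",
    fractions: tuple = (0.5, 0.25, 0.25),
    seed: int = 0,
    boundaries: tuple | None = None,
) -> SplitAssignment:
    """Partition patients into train/validation/test without leakage.

    ``random_patient`` shuffles patient ids with the given seed and cuts at
    the cumulative fractions.  ``temporal`` assigns by each patient's first
    ECG date: before ``boundaries[0]`` -> train, before ``boundaries[1]``
    -> validation, else test.  Boundaries that empty a partition raise.
    """
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient_id in cohort")
    assignment: dict = {}
    if mode == "random_patient":
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {fractions}")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(ids))
        n = len(ids)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        for rank, idx in enumerate(order):
            if rank < n_train:
                part = "train"
            elif rank < n_train + n_val:
                part = "validation"
            else:
                part = "test"
            assignment[ids[idx]] = part
    elif mode == "temporal":
        if boundaries is None or len(boundaries) != 2:
            raise ValueError("temporal mode needs two boundary dates")
        b1, b2 = boundaries
        for p in patients:
            first = min(e.date for e in p.ecgs) if p.ecgs else min(p.visit_dates)
            if first < b1:
                assignment[p.patient_id] = "train"
            elif first < b2:
                assignment[p.patient_id] = "validation"
            else:
                assignment[p.patient_id] = "test"
        counts = {s: 0 for s in ("train", "validation", "test")}
        for s in assignment.values():
            counts[s] += 1
        if min(counts.values()) == 0:
            raise ValueError(f"temporal boundaries empty a partition: {counts}")
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    split = SplitAssignment(
        assignment=assignment, split_mode=mode, seed=seed, boundaries=boundaries
    )
    split.check_no_leakage()
    return split


def patient_record_from_profile(profile) -> PatientRecord:
    """Build an adjudication-ready PatientRecord from a synthetic profile.

    Synthetic visits are sinus-rhythm recordings; cases carry their
    (post-follow-up) index AF date as documentation.
    """
    ecgs = [
        ECGMeta(
            record_id=f"{profile.patient_id}_v{i}", date=d, rhythm="NSR"
        )
        for i, d in enumerate(profile.visit_dates)
    ]
    af_dates = (
        [profile.index_af_date] if profile.index_af_date is not None else []
    )
    return PatientRecord(
        patient_id=profile.patient_id,
        ecgs=ecgs,
        af_dates=af_dates,
        age=profile.age,
        sex=profile.sex,
        stroke_history=profile.stroke_history,
    )
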