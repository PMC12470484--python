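"""Core waveform containers: multi-lead ECG records and beat annotations.

An :class:`ECGRecord` holds one 10-second, multi-lead tracing in millivolts
with its sampling metadata.  Nine independent leads are used throughout
(I, II, III and V1-V6); the augmented limb leads are linear combinations of
the limb leads and carry no independent information, so they are excluded.
A :class:`BeatAnnotation` holds the per-beat fiducial points (P onset / peak
/ offset, QRS onset / offset, T peak / offset) produced by delineation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The nine independent leads of a standard 12-lead recording.
LEADS9 = ("I", "II", "III", "V1", "V2", "V3", "V4", "V5", "V6")

#: Amplitude resolution of the acquisition system, microvolts per LSB.
DEFAULT_RESOLUTION_UV = 5.0

DEFAULT_FS = 500.0


@dataclass
class ECGRecord:
    """One multi-lead ECG waveform.

    Parameters
    ----------
    signal : ndarray of shape (n_leads, n_samples)
        Waveform in millivolts.
    fs : float
        Sampling frequency in Hz.
    lead_names : tuple of str
        Ordered lead labels, one per signal row.
    resolution_uv : float
        Amplitude quantization step in microvolts.
    record_id : str
        Opaque identifier.
    meta : dict
        Free-form metadata.  Synthetic records carry their ground-truth
        fiducials and generative parameters here.
    """

    signal: np.ndarray
    fs: float = DEFAULT_FS
    lead_names: tuple = LEADS9
    resolution_uv: float = DEFAULT_RESOLUTION_UV
    record_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (leads x samples) array")
        if self.signal.shape[0] != len(self.lead_names):
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.lead_names)} lead names"
            )
        if np.isnan(self.signal).any():
            raise ValueError("signal contains NaN values")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples by label."""
        try:
            idx = self.lead_names.index(name)
        except ValueError as exc:
            raise KeyError(f"lead {name!r} not present in {self.lead_names}") from exc
        return self.signal[idx]

    def validate(self) -> None:
        """Check the full record contract (9 leads, 10 s duration, no NaN)."""
        if self.n_leads != 9:
            raise ValueError(f"expected 9 independent leads, got {self.n_leads}")
        if self.n_samples != round(10 * self.fs):
            raise ValueError(
                f"expected {round(10 * self.fs)} samples (10 s at {self.fs} Hz), "
                f"got {self.n_samples}"
            )


@dataclass
class BeatAnnotation:
    """Per-beat fiducial points, as sample indices (NaN where absent).

    Indices are 0-based; intervals are half-open ``[onset, offset)``.
    ``quality`` flags beats whose P wave could be located reliably; features
    that need a P wave are computed on quality beats only.
    """

    r_peaks: np.ndarray
    p_onset: np.ndarray
    p_peak: np.ndarray
    p_offset: np.ndarray
    qrs_onset: np.ndarray
    qrs_offset: np.ndarray
    t_peak: np.ndarray
    t_offset: np.ndarray
    quality: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        for name in (
            "p_onset",
            "p_peak",
            "p_offset",
            "qrs_onset",
            "qrs_offset",
            "t_peak",
            "t_offset",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.quality = np.asarray(self.quality, dtype=bool)

    @property
    def n_beats(self) -> int:
        return len(self.r_peaks)

    def check_invariants(self, n_samples: int | None = None) -> None:
        """Raise if fiducial ordering or bounds are violated."""
        if np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        with np.errstate(invalid="ignore"):
            has_p = ~np.isnan(self.p_onset)
            bad = has_p & ~(
                (self.p_onset < self.p_offset) & (self.p_offset <= self.qrs_onset)
            )
        if bad.any():
            raise ValueError("P onset < P offset <= QRS onset violated")
        for name in ("p_onset", "qrs_onset", "qrs_offset", "t_offset"):
            arr = getattr(self, name)
            finite = arr[~np.isnan(arr)]
            if finite.size and (finite.min() < 0):
                raise ValueError(f"{name} contains negative indices")
            if n_samples is not None and finite.size and finite.max() >= n_samples:
                raise ValueError(f"{name} exceeds record bounds")

    def to_json(self, path: str | Path) -> None:
        """Serialize to a per-record JSON sidecar."""
        payload = {
            "fs": self.fs,
            "r_peaks": self.r_peaks.tolist(),
            "quality": self.quality.astype(int).tolist(),
        }
        for name in (
            "p_onset",
            "p_peak",
            "p_offset",
            "qrs_onset",
            "qrs_offset",
            "t_peak",
            "t_offset",
        ):
            arr = getattr(self, name)
            payload[name] = [None if np.isnan(v) else float(v) for v in arr]
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "BeatAnnotation":
        payload = json.loads(Path(path).read_text())

        def arr(key):
            return np.array(
                [np.nan if v is None else v for v in payload[key]], dtype=float
            )

        return cls(
            r_peaks=np.asarray(payload["r_peaks"], dtype=int),
            p_onset=arr("p_onset"),
            p_peak=arr("p_peak"),
            p_offset=arr("p_offset"),
            qrs_onset=arr("qrs_onset"),
            qrs_offset=arr("qrs_offset"),
            t_peak=arr("t_peak"),
            t_offset=arr("t_offset"),
            quality=np.asarray(payload["quality"], dtype=bool),
            fs=payload["fs"],
        )


def write_record_csv(record: ECGRecord, path: str | Path) -> None:
    """Write one record as CSV: columns = leads, rows = samples (mV)."""
    df = pd.DataFrame(record.signal.T, columns=list(record.lead_names))
    df.to_csv(path, index=False, float_format="%.3f")


def read_record_csv(
    path: str | Path,
    fs: float = DEFAULT_FS,
    resolution_uv: float = DEFAULT_RESOLUTION_UV,
    record_id: str = "",
) -> ECGRecord:
    """Read a record written by :func:`write_record_csv`."""
    df = pd.read_csv(path)
    return ECGRecord(
        signal=df.to_numpy().T,
        fs=fs,
        lead_names=tuple(df.columns),
        resolution_uv=resolution_uv,
        record_id=record_id or Path(path).stem,
    )
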