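"""On-disk formats for multi-channel records, feature tables and reports.

A record is stored as a comma-delimited text table with one row per sample
(``time_s, ecg, ppg, icg``) plus a JSON sidecar (same path with a ``.json``
suffix) carrying the sampling rate, subject id, per-minute blood-pressure
labels and, for synthetic records, the ground-truth fiducials.  Round trips
are lossless: samples are written with 17 significant digits, enough to
reproduce any IEEE-754 double exactly.

Time is stored in seconds; all in-memory indexing is 0-based samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = ("ecg", "ppg", "icg")

__all__ = [
    "CHANNELS",
    "BPLabel",
    "GroundTruth",
    "SignalRecord",
    "SidecarMissingError",
    "RecordFormatError",
    "FeatureTableError",
    "write_record",
    "read_record",
    "write_feature_table",
    "read_feature_table",
]


class SidecarMissingError(FileNotFoundError):
    """The JSON sidecar that carries record metadata is absent."""


class RecordFormatError(ValueError):
    """The on-disk record violates the SignalRecord contract."""


class FeatureTableError(ValueError):
    """Malformed feature table (e.g. duplicate feature names)."""


@dataclass
class BPLabel:
    """One reference-BP interval: [start_s, end_s) with its cuff reading."""

    start_s: float
    end_s: float
    sbp: float
    dbp: float
    stage: int = 0
    activity: str = ""

    def validate(self) -> None:
        if not self.end_s > self.start_s:
            raise RecordFormatError(
                f"BP label interval empty: [{self.start_s}, {self.end_s})"
            )
        if not self.sbp > self.dbp:
            raise RecordFormatError(
                f"SBP ({self.sbp}) must exceed DBP ({self.dbp})"
            )


# Per-beat fiducial fields, in intra-beat order for ECG / PPG / ICG.
FIDUCIAL_FIELDS = ("q", "r", "s", "p", "dmax", "b", "c", "x")


@dataclass
class GroundTruth:
    """Known per-beat fiducial indices and beat-level BP of a synthetic record.

    Index arrays are 0-based samples into the record.  ``clean`` holds the
    noise-free channels (not serialized; used as the SNR noise reference and
    by detector-recovery tests).
    """

    q: np.ndarray
    r: np.ndarray
    s: np.ndarray
    p: np.ndarray
    dmax: np.ndarray
    b: np.ndarray
    c: np.ndarray
    x: np.ndarray
    beat_sbp: np.ndarray
    beat_dbp: np.ndarray
    clean: dict[str, np.ndarray] | None = None

    @property
    def n_beats(self) -> int:
        return len(self.r)

    def pat(self, fs: float) -> np.ndarray:
        return (self.dmax - self.q) / fs

    def pep(self, fs: float) -> np.ndarray:
        return (self.b - self.q) / fs

    def ptt(self, fs: float) -> np.ndarray:
        return (self.dmax - self.b) / fs

    def to_jsonable(self) -> dict:
        out = {k: np.asarray(getattr(self, k)).tolist() for k in FIDUCIAL_FIELDS}
        out["beat_sbp"] = np.asarray(self.beat_sbp).tolist()
        out["beat_dbp"] = np.asarray(self.beat_dbp).tolist()
        return out

    @classmethod
    def from_jsonable(cls, d: dict) -> "GroundTruth":
        kw = {k: np.asarray(d[k], dtype=np.int64) for k in FIDUCIAL_FIELDS}
        kw["beat_sbp"] = np.asarray(d["beat_sbp"], dtype=float)
        kw["beat_dbp"] = np.asarray(d["beat_dbp"], dtype=float)
        return cls(**kw)


@dataclass
class SignalRecord:
    """One subject-session of synchronized ECG/PPG/ICG samples."""

    subject_id: int
    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    icg: np.ndarray
    bp_labels: list[BPLabel] = field(default_factory=list)
    ground_truth: GroundTruth | None = None

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {"ecg": self.ecg, "ppg": self.ppg, "icg": self.icg}

    def validate(self) -> None:
        if self.fs <= 0:
            raise RecordFormatError(f"fs must be positive, got {self.fs}")
        n = len(self.ecg)
        if len(self.ppg) != n or len(self.icg) != n:
            raise RecordFormatError(
                "channel length mismatch: "
                f"ecg={len(self.ecg)} ppg={len(self.ppg)} icg={len(self.icg)}"
            )
        last_end = -np.inf
        for lab in sorted(self.bp_labels, key=lambda L: L.start_s):
            lab.validate()
            if lab.start_s < last_end:
                raise RecordFormatError("BP label intervals overlap")
            if lab.start_s < 0 or lab.end_s > self.duration_s + 1e-9:
                raise RecordFormatError(
                    f"BP label [{lab.start_s}, {lab.end_s}) outside record "
                    f"duration {self.duration_s:.3f}s"
                )
            last_end = lab.end_s


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_record(record: SignalRecord, path: str | Path) -> Path:
    """Write a record as CSV samples plus a JSON metadata sidecar."""
    record.validate()
    path = Path(path)
    t = np.arange(record.n_samples) / record.fs
    df = pd.DataFrame(
        {"time_s": t, "ecg": record.ecg, "ppg": record.ppg, "icg": record.icg}
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "subject_id": int(record.subject_id),
        "fs": float(record.fs),
        "n_samples": int(record.n_samples),
        "bp_labels": [asdict(lab) for lab in record.bp_labels],
        "ground_truth": (
            record.ground_truth.to_jsonable() if record.ground_truth else None
        ),
    }
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_record(path: str | Path) -> SignalRecord:
    """Read a record written by :func:`write_record`; validates invariants."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SidecarMissingError(
            f"missing metadata sidecar: expected {sidecar}"
        )
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time_s", "ecg", "ppg", "icg"]
    if list(df.columns) != expected:
        raise RecordFormatError(
            f"record columns {list(df.columns)} != {expected}"
        )
    if df.isna().any().any():
        raise RecordFormatError("record contains missing samples (ragged rows?)")
    t = df["time_s"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise RecordFormatError("time column is not strictly increasing")
    gt = meta.get("ground_truth")
    record = SignalRecord(
        subject_id=int(meta["subject_id"]),
        fs=float(meta["fs"]),
        ecg=df["ecg"].to_numpy(),
        ppg=df["ppg"].to_numpy(),
        icg=df["icg"].to_numpy(),
        bp_labels=[BPLabel(**lab) for lab in meta.get("bp_labels", [])],
        ground_truth=GroundTruth.from_jsonable(gt) if gt else None,
    )
    record.validate()
    return record


def write_feature_table(rows: pd.DataFrame | list[dict], path: str | Path) -> Path:
    """Write per-segment feature vectors as a header-first CSV."""
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    dupes = df.columns[df.columns.duplicated()].tolist()
    if dupes:
        raise FeatureTableError(f"duplicate feature names: {dupes}")
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    dupes = [c for c in df.columns if c.endswith(".1")]
    if df.columns.duplicated().any() or dupes:
        raise FeatureTableError("duplicate feature names in table header")
    return df
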