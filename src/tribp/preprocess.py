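"""Denoising, voltage-to-impedance conversion, segmentation and SNR.

Filtering follows the acquisition-chain conventions of the study design:
Butterworth high-pass (order 5, 0.5 Hz) removes respiratory baseline drift
from PPG and ICG; Butterworth low-pass removes high-frequency noise from
ICG (order 15, 10 Hz) and ECG (order 15, 40 Hz).  PPG receives no low-pass
because its front end is already band-limited.  All filters are applied
zero-phase (forward-backward) as cascaded second-order sections: fiducial
timing — on which every transit-time interval depends — is then preserved
to within a sample, and high-order designs stay numerically stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .signal_io import BPLabel, SignalRecord

__all__ = [
    "FilterSpec",
    "ImpedanceCalib",
    "Segment",
    "DEFAULT_FILTERS",
    "butterworth_filter",
    "preprocess_record",
    "voltage_to_impedance",
    "segment",
    "segment_count",
    "snr_db",
]


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter design: kind is 'high-pass' or 'low-pass'."""

    kind: str
    order: int
    cutoff_hz: float

    def validate(self, fs: float) -> None:
        if self.kind not in ("high-pass", "low-pass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0.0 < self.cutoff_hz < fs / 2.0:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz outside (0, Nyquist={fs / 2}) Hz"
            )


# Per-channel defaults: drift removal for PPG/ICG, low-pass for ICG/ECG.
DEFAULT_FILTERS: dict[str, tuple[FilterSpec, ...]] = {
    "ppg": (FilterSpec("high-pass", 5, 0.5),),
    "icg": (FilterSpec("high-pass", 5, 0.5), FilterSpec("low-pass", 15, 10.0)),
    "ecg": (FilterSpec("low-pass", 15, 40.0),),
}


def butterworth_filter(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth filtering via cascaded second-order sections."""
    spec.validate(fs)
    x = np.asarray(x, dtype=float)
    if len(x) <= 3 * spec.order:
        raise ValueError(
            f"signal too short ({len(x)} samples) for order-{spec.order} filter"
        )
    btype = "highpass" if spec.kind == "high-pass" else "lowpass"
    sos = sps.butter(spec.order, spec.cutoff_hz, btype=btype, fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, x)


def preprocess_record(record: SignalRecord,
                      filters: dict[str, tuple[FilterSpec, ...]] | None = None
                      ) -> SignalRecord:
    """Apply the per-channel default (or given) filter chains to a record."""
    filters = DEFAULT_FILTERS if filters is None else filters
    out = {}
    for name, sig in record.channels.items():
        y = np.asarray(sig, dtype=float)
        for spec in filters.get(name, ()):
            y = butterworth_filter(y, record.fs, spec)
        out[name] = y
    return SignalRecord(
        subject_id=record.subject_id,
        fs=record.fs,
        ecg=out["ecg"],
        ppg=out["ppg"],
        icg=out["icg"],
        bp_labels=list(record.bp_labels),
        ground_truth=record.ground_truth,
    )


@dataclass(frozen=True)
class ImpedanceCalib:
    """ICG calibration: overall module gain A and excitation-current amplitude."""

    gain: float          # dimensionless overall gain A
    i_peak_amp: float    # excitation current amplitude, A

    def validate(self) -> None:
        if self.gain <= 0 or self.i_peak_amp <= 0:
            raise ValueError("calibration gain and current must be positive")


def voltage_to_impedance(vout: float | np.ndarray,
                         calib: ImpedanceCalib) -> float | np.ndarray:
    """Convert the measured ICG voltage to an impedance change (ohms).

    R = Vout / (A · Ipeak): Ohm's law applied to the demodulated ICG output,
    undoing the module gain and the excitation-current amplitude.
    """
    calib.validate()
    return np.asarray(vout, dtype=float) / (calib.gain * calib.i_peak_amp)


@dataclass
class Segment:
    """A windowed slice of the three channels with its reference BP."""

    subject_id: int
    stage: int
    activity: str
    label_index: int
    window_index: int
    start_s: float
    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    icg: np.ndarray
    sbp: float
    dbp: float

    @property
    def start_idx(self) -> int:
        return int(round(self.start_s * self.fs))

    @property
    def n_samples(self) -> int:
        return len(self.ecg)


def segment_count(duration_s: float, window_s: float, step_s: float) -> int:
    """Number of complete half-open windows: floor((T − w)/s) + 1 for T ≥ w."""
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / step_s + 1e-9)) + 1


def segment(record: SignalRecord, window_s: float = 10.0,
            step_s: float = 5.0) -> list[Segment]:
    """Slide a fixed window over each BP-labelled interval of the record.

    Windows are half-open [start, start + window_s), start at multiples of
    ``step_s`` within each labelled interval, and only complete windows are
    kept; each segment inherits the interval's reference SBP/DBP.
    """
    if record.duration_s < window_s:
        raise ValueError(
            f"record ({record.duration_s:.1f}s) shorter than one "
            f"{window_s:.0f}s window"
        )
    win = int(round(window_s * record.fs))
    segs: list[Segment] = []
    for li, lab in enumerate(record.bp_labels):
        n_win = segment_count(lab.end_s - lab.start_s, window_s, step_s)
        for k in range(n_win):
            start_s = lab.start_s + k * step_s
            i0 = int(round(start_s * record.fs))
            segs.append(
                Segment(
                    subject_id=record.subject_id,
                    stage=lab.stage,
                    activity=lab.activity,
                    label_index=li,
                    window_index=k,
                    start_s=start_s,
                    fs=record.fs,
                    ecg=record.ecg[i0:i0 + win],
                    ppg=record.ppg[i0:i0 + win],
                    icg=record.icg[i0:i0 + win],
                    sbp=lab.sbp,
                    dbp=lab.dbp,
                )
            )
    return segs


def snr_db(processed: np.ndarray, noise_reference: np.ndarray) -> float:
    """10·log10(signal power / noise power).

    For synthetic data the noise reference is (noisy − clean); for measured
    data, (raw − filtered).  Zero noise power returns +inf ("clean") rather
    than raising.
    """
    processed = np.asarray(processed, dtype=float)
    noise_reference = np.asarray(noise_reference, dtype=float)
    if processed.shape != noise_reference.shape:
        raise ValueError("processed and noise reference must have equal length")
    p_sig = float(np.mean(processed ** 2))
    p_noise = float(np.mean(noise_reference ** 2))
    if p_noise == 0.0:
        return float("inf")
    return 10.0 * np.log10(p_sig / p_noise)
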