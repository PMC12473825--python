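"""Per-beat key-point delineation: ECG Q/R, PPG valley/peak/dmax, ICG B/C/X.

Cardiac cycles are anchored on ECG R peaks.  Within each cycle:

* Q is the local minimum of the ECG in the 80 ms window preceding R;
* the PPG valley (pulse foot) is the minimum in (R, R + 0.6 s], the peak the
  maximum between that valley and the next one, and dmax the maximum of the
  first difference between valley and peak (the steepest systolic upstroke);
* the ICG C point is the maximum in (R, R + 0.4 s], B the last local minimum
  of the ICG in [R, C) — falling back to the point of maximum upward
  curvature (second difference) when no notch exists — and X the minimum in
  (C, C + 0.4 s].

Ties are always broken toward the earliest sample.  Beats failing the
physiological validity screen (RR, intra-beat ordering, PEP/PAT/PTT bounds)
are flagged invalid rather than dropped, so beat tables stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocess import Segment
from .signal_io import FIDUCIAL_FIELDS, SignalRecord

__all__ = [
    "FiducialSet",
    "detect_r_peaks",
    "detect_q_points",
    "detect_ppg_points",
    "detect_icg_points",
    "assemble_beats",
    "delineate",
    "delineate_record",
    "slice_fiducials",
]

MISSING = -1

# validity screen bounds (seconds); standard resting-adult physiology
RR_BOUNDS = (0.3, 2.0)
PEP_BOUNDS = (0.02, 0.20)
PAT_BOUNDS = (0.05, 0.40)
MIN_VALID_BEATS = 5


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak indices: amplitude-adaptive threshold + 0.3 s refractory period."""
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 or np.ptp(ecg) == 0.0:
        return np.asarray([], dtype=np.int64)
    refractory = max(1, int(round(0.3 * fs)))
    cand, _ = find_peaks(ecg, distance=refractory)
    if len(cand) == 0:
        return np.asarray([], dtype=np.int64)
    # adaptive height: half of the upper candidate amplitude, which separates
    # R spikes from T waves and baseline ripple
    thr = 0.5 * float(np.quantile(ecg[cand], 0.95))
    if thr <= 0.0:
        return np.asarray([], dtype=np.int64)
    peaks, _ = find_peaks(ecg, height=thr, distance=refractory)
    return peaks.astype(np.int64)


def detect_q_points(ecg: np.ndarray, r_peaks: np.ndarray,
                    fs: float) -> np.ndarray:
    """Q = earliest minimum of the ECG in the 80 ms window preceding each R."""
    ecg = np.asarray(ecg, dtype=float)
    win = int(round(0.08 * fs))
    out = np.full(len(r_peaks), MISSING, dtype=np.int64)
    for i, r in enumerate(r_peaks):
        lo = r - win
        if lo < 0 or r <= lo:
            continue
        out[i] = lo + int(np.argmin(ecg[lo:r]))
    return out


def detect_ppg_points(ppg: np.ndarray, fs: float, r_peaks: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per beat: (valley, peak, first-derivative max) indices; -1 if missing."""
    ppg = np.asarray(ppg, dtype=float)
    n = len(ppg)
    nb = len(r_peaks)
    s_idx = np.full(nb, MISSING, dtype=np.int64)
    p_idx = np.full(nb, MISSING, dtype=np.int64)
    d_idx = np.full(nb, MISSING, dtype=np.int64)
    if n < 3:
        return s_idx, p_idx, d_idx
    w = int(round(0.6 * fs))
    for i, r in enumerate(r_peaks):
        lo, hi = r + 1, min(n, r + w + 1)
        if hi - lo < 2:
            continue
        s_idx[i] = lo + int(np.argmin(ppg[lo:hi]))
    dppg = np.diff(ppg)
    rr_med = float(np.median(np.diff(r_peaks))) if nb > 1 else 0.8 * fs
    for i in range(nb):
        s = s_idx[i]
        if s == MISSING:
            continue
        if i + 1 < nb and s_idx[i + 1] != MISSING and s_idx[i + 1] > s:
            upper = int(s_idx[i + 1])
        else:
            upper = min(n, s + int(round(rr_med)))
        if upper - s < 3:
            s_idx[i] = MISSING
            continue
        p = s + int(np.argmax(ppg[s:upper]))
        if p <= s:
            # no rise after the valley: non-alternating sequence
            s_idx[i] = MISSING
            continue
        p_idx[i] = p
        d_idx[i] = s + int(np.argmax(dppg[s:p]))
    return s_idx, p_idx, d_idx


def detect_icg_points(icg: np.ndarray, fs: float, r_peaks: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per beat: (B, C, X) indices on a dZ/dt-like ICG waveform; -1 if missing."""
    icg = np.asarray(icg, dtype=float)
    n = len(icg)
    nb = len(r_peaks)
    b_idx = np.full(nb, MISSING, dtype=np.int64)
    c_idx = np.full(nb, MISSING, dtype=np.int64)
    x_idx = np.full(nb, MISSING, dtype=np.int64)
    w = int(round(0.4 * fs))
    d2 = np.diff(icg, 2) if n > 2 else np.asarray([])
    for i, r in enumerate(r_peaks):
        lo, hi = r + 1, min(n, r + w + 1)
        if hi - lo < 2:
            continue
        c = lo + int(np.argmax(icg[lo:hi]))
        c_idx[i] = c
        # B: last local minimum (zero-slope notch) before the C upstroke
        seg = icg[r:c]
        b = MISSING
        if len(seg) >= 3:
            interior = np.nonzero(
                (seg[1:-1] < seg[:-2]) & (seg[1:-1] <= seg[2:])
            )[0]
            if len(interior):
                b = r + 1 + int(interior[-1])
        if b == MISSING and c - r >= 4:
            # fallback: maximum upward curvature marks the B onset
            lo2 = max(0, r - 1)
            hi2 = min(len(d2), c - 1)
            if hi2 > lo2:
                b = lo2 + 1 + int(np.argmax(d2[lo2:hi2]))
        b_idx[i] = b
        lo3, hi3 = c + 1, min(n, c + w + 1)
        if hi3 - lo3 >= 2:
            x_idx[i] = lo3 + int(np.argmin(icg[lo3:hi3]))
    return b_idx, c_idx, x_idx


@dataclass
class FiducialSet:
    """Aligned per-beat fiducial indices with a validity flag."""

    fs: float
    q: np.ndarray
    r: np.ndarray
    s: np.ndarray
    p: np.ndarray
    dmax: np.ndarray
    b: np.ndarray
    c: np.ndarray
    x: np.ndarray
    valid: np.ndarray

    @property
    def n_beats(self) -> int:
        return len(self.r)

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))

    @property
    def usable(self) -> bool:
        return self.n_valid >= MIN_VALID_BEATS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {k: getattr(self, k) for k in FIDUCIAL_FIELDS} |
            {"valid": self.valid.astype(int)}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fs: float) -> "FiducialSet":
        kw = {k: df[k].to_numpy(dtype=np.int64) for k in FIDUCIAL_FIELDS}
        return cls(fs=fs, valid=df["valid"].to_numpy(dtype=bool), **kw)


def assemble_beats(q: np.ndarray, r: np.ndarray, s: np.ndarray, p: np.ndarray,
                   dmax: np.ndarray, b: np.ndarray, c: np.ndarray,
                   x: np.ndarray, fs: float, n_samples: int) -> FiducialSet:
    """Align detections by R and apply the physiological validity screen."""
    nb = len(r)
    arrays = [np.asarray(a, dtype=np.int64) for a in (q, r, s, p, dmax, b, c, x)]
    q, r, s, p, dmax, b, c, x = arrays
    valid = np.ones(nb, dtype=bool)
    for a in arrays:
        valid &= (a >= 0) & (a < n_samples)
    with np.errstate(invalid="ignore"):
        valid &= (r > q) & (s < dmax) & (dmax < p) & (b < c) & (c < x)
        pep = (b - q) / fs
        pat = (dmax - q) / fs
        valid &= (pep >= PEP_BOUNDS[0]) & (pep <= PEP_BOUNDS[1])
        valid &= (pat >= PAT_BOUNDS[0]) & (pat <= PAT_BOUNDS[1])
        valid &= (pat - pep) > 0
    if nb > 1:
        rr = np.diff(r) / fs
        rr_ok = (rr >= RR_BOUNDS[0]) & (rr <= RR_BOUNDS[1])
        # a beat needs a plausible interval to at least one neighbour
        neigh = np.zeros(nb, dtype=bool)
        neigh[1:] |= rr_ok
        neigh[:-1] |= rr_ok
        valid &= neigh
    return FiducialSet(fs=fs, q=q, r=r, s=s, p=p, dmax=dmax, b=b, c=c, x=x,
                       valid=valid)


def delineate(ecg: np.ndarray, ppg: np.ndarray, icg: np.ndarray,
              fs: float) -> FiducialSet:
    """Run all detectors on preprocessed channels and assemble the beat table."""
    r = detect_r_peaks(ecg, fs)
    q = detect_q_points(ecg, r, fs)
    s, p, dm = detect_ppg_points(ppg, fs, r)
    b, c, x = detect_icg_points(icg, fs, r)
    return assemble_beats(q, r, s, p, dm, b, c, x, fs, len(ecg))


def delineate_record(record: SignalRecord) -> FiducialSet:
    return delineate(record.ecg, record.ppg, record.icg, record.fs)


def slice_fiducials(fid: FiducialSet, start_idx: int, stop_idx: int
                    ) -> FiducialSet:
    """Beats whose fiducials all fall in [start, stop), rebased to the window."""
    arrays = {k: getattr(fid, k) for k in FIDUCIAL_FIELDS}
    stacked = np.vstack(list(arrays.values()))
    inside = np.all((stacked >= start_idx) & (stacked < stop_idx), axis=0)
    out = {k: a[inside] - start_idx for k, a in arrays.items()}
    return FiducialSet(fs=fid.fs, valid=fid.valid[inside].copy(), **out)


def delineate_segment(seg: Segment) -> FiducialSet:
    return delineate(seg.ecg, seg.ppg, seg.icg, seg.fs)
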