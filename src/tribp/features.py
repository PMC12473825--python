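"""Per-segment interval (PAT/PEP/PTT) and pulse-wave-analysis features.

Each usable 10 s segment yields exactly 154 PWA features — 88 from the PPG
channel and 66 from the ICG channel — across four families:

* morphological (per cardiac cycle, averaged over the segment's valid
  beats): timings, amplitudes, widths at 10–90 % of pulse amplitude, areas,
  derivative landmarks and their ratio coefficients;
* statistical (per cycle, averaged): mean, median, SD, variance, max, min,
  range, skewness, kurtosis;
* sequential (whole segment): inter-beat-interval variability (SDNN,
  RMSSD), Poincaré SD1/SD2, sample entropy and approximate entropy;
* frequency-domain (whole segment): the three largest amplitude-spectrum
  peaks (amplitude and frequency), band energy fractions and spectral
  entropy.

Conventions: population (1/N) variance/skewness/kurtosis; entropies use
m = 2, r = 0.2·SD; the FFT is taken on the mean-removed segment without
windowing; width levels are measured relative to the pulse-foot amplitude.
A beat that never crosses a width level is excluded from that feature's
average; a feature with no contributing beats is NaN and the segment is
flagged unusable by the caller.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from scipy.fft import rfft, rfftfreq
from scipy.signal import find_peaks

from .fiducials import MIN_VALID_BEATS, FiducialSet
from .preprocess import Segment

__all__ = [
    "SegmentSkipped",
    "BeatIntervals",
    "WIDTH_LEVELS",
    "ppg_feature_names",
    "icg_feature_names",
    "all_feature_names",
    "compute_intervals",
    "morphological_ppg",
    "morphological_icg",
    "statistical_features",
    "sequential_features",
    "frequency_features",
    "sample_entropy",
    "approximate_entropy",
    "extract_all",
    "METADATA_COLUMNS",
    "INTERVAL_COLUMNS",
]

WIDTH_LEVELS = tuple(range(10, 100, 10))  # 10% .. 90%

METADATA_COLUMNS = ("subject", "stage", "activity", "label_index",
                    "window_index", "sbp", "dbp")
INTERVAL_COLUMNS = ("pat", "pep", "ptt")


class SegmentSkipped(ValueError):
    """Segment cannot yield features (too few valid beats)."""


# ---------------------------------------------------------------------------
# frozen feature-name inventory


def _ppg_morph_names() -> list[str]:
    names = ["cycle", "sys", "dia", "k", "pulse_amp",
             "sys_cycle_ratio", "dia_cycle_ratio", "sys_dia_ratio"]
    names += [f"width_sys_{v}" for v in WIDTH_LEVELS]
    names += [f"width_dia_{v}" for v in WIDTH_LEVELS]
    names += [f"width_total_{v}" for v in WIDTH_LEVELS]
    names += [f"width_ratio_{v}" for v in WIDTH_LEVELS]
    names += ["area_total", "area_sys", "area_dia", "area_sys_dia_ratio",
              "area_norm"]
    names += ["d1_max", "d1_min", "d1_range", "d1_tmax", "d1_tmin"]
    names += ["d2_a", "d2_b", "d2_ba_ratio"]
    names += ["slope_pa_sys", "upslope_mean", "downslope_mean"]
    names += ["pa", "sa", "pa_sa_ratio"]
    assert len(names) == 63
    return names


def _icg_morph_names() -> list[str]:
    names = ["b_amp", "c_amp", "x_amp", "cb_amp_diff", "bc_amp_ratio",
             "rb_time", "rc_time", "rx_time", "lvet", "bc_time", "cx_time",
             "cycle", "lvet_cycle_ratio", "rc_cycle_ratio"]
    names += [f"cwidth_left_{v}" for v in WIDTH_LEVELS]
    names += [f"cwidth_right_{v}" for v in WIDTH_LEVELS]
    names += [f"cwidth_total_{v}" for v in WIDTH_LEVELS]
    assert len(names) == 41
    return names


_STAT_NAMES = ["stat_mean", "stat_median", "stat_std", "stat_var", "stat_max",
               "stat_min", "stat_range", "stat_skew", "stat_kurtosis"]
_SEQ_NAMES = ["sdnn", "rmssd", "sd1", "sd2", "sampen", "apen"]
_FREQ_NAMES = ["fpeak1_amp", "fpeak1_freq", "fpeak2_amp", "fpeak2_freq",
               "fpeak3_amp", "fpeak3_freq", "band_0_2", "band_2_5",
               "band_5_10", "spec_entropy"]


def ppg_feature_names() -> list[str]:
    base = _ppg_morph_names() + _STAT_NAMES + _SEQ_NAMES + _FREQ_NAMES
    return [f"ppg_{n}" for n in base]


def icg_feature_names() -> list[str]:
    base = _icg_morph_names() + _STAT_NAMES + _SEQ_NAMES + _FREQ_NAMES
    return [f"icg_{n}" for n in base]


def all_feature_names() -> list[str]:
    return ppg_feature_names() + icg_feature_names()


assert len(ppg_feature_names()) == 88
assert len(icg_feature_names()) == 66
assert len(all_feature_names()) == 154
assert len(set(all_feature_names())) == 154


# ---------------------------------------------------------------------------
# intervals


@dataclass
class BeatIntervals:
    """Per-beat cardiac timing intervals (seconds) over a segment's valid beats."""

    pat: np.ndarray
    pep: np.ndarray
    ptt: np.ndarray
    lvet: np.ndarray
    cycle: np.ndarray

    @property
    def means(self) -> dict[str, float]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return {
                "pat": float(np.nanmean(self.pat)),
                "pep": float(np.nanmean(self.pep)),
                "ptt": float(np.nanmean(self.ptt)),
                "lvet": float(np.nanmean(self.lvet)),
                "cycle": float(np.nanmean(self.cycle)),
            }


def compute_intervals(fid: FiducialSet, fs: float | None = None
                      ) -> BeatIntervals:
    """PAT = (dmax−Q)/fs, PEP = (B−Q)/fs, PTT = PAT − PEP, LVET = (X−B)/fs.

    Values are taken over valid beats only; Cycle is the R-to-next-R
    interval where the next beat exists.  Raises :class:`SegmentSkipped`
    with the reason when fewer than 5 beats are valid.
    """
    fs = fid.fs if fs is None else fs
    if fid.n_valid < MIN_VALID_BEATS:
        raise SegmentSkipped(
            f"only {fid.n_valid} valid beats (< {MIN_VALID_BEATS})"
        )
    v = fid.valid
    pat = (fid.dmax[v] - fid.q[v]) / fs
    pep = (fid.b[v] - fid.q[v]) / fs
    lvet = (fid.x[v] - fid.b[v]) / fs
    rr_next = np.full(fid.n_beats, np.nan)
    if fid.n_beats > 1:
        rr = np.diff(fid.r) / fs
        rr_next[:-1] = np.where((rr >= 0.3) & (rr <= 2.0), rr, np.nan)
    return BeatIntervals(pat=pat, pep=pep, ptt=pat - pep, lvet=lvet,
                         cycle=rr_next[v])


# ---------------------------------------------------------------------------
# morphological helpers


def _cross_time_rising(y: np.ndarray, level: float) -> float | None:
    """Earliest level-upcrossing time (samples, interpolated) on a rising limb."""
    above = y >= level
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return 0.0
    y0, y1 = y[k - 1], y[k]
    frac = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
    return (k - 1) + float(frac)


def _cross_time_falling(y: np.ndarray, level: float) -> float | None:
    """Latest level-downcrossing time (samples, interpolated) on a falling limb."""
    above = y >= level
    if not above.any():
        return None
    k = len(y) - 1 - int(np.argmax(above[::-1]))  # last index still >= level
    if k == len(y) - 1:
        return float(k)
    y0, y1 = y[k], y[k + 1]
    frac = 0.0 if y1 == y0 else (y0 - level) / (y0 - y1)
    return k + float(frac)


def _nanmean_cols(rows: list[dict[str, float]], names: list[str]
                  ) -> dict[str, float]:
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for n in names:
            vals = np.asarray([row.get(n, np.nan) for row in rows], dtype=float)
            out[n] = float(np.nanmean(vals)) if len(vals) else float("nan")
    return out


def _ppg_beat_windows(fid: FiducialSet, n: int) -> list[tuple[int, int, int, int]]:
    """(s, p, dmax, next_s) for valid beats that have a following valley."""
    wins = []
    for i in range(fid.n_beats):
        if not fid.valid[i]:
            continue
        nxt = None
        for j in range(i + 1, fid.n_beats):
            if fid.s[j] > fid.s[i]:
                nxt = int(fid.s[j])
                break
        if nxt is None or nxt > n:
            continue
        wins.append((int(fid.s[i]), int(fid.p[i]), int(fid.dmax[i]), nxt))
    return wins


def morphological_ppg(ppg: np.ndarray, fid: FiducialSet,
                      fs: float | None = None) -> dict[str, float]:
    """63 morphological PPG features, averaged over the segment's valid beats."""
    fs = fid.fs if fs is None else fs
    names = _ppg_morph_names()
    rows: list[dict[str, float]] = []
    for s, p, dmax, nxt in _ppg_beat_windows(fid, len(ppg)):
        row: dict[str, float] = {}
        pa, sa = float(ppg[p]), float(ppg[s])
        cycle = (nxt - s) / fs
        sys_t = (p - s) / fs
        dia_t = cycle - sys_t
        amp = pa - sa
        if amp <= 0 or sys_t <= 0 or dia_t <= 0:
            continue
        row["cycle"] = cycle
        row["sys"] = sys_t
        row["dia"] = dia_t
        row["k"] = amp / sys_t
        row["pulse_amp"] = amp
        row["sys_cycle_ratio"] = sys_t / cycle
        row["dia_cycle_ratio"] = dia_t / cycle
        row["sys_dia_ratio"] = sys_t / dia_t
        y = ppg[s:nxt + 1] - sa
        kp = p - s
        for lev in WIDTH_LEVELS:
            lv = amp * lev / 100.0
            tr = _cross_time_rising(y[:kp + 1], lv)
            tf = _cross_time_falling(y[kp:], lv)
            if tr is None or tf is None:
                continue
            w_sys = (kp - tr) / fs
            w_dia = tf / fs
            row[f"width_sys_{lev}"] = w_sys
            row[f"width_dia_{lev}"] = w_dia
            row[f"width_total_{lev}"] = w_sys + w_dia
            if w_sys > 0:
                row[f"width_ratio_{lev}"] = w_dia / w_sys
        area_total = float(np.trapezoid(y)) / fs
        area_sys = float(np.trapezoid(y[:kp + 1])) / fs
        area_dia = area_total - area_sys
        row["area_total"] = area_total
        row["area_sys"] = area_sys
        row["area_dia"] = area_dia
        if area_dia != 0:
            row["area_sys_dia_ratio"] = area_sys / area_dia
        row["area_norm"] = area_total / (amp * cycle)
        d1 = np.diff(ppg[s:nxt + 1]) * fs
        if len(d1):
            row["d1_max"] = float(np.max(d1))
            row["d1_min"] = float(np.min(d1))
            row["d1_range"] = row["d1_max"] - row["d1_min"]
            row["d1_tmax"] = float(np.argmax(d1)) / fs
            row["d1_tmin"] = float(np.argmin(d1)) / fs
        if kp >= 3:
            d2 = np.diff(ppg[s:p + 1], 2) * fs * fs
            ia = int(np.argmax(d2))
            a_wave = float(d2[ia])
            b_wave = float(np.min(d2[ia:]))
            row["d2_a"] = a_wave
            row["d2_b"] = b_wave
            if a_wave != 0:
                row["d2_ba_ratio"] = b_wave / a_wave
        row["slope_pa_sys"] = pa / sys_t
        rising = d1[d1 > 0]
        falling = d1[d1 < 0]
        if len(rising):
            row["upslope_mean"] = float(np.mean(rising))
        if len(falling):
            row["downslope_mean"] = float(np.mean(falling))
        row["pa"] = pa
        row["sa"] = sa
        if abs(sa) > 1e-12:
            row["pa_sa_ratio"] = pa / sa
        rows.append(row)
    return _nanmean_cols(rows, names)


def morphological_icg(icg: np.ndarray, fid: FiducialSet,
                      fs: float | None = None) -> dict[str, float]:
    """41 morphological ICG features, averaged over the segment's valid beats."""
    fs = fid.fs if fs is None else fs
    names = _icg_morph_names()
    rows: list[dict[str, float]] = []
    for i in range(fid.n_beats):
        if not fid.valid[i]:
            continue
        r, b, c, x = (int(fid.r[i]), int(fid.b[i]), int(fid.c[i]),
                      int(fid.x[i]))
        if x + 1 > len(icg):
            continue
        row: dict[str, float] = {}
        b_amp, c_amp, x_amp = float(icg[b]), float(icg[c]), float(icg[x])
        row["b_amp"] = b_amp
        row["c_amp"] = c_amp
        row["x_amp"] = x_amp
        row["cb_amp_diff"] = c_amp - b_amp
        if c_amp != 0:
            row["bc_amp_ratio"] = b_amp / c_amp
        row["rb_time"] = (b - r) / fs
        row["rc_time"] = (c - r) / fs
        row["rx_time"] = (x - r) / fs
        row["lvet"] = (x - b) / fs
        row["bc_time"] = (c - b) / fs
        row["cx_time"] = (x - c) / fs
        if i + 1 < fid.n_beats:
            rr = (fid.r[i + 1] - r) / fs
            if 0.3 <= rr <= 2.0:
                row["cycle"] = rr
                row["lvet_cycle_ratio"] = row["lvet"] / rr
                row["rc_cycle_ratio"] = row["rc_time"] / rr
        if c_amp > 0:
            left = icg[b:c + 1]
            right = icg[c:x + 1]
            for lev in WIDTH_LEVELS:
                lv = c_amp * lev / 100.0
                tr = _cross_time_rising(left, lv)
                tf = _cross_time_falling(right, lv)
                if tr is None or tf is None:
                    continue
                wl = ((c - b) - tr) / fs
                wr = tf / fs
                row[f"cwidth_left_{lev}"] = wl
                row[f"cwidth_right_{lev}"] = wr
                row[f"cwidth_total_{lev}"] = wl + wr
        rows.append(row)
    return _nanmean_cols(rows, names)


# ---------------------------------------------------------------------------
# statistical / sequential / frequency families


def statistical_features(sig: np.ndarray,
                         beat_bounds: list[tuple[int, int]]) -> dict[str, float]:
    """The nine summary statistics, computed per beat then averaged.

    Population (1/N) conventions throughout; a zero-variance beat has no
    defined skewness/kurtosis and is excluded from those two averages.
    """
    rows: list[dict[str, float]] = []
    for lo, hi in beat_bounds:
        y = np.asarray(sig[lo:hi], dtype=float)
        if len(y) == 0:
            continue
        row = {
            "stat_mean": float(np.mean(y)),
            "stat_median": float(np.median(y)),
            "stat_std": float(np.std(y)),
            "stat_var": float(np.var(y)),
            "stat_max": float(np.max(y)),
            "stat_min": float(np.min(y)),
        }
        row["stat_range"] = row["stat_max"] - row["stat_min"]
        if np.std(y) > 0:
            row["stat_skew"] = float(sstats.skew(y, bias=True))
            row["stat_kurtosis"] = float(sstats.kurtosis(y, fisher=True,
                                                         bias=True))
        rows.append(row)
    return _nanmean_cols(rows, _STAT_NAMES)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy (template matches exclude self-matches); 0 if degenerate."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        return 0.0
    sd = float(np.std(x))
    if sd == 0:
        warnings.warn("constant series: sample entropy set to 0", stacklevel=2)
        return 0.0
    tol = 0.2 * sd if r is None else r

    def _count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        k = len(templ)
        total = 0
        for i in range(k - 1):
            d = np.max(np.abs(templ[i + 1:] - templ[i]), axis=1)
            total += int(np.sum(d <= tol))
        return total

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return float(-math.log(a / b))


def approximate_entropy(x: np.ndarray, m: int = 2,
                        r: float | None = None) -> float:
    """Approximate entropy (self-matches included); 0 if degenerate."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        return 0.0
    sd = float(np.std(x))
    if sd == 0:
        warnings.warn("constant series: approximate entropy set to 0",
                      stacklevel=2)
        return 0.0
    tol = 0.2 * sd if r is None else r

    def _phi(mm: int) -> float:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        k = len(templ)
        logs = np.empty(k)
        for i in range(k):
            d = np.max(np.abs(templ - templ[i]), axis=1)
            logs[i] = math.log(np.mean(d <= tol))
        return float(np.mean(logs))

    return _phi(m) - _phi(m + 1)


def sequential_features(ibis: np.ndarray) -> dict[str, float]:
    """SDNN, RMSSD, Poincaré SD1/SD2 and the two entropies of an IBI series.

    Population conventions; SD2 follows sqrt(2·SDNN² − SD1²) so the ellipse
    identity SD1² + SD2² = 2·SDNN² holds exactly.
    """
    ibis = np.asarray(ibis, dtype=float)
    out = dict.fromkeys(_SEQ_NAMES, float("nan"))
    if len(ibis) < 2:
        return out
    sdnn = float(np.std(ibis))
    d = np.diff(ibis)
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    sd1 = float(np.sqrt(np.var(d) / 2.0))
    sd2 = float(np.sqrt(max(2.0 * sdnn ** 2 - sd1 ** 2, 0.0)))
    out.update(sdnn=sdnn, rmssd=rmssd, sd1=sd1, sd2=sd2,
               sampen=sample_entropy(ibis), apen=approximate_entropy(ibis))
    return out


def frequency_features(sig: np.ndarray, fs: float) -> dict[str, float]:
    """Amplitude-spectrum features of the mean-removed segment (no window)."""
    sig = np.asarray(sig, dtype=float)
    if len(sig) < int(2 * fs):
        raise ValueError("segment shorter than 2 s")
    x = sig - np.mean(sig)
    amp = np.abs(rfft(x))
    freqs = rfftfreq(len(x), d=1.0 / fs)
    out: dict[str, float] = {}
    peaks, _ = find_peaks(amp)
    order = peaks[np.argsort(-amp[peaks], kind="stable")] if len(peaks) else \
        np.asarray([], dtype=int)
    chosen = list(order[:3])
    if len(chosen) < 3:  # degenerate spectra: top up with largest raw bins
        for k in np.argsort(-amp, kind="stable"):
            if k not in chosen:
                chosen.append(int(k))
            if len(chosen) == 3:
                break
    for rank, k in enumerate(chosen, start=1):
        out[f"fpeak{rank}_amp"] = float(amp[k])
        out[f"fpeak{rank}_freq"] = float(freqs[k])
    power = amp ** 2
    total = float(np.sum(power))
    for lo, hi, name in ((0, 2, "band_0_2"), (2, 5, "band_2_5"),
                         (5, 10, "band_5_10")):
        sel = (freqs >= lo) & (freqs < hi)
        out[name] = float(np.sum(power[sel]) / total) if total > 0 else 0.0
    p = amp / np.sum(amp) if np.sum(amp) > 0 else None
    if p is None:
        out["spec_entropy"] = 0.0
    else:
        nz = p[p > 0]
        out["spec_entropy"] = float(-np.sum(nz * np.log(nz)))
    return out


# ---------------------------------------------------------------------------
# assembly


def extract_all(seg: Segment, fid: FiducialSet) -> dict[str, float]:
    """All metadata, interval and 154 PWA features for one segment.

    Raises :class:`SegmentSkipped` when fewer than 5 beats are valid.
    """
    fs = seg.fs
    intervals = compute_intervals(fid, fs)
    means = intervals.means
    row: dict[str, float] = {
        "subject": seg.subject_id,
        "stage": seg.stage,
        "activity": seg.activity,
        "label_index": seg.label_index,
        "window_index": seg.window_index,
        "sbp": seg.sbp,
        "dbp": seg.dbp,
        "pat": means["pat"],
        "pep": means["pep"],
        "ptt": means["ptt"],
    }
    v = fid.valid
    # PPG families
    ppg_vals = morphological_ppg(seg.ppg, fid, fs)
    ppg_bounds = [(s, nxt) for s, _, _, nxt in _ppg_beat_windows(fid, len(seg.ppg))]
    ppg_vals.update(statistical_features(seg.ppg, ppg_bounds))
    s_valid = np.sort(fid.s[v])
    ppg_ibis = np.diff(s_valid) / fs
    ppg_vals.update(sequential_features(ppg_ibis[(ppg_ibis >= 0.3)
                                                 & (ppg_ibis <= 2.0)]))
    ppg_vals.update(frequency_features(seg.ppg, fs))
    for name, val in ppg_vals.items():
        row[f"ppg_{name}"] = val
    # ICG families
    icg_vals = morphological_icg(seg.icg, fid, fs)
    r_valid = fid.r[v]
    icg_bounds = [(int(r_valid[i]), int(r_valid[i + 1]))
                  for i in range(len(r_valid) - 1)
                  if 0.3 <= (r_valid[i + 1] - r_valid[i]) / fs <= 2.0]
    icg_vals.update(statistical_features(seg.icg, icg_bounds))
    c_ibis = np.diff(np.sort(fid.c[v])) / fs
    icg_vals.update(sequential_features(c_ibis[(c_ibis >= 0.3)
                                               & (c_ibis <= 2.0)]))
    icg_vals.update(frequency_features(seg.icg, fs))
    for name, val in icg_vals.items():
        row[f"icg_{name}"] = val
    return row
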