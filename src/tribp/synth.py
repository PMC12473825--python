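"""Synthetic tri-signal cohort generator with known BP and fiducials.

Generates cohorts of synchronized ECG/PPG/ICG records that mimic the
acquisition protocol of the real study: each subject contributes four
stages (rest, then three identical exercise blocks of cycling-elevated /
recovery / slow-breathing activity), every activity block being two minutes
of unlabelled lead-in followed by one BP-labelled minute — 10 labelled
minutes and 30 minutes of signal per subject at 250 Hz.

Waveforms are rendered from parameterized beat templates:

* ECG — sum of Gaussians (P, Q, R, S, T);
* PPG — two skewed Gaussian lobes (systolic + dicrotic) on a sawtooth-like
  diastolic-decay baseline that gives each pulse a well-defined foot;
* ICG — a dZ/dt-like wave with a B notch (small pre-ejection dip), C peak,
  X trough and a small O wave.

Blood pressure couples into the timing chain linearly: per-beat
PEP = pep0 + pep_slope·(SBP − sbp_ref) and likewise for PTT, with negative
slopes (both intervals shorten as pressure rises).  The pulse amplitude,
systolic rise time, dicrotic amplitude and ejection time also drift
linearly with BP so that waveform morphology genuinely carries pressure
information.  On top of the deterministic coupling, slow "vasomotor"
wander (per labelled minute / block) and small per-beat jitter are added to
the intervals and amplitudes, independent of BP — interval-only predictors
therefore see physiological noise that the fused waveform features can
average out, as in real data.

Every record is reproducible from (seed, subject_id); ground-truth fiducials
are measured numerically from the rendered noise-free channels, so they are
exact landmarks of the clean waveform by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import BPLabel, GroundTruth, SignalRecord

__all__ = [
    "PhaseBlock",
    "Coupling",
    "SubjectVariation",
    "NoiseConfig",
    "SynthConfig",
    "GroundTruth",
    "default_phase_plan",
    "simulate_record",
    "simulate_cohort",
    "add_noise",
]


@dataclass(frozen=True)
class PhaseBlock:
    """One activity block: unlabelled lead-in then one BP-labelled interval."""

    stage: int
    activity: str
    prep_s: float
    label_s: float
    sbp: float  # target systolic pressure during the block, mmHg
    dbp: float  # target diastolic pressure, mmHg
    hr: float   # target heart rate, beats/min

    @property
    def duration_s(self) -> float:
        return self.prep_s + self.label_s


def default_phase_plan() -> tuple[PhaseBlock, ...]:
    """The 4-stage, 10-labelled-minute, 30-minute acquisition protocol."""
    blocks = [PhaseBlock(1, "rest", 120.0, 60.0, 110.0, 70.0, 70.0)]
    for stage in (2, 3, 4):
        blocks += [
            PhaseBlock(stage, "cycling", 120.0, 60.0, 135.0, 82.0, 100.0),
            PhaseBlock(stage, "recovery", 120.0, 60.0, 118.0, 74.0, 80.0),
            PhaseBlock(stage, "slow_breathing", 120.0, 60.0, 105.0, 68.0, 62.0),
        ]
    return tuple(blocks)


@dataclass(frozen=True)
class Coupling:
    """Linear BP-to-timing coupling.

    PEP and PTT (seconds) decrease as SBP rises; slopes are s/mmHg and must
    be negative.  ``sbp_ref`` is the pressure at which the intercepts apply.
    """

    pep0: float = 0.100
    pep_slope: float = -0.0005
    ptt0: float = 0.200
    ptt_slope: float = -0.0010
    sbp_ref: float = 110.0

    def pep(self, sbp: float | np.ndarray) -> float | np.ndarray:
        return self.pep0 + self.pep_slope * (np.asarray(sbp) - self.sbp_ref)

    def ptt(self, sbp: float | np.ndarray) -> float | np.ndarray:
        return self.ptt0 + self.ptt_slope * (np.asarray(sbp) - self.sbp_ref)


@dataclass(frozen=True)
class SubjectVariation:
    """Between-subject heterogeneity (SDs of per-subject random offsets)."""

    sbp_sd: float = 8.0
    dbp_sd: float = 5.0
    hr_sd: float = 5.0
    pep0_sd: float = 0.008
    ptt0_sd: float = 0.012


@dataclass(frozen=True)
class TimingWander:
    """Slow physiological variability independent of BP (seconds / fraction)."""

    pep_minute_sd: float = 0.0015
    ptt_minute_sd: float = 0.004
    beat_jitter_sd: float = 0.0012
    amp_minute_sd: float = 0.05


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise model: respiratory drift, mains hum, broadband noise.

    Drift affects PPG and ICG only (the ECG front end is drift-free);
    50 Hz interference and broadband noise are per-channel.  The PPG channel
    carries almost no high-frequency noise (its front end is band-limited),
    while ICG is the noisiest channel.
    """

    drift_amp: dict[str, float] = field(
        default_factory=lambda: {"ppg": 0.40, "icg": 0.20}
    )
    drift_freq_hz: float = 0.25
    powerline_amp: dict[str, float] = field(
        default_factory=lambda: {"ecg": 0.02, "ppg": 0.0005, "icg": 0.08}
    )
    powerline_freq_hz: float = 50.0
    broadband_sd: dict[str, float] = field(
        default_factory=lambda: {"ecg": 0.010, "ppg": 0.001, "icg": 0.050}
    )

    def scaled(self, factor: float) -> "NoiseConfig":
        return NoiseConfig(
            drift_amp={k: v * factor for k, v in self.drift_amp.items()},
            drift_freq_hz=self.drift_freq_hz,
            powerline_amp={k: v * factor for k, v in self.powerline_amp.items()},
            powerline_freq_hz=self.powerline_freq_hz,
            broadband_sd={k: v * factor for k, v in self.broadband_sd.items()},
        )

    @classmethod
    def silent(cls) -> "NoiseConfig":
        return cls().scaled(0.0)


@dataclass(frozen=True)
class SynthConfig:
    n_subjects: int = 40
    fs: float = 250.0
    phase_plan: tuple[PhaseBlock, ...] = field(default_factory=default_phase_plan)
    hr_range: tuple[float, float] = (50.0, 120.0)
    coupling: Coupling = field(default_factory=Coupling)
    variation: SubjectVariation = field(default_factory=SubjectVariation)
    wander: TimingWander = field(default_factory=TimingWander)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    minute_bp_sd: float = 1.5
    rr_jitter: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.fs < 100.0:
            raise ValueError(f"fs must be >= 100 Hz, got {self.fs}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not self.phase_plan:
            raise ValueError("phase_plan is empty")
        for blk in self.phase_plan:
            if blk.prep_s < 0 or blk.label_s <= 0:
                raise ValueError(f"non-positive durations in block {blk}")
            if not blk.sbp > blk.dbp:
                raise ValueError(f"SBP must exceed DBP in block {blk}")
        if self.coupling.pep_slope >= 0 or self.coupling.ptt_slope >= 0:
            raise ValueError("coupling slopes must be negative")
        # Reject couplings that drive PEP or PTT non-positive at the highest
        # SBP plausibly reached (plan maximum + 3 SD of subject/minute spread).
        sbp_max = max(b.sbp for b in self.phase_plan)
        sbp_max += 3.0 * (self.variation.sbp_sd + self.minute_bp_sd)
        if self.coupling.pep(sbp_max) <= 0:
            raise ValueError(
                f"coupling drives PEP <= 0 at SBP {sbp_max:.1f} mmHg"
            )
        if self.coupling.ptt(sbp_max) <= 0:
            raise ValueError(
                f"coupling drives PTT <= 0 at SBP {sbp_max:.1f} mmHg"
            )

    @property
    def duration_s(self) -> float:
        return sum(b.duration_s for b in self.phase_plan)


# ----------------------------------------------------------------------------
# waveform rendering


def _add_gaussian(sig: np.ndarray, fs: float, tc: float, amp: float,
                  sigma: float) -> None:
    """Add amp·exp(−(t−tc)²/2σ²) to ``sig`` over a ±5σ local window."""
    n = len(sig)
    lo = max(0, int((tc - 5.0 * sigma) * fs))
    hi = min(n, int((tc + 5.0 * sigma) * fs) + 1)
    if lo >= hi:
        return
    t = np.arange(lo, hi) / fs
    sig[lo:hi] += amp * np.exp(-0.5 * ((t - tc) / sigma) ** 2)


def _argrel(sig: np.ndarray, fs: float, t_lo: float, t_hi: float,
            mode: str) -> int:
    """Arg-extremum of ``sig`` on [t_lo, t_hi] (clipped), as a sample index."""
    n = len(sig)
    lo = max(0, int(round(t_lo * fs)))
    hi = min(n, int(round(t_hi * fs)) + 1)
    if hi <= lo:
        raise ValueError("empty ground-truth search window")
    w = sig[lo:hi]
    off = int(np.argmin(w)) if mode == "min" else int(np.argmax(w))
    return lo + off


@dataclass
class _BeatPlan:
    t_r: float
    rr: float
    sbp: float
    dbp: float
    pep: float
    ptt: float
    amp_ppg: float
    amp_icg: float
    dicrotic: float
    rise_mu: float
    lvet: float


def _plan_beats(cfg: SynthConfig, rng: np.random.Generator,
                subj: dict) -> tuple[list[_BeatPlan], list[BPLabel]]:
    """Lay out beat times, per-beat BP and template parameters for one subject."""
    hr_lo, hr_hi = cfg.hr_range
    beats: list[_BeatPlan] = []
    labels: list[BPLabel] = []
    t_block = 0.0
    total = cfg.duration_s
    t = 1.0  # first beat 1 s in, away from filter edge transients
    for blk in cfg.phase_plan:
        block_sbp = blk.sbp + subj["sbp_off"]
        block_dbp = blk.dbp + subj["dbp_off"]
        label_start = t_block + blk.prep_s
        label_end = t_block + blk.duration_s
        lab_sbp = block_sbp + rng.normal(0.0, cfg.minute_bp_sd)
        lab_dbp = block_dbp + rng.normal(0.0, cfg.minute_bp_sd)
        lab_dbp = min(lab_dbp, lab_sbp - 10.0)
        labels.append(
            BPLabel(label_start, label_end, lab_sbp, lab_dbp,
                    stage=blk.stage, activity=blk.activity)
        )
        hr = float(np.clip(blk.hr + subj["hr_off"] + rng.normal(0.0, 2.0),
                           hr_lo + 2.0, hr_hi - 2.0))
        # slow wander, redrawn per block: vasomotor tone not explained by BP
        w_pep_prep = rng.normal(0.0, cfg.wander.pep_minute_sd)
        w_ptt_prep = rng.normal(0.0, cfg.wander.ptt_minute_sd)
        w_amp_prep = rng.normal(0.0, cfg.wander.amp_minute_sd)
        w_pep_lab = rng.normal(0.0, cfg.wander.pep_minute_sd)
        w_ptt_lab = rng.normal(0.0, cfg.wander.ptt_minute_sd)
        w_amp_lab = rng.normal(0.0, cfg.wander.amp_minute_sd)
        while t < label_end and t < total - 1.5:
            in_label = t >= label_start
            sbp = lab_sbp if in_label else block_sbp
            dbp = lab_dbp if in_label else block_dbp
            w_pep = w_pep_lab if in_label else w_pep_prep
            w_ptt = w_ptt_lab if in_label else w_ptt_prep
            w_amp = w_amp_lab if in_label else w_amp_prep
            d_sbp = sbp - cfg.coupling.sbp_ref
            pep = (subj["pep0"] + cfg.coupling.pep_slope * d_sbp + w_pep
                   + rng.normal(0.0, cfg.wander.beat_jitter_sd))
            ptt = (subj["ptt0"] + cfg.coupling.ptt_slope * d_sbp + w_ptt
                   + rng.normal(0.0, cfg.wander.beat_jitter_sd))
            pep = max(pep, 0.03)
            ptt = max(ptt, 0.05)
            rr = 60.0 / hr * (1.0 + rng.normal(0.0, cfg.rr_jitter))
            rr = float(np.clip(rr, 60.0 / hr_hi, 60.0 / hr_lo))
            beats.append(
                _BeatPlan(
                    t_r=t,
                    rr=rr,
                    sbp=sbp,
                    dbp=dbp,
                    pep=pep,
                    ptt=ptt,
                    amp_ppg=(1.0 + 0.004 * d_sbp) * (1.0 + w_amp),
                    amp_icg=(1.0 + 0.005 * d_sbp) * (1.0 + w_amp),
                    dicrotic=0.25 + 0.004 * (dbp - 70.0),
                    rise_mu=0.13 - 0.0003 * d_sbp,
                    lvet=0.30 - 0.0008 * d_sbp,
                )
            )
            t += rr
        t_block += blk.duration_s
        t = max(t, t_block + 0.0)
    return beats, labels


_PPG_SIGMA1 = 0.035          # systolic lobe width, s
_PPG_SIGMA2 = 0.090          # dicrotic lobe width, s
_PPG_DICROTIC_DELAY = 0.28   # dicrotic lobe lag after systolic peak, s
_PPG_BASELINE_DEPTH = 0.30   # diastolic-decay sawtooth depth (fraction of amp)
_ICG_B_DEPTH = 0.12
_ICG_B_SIGMA = 0.020
_ICG_C_SIGMA = 0.030
_ICG_RC_DELAY = 0.10         # B-to-C delay, s
_ICG_X_DEPTH = 0.45
_ICG_X_SIGMA = 0.035


def _render_clean(cfg: SynthConfig, beats: list[_BeatPlan],
                  n: int) -> dict[str, np.ndarray]:
    fs = cfg.fs
    ecg = np.zeros(n)
    ppg = np.zeros(n)
    icg = np.zeros(n)
    # PPG diastolic-decay baseline: piecewise-linear sawtooth rising with the
    # pulse and decaying to zero at the next foot, so each foot is a crisp V.
    base_t: list[float] = []
    base_v: list[float] = []
    for bp in beats:
        tr = bp.t_r
        # ECG: P-QRS-T sum of Gaussians
        _add_gaussian(ecg, fs, tr - 0.20, 0.12, 0.025)
        _add_gaussian(ecg, fs, tr - 0.040, -0.20, 0.010)
        _add_gaussian(ecg, fs, tr, 1.00, 0.012)
        _add_gaussian(ecg, fs, tr + 0.035, -0.25, 0.010)
        _add_gaussian(ecg, fs, tr + 0.25, 0.30, 0.045)
        # timing chain: Q -> (PEP) -> B -> (PTT) -> PPG dmax
        t_q = tr - 0.040
        t_b = t_q + bp.pep
        t_dmax = t_b + bp.ptt
        # PPG lobes; the systolic lobe's steepest rise sits ~(mu - sigma)
        # after the pulse origin, so anchor the lobe centre on t_dmax.
        mu1 = max(bp.rise_mu, 2.5 * _PPG_SIGMA1)
        t_origin = t_dmax - (mu1 - _PPG_SIGMA1)
        t_sys_peak = t_origin + mu1
        _add_gaussian(ppg, fs, t_sys_peak, bp.amp_ppg, _PPG_SIGMA1)
        _add_gaussian(ppg, fs, t_sys_peak + _PPG_DICROTIC_DELAY,
                      bp.amp_ppg * bp.dicrotic, _PPG_SIGMA2)
        if not base_t:
            # lead-in before the first beat so its foot is a genuine minimum
            base_t.append(t_origin - 0.4)
            base_v.append(_PPG_BASELINE_DEPTH * bp.amp_ppg)
        if t_origin > base_t[-1]:
            base_t += [t_origin, t_origin + 0.25 * bp.rr]
            base_v += [0.0, _PPG_BASELINE_DEPTH * bp.amp_ppg]
        # ICG: B notch, C peak, X trough, O wave
        _add_gaussian(icg, fs, t_b, -_ICG_B_DEPTH * bp.amp_icg, _ICG_B_SIGMA)
        _add_gaussian(icg, fs, t_b + _ICG_RC_DELAY, bp.amp_icg, _ICG_C_SIGMA)
        _add_gaussian(icg, fs, t_b + bp.lvet, -_ICG_X_DEPTH * bp.amp_icg,
                      _ICG_X_SIGMA)
        _add_gaussian(icg, fs, t_b + bp.lvet + 0.12, 0.15 * bp.amp_icg, 0.040)
    if base_t:
        t_axis = np.arange(n) / fs
        ppg += np.interp(t_axis, base_t, base_v)
    return {"ecg": ecg, "ppg": ppg, "icg": icg}


def _measure_ground_truth(cfg: SynthConfig, beats: list[_BeatPlan],
                          clean: dict[str, np.ndarray]) -> GroundTruth:
    """Locate the true fiducials numerically on the clean channels."""
    fs = cfg.fs
    ecg, ppg, icg = clean["ecg"], clean["ppg"], clean["icg"]
    cols: dict[str, list[int]] = {k: [] for k in
                                  ("q", "r", "s", "p", "dmax", "b", "c", "x")}
    sbps: list[float] = []
    dbps: list[float] = []
    dppg = np.diff(ppg)
    for bp in beats:
        tr = bp.t_r
        t_q = tr - 0.040
        t_b = t_q + bp.pep
        t_dmax = t_b + bp.ptt
        mu1 = max(bp.rise_mu, 2.5 * _PPG_SIGMA1)
        t_origin = t_dmax - (mu1 - _PPG_SIGMA1)
        r = _argrel(ecg, fs, tr - 0.03, tr + 0.03, "max")
        q = _argrel(ecg, fs, tr - 0.08, tr - 0.005, "min")
        s = _argrel(ppg, fs, t_origin - 0.05, t_origin + 0.04, "min")
        p = _argrel(ppg, fs, t_origin + mu1 - 0.06, t_origin + mu1 + 0.06, "max")
        lo = s
        hi = max(p, s + 2)
        dm = lo + int(np.argmax(dppg[lo:hi]))
        b = _argrel(icg, fs, t_b - 0.03, t_b + 0.03, "min")
        c = _argrel(icg, fs, t_b + _ICG_RC_DELAY - 0.05,
                    t_b + _ICG_RC_DELAY + 0.05, "max")
        x = _argrel(icg, fs, t_b + bp.lvet - 0.06, t_b + bp.lvet + 0.06, "min")
        for key, val in zip(cols, (q, r, s, p, dm, b, c, x)):
            cols[key].append(val)
        sbps.append(bp.sbp)
        dbps.append(bp.dbp)
    return GroundTruth(
        **{k: np.asarray(v, dtype=np.int64) for k, v in cols.items()},
        beat_sbp=np.asarray(sbps),
        beat_dbp=np.asarray(dbps),
        clean=clean,
    )


# ----------------------------------------------------------------------------
# public API


def add_noise(record: SignalRecord, noise: NoiseConfig,
              seed: int | np.random.Generator) -> SignalRecord:
    """Return a copy of ``record`` with the measurement-noise model applied.

    Baseline drift is added to PPG and ICG only; 50 Hz interference and
    broadband Gaussian noise are added per channel with channel-specific
    amplitudes.  Zero amplitudes reproduce the input exactly.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = record.n_samples
    t = np.arange(n) / record.fs
    out = {}
    for name, sig in record.channels.items():
        noisy = sig.astype(float).copy()
        amp = noise.drift_amp.get(name, 0.0)
        if amp > 0:
            phase = rng.uniform(0.0, 2.0 * math.pi)
            noisy += amp * np.sin(2.0 * math.pi * noise.drift_freq_hz * t + phase)
        amp = noise.powerline_amp.get(name, 0.0)
        if amp > 0:
            phase = rng.uniform(0.0, 2.0 * math.pi)
            noisy += amp * np.sin(
                2.0 * math.pi * noise.powerline_freq_hz * t + phase
            )
        sd = noise.broadband_sd.get(name, 0.0)
        if sd > 0:
            noisy += rng.normal(0.0, sd, size=n)
        out[name] = noisy
    return SignalRecord(
        subject_id=record.subject_id,
        fs=record.fs,
        ecg=out["ecg"],
        ppg=out["ppg"],
        icg=out["icg"],
        bp_labels=list(record.bp_labels),
        ground_truth=record.ground_truth,
    )


def simulate_record(config: SynthConfig,
                    subject_id: int) -> tuple[SignalRecord, GroundTruth]:
    """Simulate one subject-session; reproducible from (config.seed, subject_id)."""
    config.validate()
    ss = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, int(subject_id)])
    rng_subj, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    v = config.variation
    subj = {
        "sbp_off": rng_subj.normal(0.0, v.sbp_sd),
        "dbp_off": rng_subj.normal(0.0, v.dbp_sd),
        "hr_off": rng_subj.normal(0.0, v.hr_sd),
        "pep0": config.coupling.pep0 + rng_subj.normal(0.0, v.pep0_sd),
        "ptt0": config.coupling.ptt0 + rng_subj.normal(0.0, v.ptt0_sd),
    }
    beats, labels = _plan_beats(config, rng_subj, subj)
    n = int(round(config.duration_s * config.fs))
    clean = _render_clean(config, beats, n)
    gt = _measure_ground_truth(config, beats, clean)
    record = SignalRecord(
        subject_id=subject_id,
        fs=config.fs,
        ecg=clean["ecg"],
        ppg=clean["ppg"],
        icg=clean["icg"],
        bp_labels=labels,
        ground_truth=gt,
    )
    record = add_noise(record, config.noise, rng_noise)
    record.validate()
    return record, gt


def simulate_cohort(config: SynthConfig):
    """Yield (record, ground_truth) for subjects 0..n_subjects-1."""
    for sid in range(config.n_subjects):
        yield simulate_record(config, sid)
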