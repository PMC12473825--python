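"""Feature inventory, closed-form morphology checks and family properties."""

import numpy as np
import pytest

from tribp.features import (BeatIntervals, SegmentSkipped, all_feature_names,
                            approximate_entropy, compute_intervals,
                            frequency_features, icg_feature_names,
                            morphological_icg, morphological_ppg,
                            ppg_feature_names, sample_entropy,
                            sequential_features, statistical_features,
                            extract_all)
from tribp.fiducials import FiducialSet

FS = 250.0


def make_fid(fs=FS, **arrays):
    """FiducialSet from keyword arrays; missing fields default to zeros."""
    names = ("q", "r", "s", "p", "dmax", "b", "c", "x")
    n = max(len(v) for v in arrays.values())
    kw = {k: np.asarray(arrays.get(k, np.zeros(n)), dtype=np.int64)
          for k in names}
    valid = np.asarray(arrays.get("valid", np.ones(n)), dtype=bool)
    return FiducialSet(fs=fs, valid=valid, **kw)


class TestInventory:
    def test_counts_88_66_154(self):
        assert len(ppg_feature_names()) == 88
        assert len(icg_feature_names()) == 66
        assert len(all_feature_names()) == 154

    def test_names_unique_and_prefixed(self):
        names = all_feature_names()
        assert len(set(names)) == 154
        assert sum(n.startswith("ppg_") for n in names) == 88
        assert sum(n.startswith("icg_") for n in names) == 66

    def test_order_is_deterministic(self):
        assert all_feature_names() == all_feature_names()


class TestIntervals:
    def test_ptt_is_pat_minus_pep(self):
        # PAT 0.25 s (50 samples), PEP 0.08 s (16 samples) at 200 Hz
        fs = 200.0
        q = np.asarray([100 + 200 * i for i in range(6)])
        fid = make_fid(fs=fs, q=q, r=q + 10, b=q + 16, dmax=q + 50,
                       s=q + 40, p=q + 90, c=q + 35, x=q + 95)
        iv = compute_intervals(fid)
        np.testing.assert_allclose(iv.pat, 0.25)
        np.testing.assert_allclose(iv.pep, 0.08)
        np.testing.assert_allclose(iv.ptt, 0.17)

    def test_too_few_valid_beats_raises_skip(self):
        q = np.asarray([100, 350, 600])
        fid = make_fid(q=q, r=q + 10, b=q + 20, dmax=q + 60, s=q + 40,
                       p=q + 90, c=q + 35, x=q + 95)
        with pytest.raises(SegmentSkipped, match="valid beats"):
            compute_intervals(fid)


def triangle_pulse(peak_frac, n_cycle=250, amp=1.0, n_beats=2):
    """Piecewise-linear pulses: foot 0, peak at peak_frac of the cycle."""
    kp = int(round(peak_frac * n_cycle))
    one = np.concatenate([np.linspace(0, amp, kp, endpoint=False),
                          np.linspace(amp, 0, n_cycle - kp, endpoint=False)])
    sig = np.tile(one, n_beats)
    sig = np.append(sig, 0.0)
    s = np.asarray([i * n_cycle for i in range(n_beats)])
    valid = np.zeros(n_beats, dtype=bool)
    valid[0] = True  # only the first beat has a complete following cycle
    fid = make_fid(s=s, p=s + kp, dmax=s + kp // 2, q=s, r=s + 1, b=s + 2,
                   c=s + 3, x=s + 4, valid=valid)
    return sig, fid


class TestMorphologicalPPG:
    def test_k_sys_dia_closed_form(self):
        # Pa=1, Sa=0, Pt−St=0.3 s, Cycle=1 s -> K=3.33, SYS=0.3, DIA=0.7
        sig, fid = triangle_pulse(peak_frac=0.3)
        f = morphological_ppg(sig, fid)
        assert f["k"] == pytest.approx(1.0 / 0.3, rel=1e-6)
        assert f["sys"] == pytest.approx(0.3, abs=1e-9)
        assert f["dia"] == pytest.approx(0.7, abs=1e-9)
        assert f["cycle"] == pytest.approx(1.0, abs=1e-9)
        assert f["pulse_amp"] == pytest.approx(1.0, rel=1e-6)

    def test_symmetric_triangle_has_unit_width_ratios(self):
        sig, fid = triangle_pulse(peak_frac=0.5)
        f = morphological_ppg(sig, fid)
        for lev in range(10, 100, 10):
            assert f[f"width_sys_{lev}"] == \
                pytest.approx(f[f"width_dia_{lev}"], rel=1e-6)
            assert f[f"width_ratio_{lev}"] == pytest.approx(1.0, rel=1e-6)

    def test_amplitude_scaling(self):
        """Scaling the channel scales amplitude/area features, not timings."""
        sig, fid = triangle_pulse(peak_frac=0.3)
        f1 = morphological_ppg(sig, fid)
        f2 = morphological_ppg(2.5 * sig, fid)
        for name in ("cycle", "sys", "dia", "sys_dia_ratio", "width_sys_50",
                     "width_ratio_30", "area_norm"):
            assert f2[name] == pytest.approx(f1[name], rel=1e-9)
        for name in ("pulse_amp", "pa", "k", "area_total", "d1_max"):
            assert f2[name] == pytest.approx(2.5 * f1[name], rel=1e-9)


class TestMorphologicalICG:
    def _c_wave(self):
        t = np.arange(500) / FS
        sig = np.exp(-0.5 * ((t - 0.6) / 0.03) ** 2)   # symmetric C at 0.6 s
        sig += 0.2 * np.exp(-0.5 * ((t - 0.45) / 0.02) ** 2)  # B bump
        b, c, x = int(0.45 * FS), int(0.6 * FS), int(0.75 * FS)
        fid = make_fid(b=[b], c=[c], x=[x], r=[b - 15], q=[b - 25],
                       s=[b + 1], p=[c + 1], dmax=[b + 2])
        return sig, fid

    def test_lvet_and_amplitude_features(self):
        sig, fid = self._c_wave()
        f = morphological_icg(sig, fid)
        assert f["lvet"] == pytest.approx(0.3, abs=1e-9)
        assert f["c_amp"] == pytest.approx(1.0, rel=1e-3)
        assert f["cb_amp_diff"] == pytest.approx(f["c_amp"] - f["b_amp"])
        assert f["bc_amp_ratio"] == pytest.approx(f["b_amp"] / f["c_amp"])

    def test_symmetric_c_wave_has_equal_left_right_widths(self):
        sig, fid = self._c_wave()
        f = morphological_icg(sig, fid)
        for lev in (50, 70, 90):  # levels above the B bump's influence
            assert f[f"cwidth_left_{lev}"] == \
                pytest.approx(f[f"cwidth_right_{lev}"], rel=0.05)


class TestStatistical:
    def test_constant_beat(self):
        f = statistical_features(np.full(100, 3.0), [(0, 100)])
        assert f["stat_std"] == 0.0
        assert f["stat_var"] == 0.0
        assert f["stat_range"] == 0.0
        assert np.isnan(f["stat_skew"])  # undefined on zero variance

    def test_two_point_beat_population_variance(self):
        f = statistical_features(np.asarray([0.0, 1.0]), [(0, 2)])
        assert f["stat_mean"] == 0.5
        assert f["stat_var"] == 0.25

    def test_symmetric_beat_has_zero_skew(self):
        y = np.sin(np.linspace(0, 2 * np.pi, 200, endpoint=False))
        f = statistical_features(y, [(0, 200)])
        assert abs(f["stat_skew"]) < 1e-10


class TestSequential:
    def test_equal_ibis_all_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            f = sequential_features(np.full(10, 0.8))
        assert f["sdnn"] == f["rmssd"] == f["sd1"] == f["sd2"] == 0.0
        assert f["sampen"] == 0.0 and f["apen"] == 0.0

    def test_alternating_ibis_sd1_closed_form(self):
        # odd length: successive differences then split evenly, mean 0
        a, b = 0.8, 0.9
        f = sequential_features(np.asarray([a, b] * 10 + [a]))
        assert f["sd1"] == pytest.approx(abs(a - b) / np.sqrt(2), rel=1e-9)

    def test_poincare_ellipse_identity(self):
        rng = np.random.default_rng(4)
        x = 0.8 + 0.05 * rng.standard_normal(50)
        f = sequential_features(x)
        assert f["sd1"] ** 2 + f["sd2"] ** 2 == \
            pytest.approx(2.0 * f["sdnn"] ** 2, abs=1e-9)

    def test_entropies_positive_on_random_series(self):
        rng = np.random.default_rng(5)
        x = 0.8 + 0.08 * rng.standard_normal(60)
        assert sample_entropy(x) > 0
        assert approximate_entropy(x) > 0


class TestFrequency:
    def test_pure_tone_dominates_low_band(self):
        t = np.arange(2500) / FS
        f = frequency_features(np.sin(2 * np.pi * 1.2 * t), FS)
        assert f["fpeak1_freq"] == pytest.approx(1.2, abs=FS / 2500 + 1e-9)
        assert f["band_0_2"] == pytest.approx(1.0, abs=0.01)

    def test_white_noise_entropy_near_maximum(self):
        rng = np.random.default_rng(6)
        f = frequency_features(rng.standard_normal(2500), FS)
        n_bins = 2500 // 2 + 1
        assert f["spec_entropy"] > 0.9 * np.log(n_bins)

    def test_two_tone_peak_ordering(self):
        t = np.arange(2500) / FS
        sig = 2.0 * np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 3.0 * t)
        f = frequency_features(sig, FS)
        assert f["fpeak1_freq"] == pytest.approx(1.0, abs=0.2)
        assert f["fpeak2_freq"] == pytest.approx(3.0, abs=0.2)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            frequency_features(np.zeros(100), FS)


class TestExtractAll:
    def test_full_vector_on_synthetic_segment(self, compact_record):
        from tribp.fiducials import delineate_record, slice_fiducials
        from tribp.preprocess import preprocess_record, segment

        record, _ = compact_record
        clean = preprocess_record(record)
        fid = delineate_record(clean)
        seg = segment(clean)[2]
        local = slice_fiducials(fid, seg.start_idx, seg.start_idx + 2500)
        row = extract_all(seg, local)
        for name in all_feature_names():
            assert name in row
            assert np.isfinite(row[name]), name
        assert 0.05 <= row["pat"] <= 0.40
        assert row["ptt"] == pytest.approx(row["pat"] - row["pep"], abs=1e-12)
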