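import numpy as np
import pytest
import pywt

from ecgdx.exceptions import (
    InsufficientPeaksError,
    InsufficientSegmentsError,
    ParameterError,
)
from ecgdx.qrs import RPeakList, detect_r_peaks
from ecgdx.signal_io import ECGRecord
from ecgdx.wavelet import (
    SegmentationConfig,
    TVGH_SEGMENTATION,
    WaveletConfig,
    group_segments,
    record_wavelet_features,
    segment_cycles,
    wavelet_feature,
)

FS = 500.0


def _record_and_peaks(n_beats=10, rr=500):
    rng = np.random.default_rng(5)
    x = rng.normal(size=n_beats * rr + 1)
    peaks = RPeakList(indices=np.arange(n_beats + 1) * rr, fs=FS)
    return ECGRecord(samples=x, fs=FS), peaks


class TestSegmentation:
    def test_ptb_scheme_gives_128_point_segments(self):
        rec, peaks = _record_and_peaks()
        segs = segment_cycles(rec, peaks, SegmentationConfig())
        assert len(segs) == 10
        assert all(s.size == 128 for s in segs)

    def test_tvgh_scheme_gives_254_point_segments(self):
        rec, peaks = _record_and_peaks()
        segs = segment_cycles(rec, peaks, TVGH_SEGMENTATION)
        assert all(s.size == 169 + 85 == 254 for s in segs)

    def test_ramp_cycle_picks_stated_positions(self):
        # a cycle resampling exactly onto the ramp 0..283 keeps index identity
        rec = ECGRecord(samples=np.arange(285.0), fs=FS)
        peaks = RPeakList(indices=np.array([0, 284]), fs=1.0)
        seg = segment_cycles(rec, peaks, SegmentationConfig())[0]
        np.testing.assert_allclose(seg[:85], np.arange(85.0), atol=1e-9)
        np.testing.assert_allclose(seg[85:], np.arange(241.0, 284.0), atol=1e-9)

    def test_requires_two_peaks(self):
        rec, _ = _record_and_peaks()
        with pytest.raises(InsufficientPeaksError):
            segment_cycles(rec, RPeakList(indices=np.array([100]), fs=FS))

    def test_cuts_must_sum_to_cycle_len(self):
        with pytest.raises(ParameterError):
            SegmentationConfig(cycle_len=284, cuts=(85, 100, 43))

    def test_segment_count_tracks_rr_intervals(self, clean_train):
        record, _ = clean_train
        peaks = detect_r_peaks(record)
        segs = segment_cycles(record, peaks, SegmentationConfig())
        assert len(segs) == len(peaks) - 1


class TestGrouping:
    def test_floor_division_discards_remainder(self):
        segs = [np.full(8, i, dtype=float) for i in range(9)]
        groups = group_segments(segs, 4)
        assert len(groups) == 2

    def test_group_holds_four_by_segment_len(self):
        segs = [np.zeros(128) for _ in range(4)]
        (group,) = group_segments(segs, 4)
        assert group.shape == (4, 128)

    def test_order_preserved(self):
        segs = [np.full(4, i, dtype=float) for i in range(8)]
        g0, g1 = group_segments(segs, 4)
        np.testing.assert_array_equal(g0[:, 0], [0, 1, 2, 3])
        np.testing.assert_array_equal(g1[:, 0], [4, 5, 6, 7])

    def test_too_few_segments(self):
        with pytest.raises(InsufficientSegmentsError):
            group_segments([np.zeros(8)] * 3, 4)


class TestWaveletFeature:
    def test_constant_segments_have_zero_detail_energy(self):
        group = np.ones((4, 128))
        cfg = WaveletConfig(n=3, coeff_set="approx_plus_details")
        feat = wavelet_feature(group, cfg)
        per_seg = feat.values.reshape(4, -1)
        n_approx = 128 // 2**3
        assert np.max(np.abs(per_seg[:, n_approx:])) < 1e-10

    def test_perfect_reconstruction(self, rng):
        # oracle: inverting the full periodized coefficient set recovers segments
        cfg = WaveletConfig(n=4, coeff_set="approx_plus_details")
        for _ in range(10):
            group = rng.normal(size=(4, 128))
            feat = wavelet_feature(group, cfg)
            per_seg = feat.values.reshape(4, -1)
            lens = [128 // 2**4] + [128 // 2**k for k in range(4, 0, -1)]
            for seg, flat in zip(group, per_seg):
                coeffs, pos = [], 0
                for ln in lens:
                    coeffs.append(flat[pos : pos + ln])
                    pos += ln
                rebuilt = pywt.waverec(coeffs, cfg.family, mode="periodization")
                assert np.max(np.abs(rebuilt[:128] - seg)) <= 1e-8

    def test_parseval_energy_conservation(self, rng):
        cfg = WaveletConfig(n=4, coeff_set="approx_plus_details")
        for _ in range(10):
            group = rng.normal(size=(4, 128))
            feat = wavelet_feature(group, cfg)
            e_sig = np.sum(group**2)
            e_coeff = np.sum(feat.values**2)
            assert abs(e_coeff - e_sig) / e_sig <= 1e-6

    def test_level_beyond_bound_names_maximum(self):
        with pytest.raises(ParameterError, match="7"):
            WaveletConfig(n=8)  # 128-point segments admit at most level 7

    def test_feature_length_constant_across_records(self, small_effect_cohort):
        cohort = small_effect_cohort
        cfg = WaveletConfig(n=4)
        lengths = set()
        for rec in cohort.records[:6]:
            peaks = detect_r_peaks(rec)
            feats = record_wavelet_features(rec, peaks, cfg)
            lengths.update(f.values.size for f in feats)
        assert len(lengths) == 1

    def test_single_dwt_over_group_switch(self, rng):
        group = rng.normal(size=(4, 128))
        cfg = WaveletConfig(n=4, per_segment_dwt=False)
        feat = wavelet_feature(group, cfg)
        assert feat.values.size == 512 // 2**4

    def test_determinism(self, rng):
        group = rng.normal(size=(4, 128))
        a = wavelet_feature(group, WaveletConfig(n=5)).values
        b = wavelet_feature(group, WaveletConfig(n=5)).values
        np.testing.assert_array_equal(a, b)
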