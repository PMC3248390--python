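"""Speed maps and segmentation: kernel exactness on affine profiles, a
direct-summation oracle for the smoothed-derivative, speed classes, CTR/TTR
segmentation against constructed truth, and per-TTR statistics."""

import numpy as np
import pytest

from replikinetics import speedscale as ss, timing as tm


def profile_from_tr50_min(tr50_min, step_kb=100, chrom="chr1"):
    n = len(tr50_min)
    starts = np.arange(n, dtype=np.int64) * int(step_kb * 1000)
    return tm.TimingProfile(np.full(n, chrom), starts,
                            starts + int(step_kb * 1000),
                            np.asarray(tr50_min) / max(np.max(tr50_min), 1e-9) / 60.0,
                            np.asarray(tr50_min) / 60.0,
                            np.zeros(n, dtype=bool), step_kb=float(step_kb))


def dog_slope_oracle(t_min, step_kb, scale_kb, i):
    """Direct plain-Python summation of the derivative-of-Gaussian weights
    (independent of the convolution plumbing)."""
    sd = (scale_kb / 2.0) / step_kb
    half = max(int(np.ceil(4.0 * sd)), 1)
    num = 0.0
    den = 0.0
    for j in range(-half, half + 1):
        w = j * np.exp(-0.5 * (j / sd) ** 2)
        num += w * t_min[i + j]
        den += w * j
    return num / den / step_kb


class TestWtSlope:
    @pytest.mark.parametrize("scale", [100.0, 200.0, 500.0])
    def test_exact_on_affine_profiles(self, scale):
        x = np.arange(200) * 100.0  # kb
        prof = profile_from_tr50_min(5.0 + 0.25 * x, step_kb=100)
        slope, mask = ss.wt_slope(prof, scale)
        assert np.all(np.abs(slope[~mask] - 0.25) < 1e-9)

    def test_flat_profile_zero_slope_and_capped_speed(self):
        prof = profile_from_tr50_min(np.full(100, 120.0), step_kb=100)
        smap = ss.build_speed_map(prof, (100.0,))
        ok = ~smap.mask[0]
        assert np.all(np.abs(smap.slope[0][ok]) < 1e-9)
        assert np.all(smap.apparent_speed(100.0)[ok] == ss.SPEED_CAP)

    def test_v_profile_sign_change_at_minimum(self):
        rng = np.random.default_rng(4)
        x = np.arange(300) * 10.0
        t = np.abs(x - 1500.0) / 2.0 + rng.normal(0, 1.0, size=len(x))
        prof = profile_from_tr50_min(t, step_kb=10)
        slope, mask = ss.wt_slope(prof, 100.0)
        sign_changes = np.nonzero(np.diff(np.sign(slope[~mask])))[0]
        centers = np.arange(300)[~mask]
        assert any(abs(centers[i] - 150) <= 5 for i in sign_changes)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(9)
        t = np.cumsum(rng.normal(1.0, 3.0, size=400))
        prof = profile_from_tr50_min(t, step_kb=10)
        slope, mask = ss.wt_slope(prof, 100.0)
        for i in (30, 100, 250, 370):
            assert slope[i] == pytest.approx(dog_slope_oracle(t, 10.0, 100.0, i),
                                             abs=1e-9)
        assert mask[0] and mask[-1]  # edges masked

    def test_all_masked_profile_is_an_error(self):
        prof = profile_from_tr50_min(np.arange(50.0), step_kb=100)
        prof.mask[:] = True
        with pytest.raises(ValueError):
            ss.wt_slope(prof, 100.0)

    def test_gap_splits_and_masks_neighbourhood(self):
        t = np.arange(200) * 25.0
        prof = profile_from_tr50_min(t, step_kb=100)
        prof.mask[100] = True
        slope, mask = ss.wt_slope(prof, 200.0)
        assert mask[100]
        assert mask[99] and mask[101]  # half-kernel exclusion near the gap
        assert not mask[50] and slope[50] == pytest.approx(0.25, abs=1e-9)


class TestSpeedClasses:
    def test_flat_profile_all_fast(self):
        prof = profile_from_tr50_min(np.full(100, 60.0), step_kb=100)
        smap = ss.build_speed_map(prof, (100.0,))
        assert ss.speed_classes(smap, 100.0) == (0.0, 0.0, 1.0)

    def test_uniform_ramp_all_intermediate(self):
        x = np.arange(200) * 100.0
        prof = profile_from_tr50_min(x / 4.0, step_kb=100)  # 4 kb/min
        smap = ss.build_speed_map(prof, (100.0,))
        assert ss.speed_classes(smap, 100.0) == (0.0, 1.0, 0.0)

    def test_constructed_mixture_fractions(self):
        # 100 slow bins (1 kb/min), 100 intermediate (4), 100+ flat, well
        # separated so kernel support does not mix them
        t = np.concatenate([np.arange(100) * 100.0,        # 1 kb/min
                            np.full(50, 9900.0),
                            9900.0 + np.arange(100) * 25.0,  # 4 kb/min
                            np.full(150, 12375.0)])
        prof = profile_from_tr50_min(t, step_kb=100)
        slow, mid, fast = ss.speed_classes(ss.build_speed_map(prof, (100.0,)), 100.0)
        assert slow == pytest.approx(100 / 396, abs=0.02)
        assert mid == pytest.approx(100 / 396, abs=0.02)


class TestSegmentation:
    def test_flat_profile_single_ctr(self):
        prof = profile_from_tr50_min(np.full(30, 100.0), step_kb=100)
        smap = ss.build_speed_map(prof, (100.0,))
        segs = ss.segment_ctr_ttr(smap, 100.0)
        assert [s.klass for s in segs.segments] == ["CTR"]

    def test_flat_ramp_flat_recovers_ttr_within_one_bin(self):
        # 400 kb ramp at 4 kb/min between flat domains, tiled 100 kb bins
        t = np.concatenate([np.full(20, 0.0),
                            (np.arange(1, 5)) * 25.0,
                            np.full(20, 125.0)])
        t[20:24] = 12.5 + np.arange(4) * 25.0  # exact window means on the ramp
        prof = profile_from_tr50_min(t, step_kb=100)
        smap = ss.build_speed_map(prof, (100.0,))
        segs = ss.segment_ctr_ttr(smap, 100.0)
        ttrs = segs.of_class("TTR")
        assert len(ttrs) == 1
        assert ttrs[0].length_kb == pytest.approx(400.0, abs=100.0)
        assert [s.klass for s in segs.segments] == ["CTR", "TTR", "CTR"]

    def test_speed_exactly_at_threshold_is_ttr(self):
        x = np.arange(60) * 100.0
        prof = profile_from_tr50_min(x / 10.0, step_kb=100)  # exactly 10 kb/min
        smap = ss.build_speed_map(prof, (100.0,))
        segs = ss.segment_ctr_ttr(smap, 100.0, threshold=10.0)
        assert [s.klass for s in segs.segments] == ["TTR"]

    def test_segments_partition_unmasked_support(self):
        rng = np.random.default_rng(12)
        t = np.cumsum(rng.normal(2.0, 8.0, size=300))
        prof = profile_from_tr50_min(t, step_kb=100)
        prof.mask[150] = True
        smap = ss.build_speed_map(prof, (100.0,))
        segs = ss.segment_ctr_ttr(smap, 100.0)
        i = smap.scale_index(100.0)
        covered = np.zeros(len(t), dtype=bool)
        for seg in segs.segments:
            k0, k1 = seg.bin_slice
            assert not covered[k0:k1].any()  # no overlaps
            covered[k0:k1] = True
        np.testing.assert_array_equal(covered, ~smap.mask[i])

    def test_segmentation_idempotent_on_reconstruction(self):
        t = np.concatenate([np.full(20, 0.0), 12.5 + np.arange(4) * 25.0,
                            np.full(20, 125.0)])
        prof = profile_from_tr50_min(t, step_kb=100)
        smap = ss.build_speed_map(prof, (100.0,))
        first = ss.segment_ctr_ttr(smap, 100.0)
        # rebuild a piecewise profile from the segment classes and re-segment
        # (edge bins outside the unmasked support keep the original values)
        rebuilt = t.copy()
        level = 0.0
        for seg in first.segments:
            k0, k1 = seg.bin_slice
            if seg.klass == "TTR":
                st = ss.ttr_stats(seg, prof, smap, 100.0)
                step_t = 100.0 / st.mean_speed
                rebuilt[k0:k1] = level + (np.arange(k1 - k0) + 0.5) * step_t
                level = level + (k1 - k0) * step_t
            else:
                rebuilt[k0:k1] = level
        prof2 = profile_from_tr50_min(rebuilt, step_kb=100)
        second = ss.segment_ctr_ttr(ss.build_speed_map(prof2, (100.0,)), 100.0)
        assert [(s.klass, s.bin_slice) for s in second.segments] == \
            [(s.klass, s.bin_slice) for s in first.segments]


class TestTTRStats:
    def make_linear_ttr(self, dx_kb=400.0, dt_min=120.0):
        step = dt_min / (dx_kb / 100.0)
        t = np.concatenate([np.full(20, 0.0),
                            step / 2 + np.arange(int(dx_kb / 100)) * step,
                            np.full(20, dt_min)])
        prof = profile_from_tr50_min(t, step_kb=100)
        smap = ss.build_speed_map(prof, (100.0,))
        segs = ss.segment_ctr_ttr(smap, 100.0)
        (seg,) = segs.of_class("TTR")
        return seg, prof, smap

    def test_linear_ttr_mean_speed_and_offsets(self):
        # long enough that the probed offsets sit clear of the smoothing
        # support at the TTR borders
        seg, prof, smap = self.make_linear_ttr(dx_kb=1200.0, dt_min=360.0)
        st = ss.ttr_stats(seg, prof, smap, 100.0,
                          offsets_kb=(300.0, 500.0, 700.0))
        assert st.mean_speed == pytest.approx(1200.0 / 360.0, rel=0.1)
        vals = list(st.offset_speeds.values())
        assert max(vals) - min(vals) < 0.02 * max(vals)
        assert np.mean(vals) == pytest.approx(1200.0 / 360.0, rel=0.02)

    def test_orientation_follows_early_edge(self):
        seg, prof, smap = self.make_linear_ttr()
        st = ss.ttr_stats(seg, prof, smap, 100.0)
        assert st.orientation == "left"
        flipped = profile_from_tr50_min(prof.tr50[::-1] * 60.0, step_kb=100)
        smap2 = ss.build_speed_map(flipped, (100.0,))
        (seg2,) = ss.segment_ctr_ttr(smap2, 100.0).of_class("TTR")
        assert ss.ttr_stats(seg2, flipped, smap2, 100.0).orientation == "right"

    def test_accelerating_ttr_speeds_up_along_gradient(self):
        # convex transition: per-bin time increments shrink along the ramp
        increments = np.array([40.0, 36.0, 32.0, 28.0, 24.0, 20.0, 16.0, 12.0])
        ramp = np.concatenate([[0.0], np.cumsum(increments)])[:-1] + 20.0
        t = np.concatenate([np.full(20, 0.0), ramp,
                            np.full(20, ramp[-1] + 12.0)])
        prof = profile_from_tr50_min(t, step_kb=100)
        smap = ss.build_speed_map(prof, (100.0,))
        ttrs = ss.segment_ctr_ttr(smap, 100.0).of_class("TTR")
        st = ss.ttr_stats(ttrs[0], prof, smap, 100.0,
                          offsets_kb=(200.0, 500.0))
        assert st.offset_speeds[500.0] > st.offset_speeds[200.0]

    def test_unidirectional_compatibility(self):
        seg, prof, smap = self.make_linear_ttr(dx_kb=400.0, dt_min=120.0)
        st = ss.ttr_stats(seg, prof, smap, 100.0)
        assert not ss.unidirectional_compatibility(st, v_max=2.0)
        assert ss.unidirectional_compatibility(st, v_max=4.0)

    def test_offsets_beyond_length_are_missing(self):
        seg, prof, smap = self.make_linear_ttr(dx_kb=300.0, dt_min=90.0)
        st = ss.ttr_stats(seg, prof, smap, 100.0,
                          offsets_kb=(100.0, 1000.0))
        assert np.isnan(st.offset_speeds[1000.0])
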