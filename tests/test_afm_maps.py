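"""Map-level AFM operations: leveling, registration, segmentation,
normalization, nanodomain statistics, volumetrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellodyn import afm, synthetic
from cellodyn.errors import DegenerateScaleError, InputError, InsufficientDataError, MaskError


def make_frame(height, modulus=None, pixel_size=2.0, **kw):
    if modulus is None:
        modulus = np.full_like(np.asarray(height, dtype=float), 1000.0)
    return afm.MapFrame(height=height, modulus=modulus, pixel_size=pixel_size, **kw)


def ridge_frame(ny=40, nx=120, h=20.0, width=10, pixel_size=2.0):
    """Simple flat-background frame with a rectangular ridge."""
    height = np.zeros((ny, nx))
    r0 = ny // 2 - width // 2
    height[r0:r0 + width, 10:nx - 10] = h
    bg = height < 1.0
    return make_frame(height, background_mask=bg, fiber_mask=~bg)


class TestLevelPlane:
    def test_known_tilt_round_trip(self):
        rng = np.random.default_rng(0)
        fr = ridge_frame()
        noise = rng.normal(0, 0.1, fr.height.shape)
        ny, nx = fr.height.shape
        Y, X = np.mgrid[0:ny, 0:nx]
        tilted = make_frame(fr.height + noise + 0.01 * X + 0.02 * Y,
                            background_mask=fr.background_mask)
        lev = afm.level_plane(tilted)
        bg = lev.background_mask
        assert abs(np.median(lev.height[bg])) < 1e-6
        assert np.sqrt(np.mean(lev.height[bg] ** 2)) < 0.12  # ~noise floor

    def test_idempotence(self):
        fr = ridge_frame()
        once = afm.level_plane(fr)
        twice = afm.level_plane(once)
        np.testing.assert_allclose(twice.height, once.height, atol=1e-9)

    def test_fiber_only_tilt_leaves_frame_unchanged(self):
        fr = ridge_frame()
        ny, nx = fr.height.shape
        X = np.mgrid[0:ny, 0:nx][1]
        h = fr.height.copy()
        h[fr.fiber_mask] += (0.05 * X)[fr.fiber_mask]
        fr2 = make_frame(h, background_mask=fr.background_mask)
        lev = afm.level_plane(fr2)
        np.testing.assert_allclose(lev.height, fr2.height, atol=1e-9)

    def test_small_background_rejected(self):
        fr = ridge_frame()
        bg = np.zeros_like(fr.background_mask)
        bg[0, :5] = True
        with pytest.raises(MaskError):
            afm.level_plane(make_frame(fr.height, background_mask=bg))


class TestRegisterDrift:
    def _stack_with_shifts(self, shifts):
        base = ridge_frame().height + np.random.default_rng(1).normal(0, 0.05, (40, 120))
        frames = [make_frame(base, time=0.0)]
        for i, (dr, dc) in enumerate(shifts, start=1):
            shifted = np.roll(np.roll(base, dr, axis=0), dc, axis=1)
            frames.append(make_frame(shifted, time=float(i)))
        return afm.FrameStack(frames)

    def test_integer_shifts_recovered_exactly(self):
        stack = self._stack_with_shifts([(3, -2)])
        reg = afm.register_drift(stack, sequential=False)
        np.testing.assert_allclose(reg.offsets[1], [-3.0, 2.0], atol=1e-9)

    def test_identical_frames_zero_offset(self):
        stack = self._stack_with_shifts([(0, 0), (0, 0)])
        reg = afm.register_drift(stack)
        np.testing.assert_allclose(reg.offsets, 0.0, atol=1e-9)

    def test_subpixel_recovery_within_quarter_pixel(self):
        from scipy.ndimage import shift as ndshift
        base = ridge_frame().height
        moved = ndshift(base, (0.5, 0.0), order=3, mode="nearest")
        stack = afm.FrameStack([make_frame(base, time=0.0), make_frame(moved, time=1.0)])
        reg = afm.register_drift(stack, upsample_factor=10)
        assert abs(reg.offsets[1][0] + 0.5) <= 0.25
        assert abs(reg.offsets[1][1]) <= 0.25

    def test_flat_frames_flagged(self):
        frames = [make_frame(np.zeros((30, 30)), time=float(i)) for i in range(3)]
        reg = afm.register_drift(afm.FrameStack(frames))
        assert reg.registration_failed[1] and reg.registration_failed[2]

    def test_volume_conserved_after_registration(self):
        stack = self._stack_with_shifts([(2, 3), (4, 6)])
        reg = afm.register_drift(stack)
        sums = [f.height.sum() for f in reg.frames]
        assert abs(sums[1] - sums[0]) / sums[0] < 0.005
        assert abs(sums[2] - sums[0]) / sums[0] < 0.005

    def test_single_frame_rejected(self):
        with pytest.raises(InsufficientDataError):
            afm.register_drift(afm.FrameStack([ridge_frame()]))


class TestSegmentFiber:
    def test_phantom_footprint_recovered(self, rendered_phantom):
        height, modulus, meta = rendered_phantom
        fr = make_frame(height, modulus)
        seg = afm.segment_fiber(fr, height_threshold=5.0)
        truth = meta["fiber_mask"]
        # agreement up to boundary pixels (partial-coverage edges)
        diff = np.count_nonzero(seg.fiber_mask ^ (height > 5.0))
        assert diff == 0
        perimeter = 2 * (truth.any(axis=0).sum() + truth.any(axis=1).sum())
        assert abs(seg.fiber_mask.sum() - truth.sum()) <= perimeter

    def test_all_zero_frame_warns_empty(self):
        fr = make_frame(np.zeros((50, 50)))
        with pytest.warns(UserWarning, match="empty fiber mask"):
            seg = afm.segment_fiber(fr, height_threshold=1.0)
        assert not seg.fiber_mask.any()

    def test_small_speck_excluded(self):
        h = np.zeros((60, 60))
        h[10:12, 10:15] = 20.0  # 10-pixel speck
        seg = afm.segment_fiber(make_frame(h), height_threshold=5.0)
        assert not seg.fiber_mask.any()
        assert not seg.background_mask[10, 11]  # speck is in neither mask

    def test_compact_blob_excluded_by_aspect(self):
        h = np.zeros((80, 80))
        h[20:40, 20:40] = 20.0  # large but square
        seg = afm.segment_fiber(make_frame(h), height_threshold=5.0, min_aspect=3.0)
        assert not seg.fiber_mask.any()


class TestNormalizeModulus:
    def test_identity_when_background_at_nominal(self):
        fr = ridge_frame()
        out = afm.normalize_modulus(fr, E_hopg_nominal=1000.0)
        np.testing.assert_allclose(out.modulus, fr.modulus)

    def test_uniform_gain_cancels(self):
        fr = ridge_frame()
        fr.modulus[fr.fiber_mask] = 15.0
        doubled = make_frame(fr.height, 2.0 * fr.modulus,
                             background_mask=fr.background_mask, fiber_mask=fr.fiber_mask)
        a = afm.normalize_modulus(fr, 1000.0)
        b = afm.normalize_modulus(doubled, 1000.0)
        np.testing.assert_allclose(a.modulus, b.modulus, rtol=1e-12)
        assert np.mean(b.modulus[b.background_mask]) == pytest.approx(1000.0)

    def test_bad_background_rejected(self):
        fr = ridge_frame()
        fr.modulus[:] = 0.0
        with pytest.raises(InputError):
            afm.normalize_modulus(fr, 1000.0)
        fr.background_mask = np.zeros_like(fr.background_mask)
        with pytest.raises(MaskError):
            afm.normalize_modulus(fr, 1000.0)


class TestNanodomainStats:
    def _stat_frame(self, values, shape=(60, 60)):
        h = np.full(shape, 10.0)
        m = np.asarray(values, dtype=float).reshape(shape)
        return make_frame(h, m, fiber_mask=np.ones(shape, bool),
                          background_mask=np.zeros(shape, bool))

    def test_estar_av_constant_and_mixture(self):
        fr = self._stat_frame(np.full(3600, 12.5))
        assert afm.estar_av(fr, min_points=100) == pytest.approx(12.5)
        vals = np.concatenate([np.full(1800, 10.0), np.full(1800, 20.0)])
        assert afm.estar_av(self._stat_frame(vals), min_points=100) == pytest.approx(15.0)

    def test_estar_av_insufficient_points(self):
        fr = self._stat_frame(np.full(3600, 12.5))
        with pytest.raises(InsufficientDataError):
            afm.estar_av(fr, min_points=10000)

    def test_roi_split_consistency_exact(self):
        rng = np.random.default_rng(3)
        fr = self._stat_frame(rng.lognormal(np.log(15), 0.2, 3600))
        whole = afm.NanodomainROI(kind="rect", rect=(0, 60, 0, 60))
        left = afm.NanodomainROI(kind="rect", rect=(0, 60, 0, 25))
        right = afm.NanodomainROI(kind="rect", rect=(0, 60, 25, 60))
        mw = afm.estar_av(fr, whole, min_points=100)
        ml = afm.estar_av(fr, left, min_points=100)
        mr = afm.estar_av(fr, right, min_points=100)
        nl, nr = 60 * 25, 60 * 35
        assert mw == pytest.approx((nl * ml + nr * mr) / (nl + nr), rel=1e-12)

    def test_distribution_left_skewed_unimodal(self):
        rng = np.random.default_rng(1)
        vals = 25.0 - rng.lognormal(np.log(8), 0.45, 4096)  # left tail
        s = afm.estar_distribution(self._stat_frame(vals[:3600]), min_points=100)
        assert s.unimodal and not s.excluded
        assert s.skewness < 0

    def test_distribution_constant(self):
        s = afm.estar_distribution(self._stat_frame(np.full(3600, 7.0)), min_points=100)
        assert s.mode == s.mean == 7.0
        assert s.skewness == 0.0 and s.unimodal

    def test_distribution_bimodal_excluded(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(10, 0.5, 1800), rng.normal(30, 0.5, 1800)])
        s = afm.estar_distribution(self._stat_frame(vals), min_points=100)
        assert not s.unimodal and s.excluded

    def test_polygon_roi_mask(self):
        roi = afm.NanodomainROI(kind="polygon",
                                vertices=np.array([[0, 0], [0, 30], [30, 30], [30, 0]]))
        mask = roi.to_mask((60, 60))
        assert mask[5, 5] and not mask[50, 50]


class TestVolumeAndActivity:
    def test_single_pixel_volume(self):
        h = np.zeros((20, 20))
        h[5, 5] = 10.0
        mask = h > 0
        fr = make_frame(h, pixel_size=2.0, background_mask=~mask, fiber_mask=mask)
        assert afm.fiber_volume(fr) == pytest.approx(40.0)

    def test_empty_mask_volume_zero(self):
        fr = ridge_frame()
        assert afm.fiber_volume(fr, np.zeros_like(fr.fiber_mask)) == 0.0

    def test_unleveled_frame_warns(self):
        fr = ridge_frame()
        fr.height += 1.0  # background median now 1 nm
        with pytest.warns(UserWarning, match="unleveled"):
            afm.fiber_volume(fr)

    def test_phantom_volume_within_2pct(self, default_phantom, rendered_phantom):
        height, _, meta = rendered_phantom
        fr = make_frame(height, pixel_size=meta["pixel_size"])
        vol = afm.fiber_volume(fr, height > 0)
        assert vol == pytest.approx(default_phantom.volume_nm3, rel=0.02)

    def test_relative_activity_constant_stack_is_zero(self):
        fr = ridge_frame()
        frames = [make_frame(fr.height, time=float(5 * i), fiber_mask=fr.fiber_mask)
                  for i in range(4)]
        t, act = afm.relative_activity(afm.FrameStack(frames))
        np.testing.assert_allclose(act, 0.0, atol=1e-12)

    def test_relative_activity_one_percent_per_min(self):
        fr = ridge_frame()
        frames = []
        for i in range(5):
            f = make_frame(fr.height * (1 - 0.05 * i), time=float(5 * i),
                           fiber_mask=fr.fiber_mask)
            frames.append(f)
        t, act = afm.relative_activity(afm.FrameStack(frames))
        np.testing.assert_allclose(act, 1.0, rtol=1e-9)  # 5% per 5 min

    def test_zero_initial_sum_rejected(self):
        frames = [make_frame(np.zeros((10, 10)), time=float(i),
                             fiber_mask=np.ones((10, 10), bool)) for i in range(2)]
        with pytest.raises(InputError):
            afm.relative_activity(afm.FrameStack(frames))


class TestScaleSeries:
    def test_basic(self):
        np.testing.assert_allclose(afm.scale_series([10, 15, 20]), [0, 50, 100])

    def test_constant_flagged(self):
        with pytest.raises(DegenerateScaleError):
            afm.scale_series([5, 5, 5])

    @given(st.floats(min_value=-1e3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, offset, gain):
        base = np.array([1.0, 2.0, 5.0, 11.0])
        np.testing.assert_allclose(afm.scale_series(gain * base + offset),
                                   afm.scale_series(base), atol=1e-6)


class TestGainJitterInvariance:
    def test_non_degrading_stack_estar_flat(self, default_phantom):
        from cellodyn import degradation
        scenario = synthetic.DegradationScenario(mode="ablation", ablation_rate_nm=0.0, seed=5)
        stack, truth = synthetic.gen_ablation_stack(default_phantom, scenario)
        records, _ = afm.process_stack(stack)
        est = np.array([r["estar_av"] for r in records if not r["excluded"]])
        # per-frame gains span +/-20%, yet E*_av stays within a few percent
        assert np.ptp(est) / est.mean() < 0.05
        vols = np.array([r["volume_nm3"] for r in records if not r["excluded"]])
        np.testing.assert_allclose(vols / vols[0], 1.0, atol=0.03)
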