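"""Algorithm-I tests: DoG edges, edge tracking, kymographs, cycle metrics.

Expected values for the derived cases are computed by independent oracles:
an explicit-convolution DoG for the step edge, and integer-shift / Radon
orientation scoring for the streak slope.
"""

import numpy as np
import pytest
from skimage.transform import radon

from gcmotility import kymograph as ky
from gcmotility import synthetic as syn


def _dog_oracle_1d(signal, s1, s2):
    """Brute-force DoG: direct convolution with truncated Gaussian kernels."""

    def blur(x, sigma):
        r = int(np.ceil(4 * sigma))
        k = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
        k /= k.sum()
        xp = np.pad(x, r, mode="reflect")
        return np.convolve(xp, k, mode="valid")

    return blur(signal, s1) - blur(signal, s2)


class TestExtractEdges:
    def test_step_edge_localised_within_one_pixel(self):
        frame = np.zeros((40, 100))
        frame[:, 50:] = 100.0
        # Oracle: the brute-force DoG of the analytic step localises the
        # edge at its zero crossing between the two lobes.
        oracle = _dog_oracle_1d(frame[0], 1.0, 3.0)
        sign = np.sign(oracle)
        crossings = np.nonzero(sign[40:60][:-1] * sign[40:60][1:] < 0)[0] + 40
        assert len(crossings) == 1 and abs(crossings[0] - 49.5) <= 1
        edges = ky.extract_edges(frame)
        assert len(np.nonzero(edges[20])[0]) > 0
        resp = ky.dog_response(frame)[20]
        np.testing.assert_allclose(resp, oracle, atol=1e-6)

    def test_constant_image_yields_no_edges(self):
        assert not ky.extract_edges(np.full((30, 30), 42.0)).any()

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            ky.extract_edges(np.zeros((20, 20)), sigma_small=3.0, sigma_large=1.0)

    def test_synthetic_frame_boundary_matches_ground_truth(self, noiseless_flat_stack):
        stack = noiseless_flat_stack
        pixel = stack.config.pixel_um
        for ti in range(0, stack.n_frames, 7):
            edges = ky.extract_edges(stack.frames[ti][0.0])
            true_col = stack.ground_truth.true_edge_um[ti] / pixel
            rows_with_edge = 0
            for r in range(10, 70, 10):
                cols = np.nonzero(edges[r])[0]
                if len(cols):
                    rows_with_edge += 1
                    # The thresholded DoG band spans both lobes (~2-3 px);
                    # sub-pixel localisation is the tracker's job.
                    assert abs(cols.max() - true_col) <= 3.0
            assert rows_with_edge > 0


class TestTrackLeadingEdge:
    def test_noiseless_tracking_within_one_pixel(self, noiseless_flat_stack):
        stack = noiseless_flat_stack
        line = ky.default_sampling_line(stack)
        prof = ky.track_leading_edge(stack, line)
        err = np.abs(prof.positions_um - stack.ground_truth.true_edge_um)
        assert err.max() <= stack.config.pixel_um

    def test_static_edge_gives_constant_profile(self):
        params = syn.MotilityParams(seed=6, n_cycles=1, noise_sd=0.0, lift_profile=None)
        cfg = syn.ImagingConfig(heights_um=(0.0,))
        stack = syn.generate_lamellipodium_stack(params, cfg)
        frozen = [dict(stack.frames[0]) for _ in range(10)]
        static = syn.ImageStackSequence(frames=frozen, config=cfg)
        prof = ky.track_leading_edge(static, ky.default_sampling_line(static))
        assert np.ptp(prof.positions_um) == pytest.approx(0.0, abs=1e-9)

    def test_dropout_frame_interpolated_as_neighbour_mean(self, noiseless_flat_stack):
        stack = noiseless_flat_stack
        cfg = stack.config
        frames = [dict(f) for f in stack.frames]
        frames[5] = {0.0: np.full(cfg.image_shape, cfg.background_level)}
        broken = syn.ImageStackSequence(frames=frames, config=cfg)
        prof = ky.track_leading_edge(broken, ky.default_sampling_line(broken))
        assert prof.interpolated[5]
        assert prof.positions_um[5] == pytest.approx(
            0.5 * (prof.positions_um[4] + prof.positions_um[6]), abs=1e-9
        )

    def test_all_blank_movie_fails(self):
        cfg = syn.ImagingConfig(heights_um=(0.0,), image_shape=(40, 60))
        frames = [{0.0: np.full((40, 60), 7.0)} for _ in range(5)]
        blank = syn.ImageStackSequence(frames=frames, config=cfg)
        line = ky.SamplingLine((0.0, 20.0), (59.0, 20.0))
        with pytest.raises(RuntimeError, match="no edge"):
            ky.track_leading_edge(blank, line)


class TestKymographConstruction:
    def test_constant_movie_gives_constant_matrix(self):
        cfg = syn.ImagingConfig(heights_um=(0.0,), image_shape=(40, 60))
        frames = [{0.0: np.full((40, 60), 5.0)} for _ in range(8)]
        stack = syn.ImageStackSequence(frames=frames, config=cfg)
        kym = ky.build_kymograph(stack, ky.SamplingLine((0.0, 20.0), (59.0, 20.0)))
        assert np.ptp(kym.data) == pytest.approx(0.0, abs=1e-12)

    def test_shape_is_line_length_by_frames(self):
        cfg = syn.ImagingConfig(heights_um=(0.0,), image_shape=(50, 80))
        frames = [{0.0: np.zeros((50, 80))} for _ in range(11)]
        stack = syn.ImageStackSequence(frames=frames, config=cfg)
        kym = ky.build_kymograph(stack, ky.SamplingLine((0.0, 25.0), (63.0, 25.0)))
        assert kym.data.shape == (64, 11)

    def test_line_validation(self):
        with pytest.raises(ValueError, match="20 px"):
            ky.SamplingLine((0.0, 0.0), (5.0, 0.0))
        line = ky.SamplingLine((0.0, 10.0), (100.0, 10.0))
        with pytest.raises(ValueError, match="outside"):
            line.validate_inside((20, 50))


def _make_streak_kymograph(n_pos, n_t, slope_um_s, dx=0.1, dt=5.0, seed=0):
    """Dark streaks translating at a known rate on a bright band."""
    rng = np.random.default_rng(seed)
    centers = np.sort(rng.uniform(0, n_pos * dx * 2, 8))
    p = (np.arange(n_pos) + 0.5) * dx
    data = np.empty((n_pos, n_t))
    for j in range(n_t):
        x = p + slope_um_s * j * dt
        dips = sum(np.exp(-0.5 * ((x - c) / 0.15) ** 2) for c in centers)
        data[:, j] = 100.0 - 40.0 * np.clip(dips, 0, 1)
    return ky.Kymograph(data=data, spatial_step_um=dx, time_step_s=dt)


def _integer_shift_oracle(kym, rates):
    """Independent streak-slope oracle: signed integer-pixel shift scoring."""
    best, best_v = -np.inf, None
    n_pos, n_t = kym.data.shape
    for v in rates:
        shifts = np.round(
            v * np.arange(n_t) * kym.time_step_s / kym.spatial_step_um
        ).astype(int)
        lo = -min(0, shifts.min())
        length = n_pos - (max(0, shifts.max()) + lo)
        if length < 8:
            continue
        acc = np.zeros(length)
        for j in range(n_t):
            s = lo + shifts[j]
            acc += kym.data[s : s + length, j]
        score = np.var(acc / n_t)
        if score > best:
            best, best_v = score, abs(v)
    return best_v


class TestRetrogradeFlow:
    def test_matches_integer_shift_oracle_on_small_kymographs(self):
        for true_v in (0.04, 0.08, 0.12):
            kym = _make_streak_kymograph(64, 8, true_v, seed=3)
            window = [(0.0, 7 * kym.time_step_s)]
            rate, _ = ky.measure_retrograde_flow(kym, window)
            oracle = _integer_shift_oracle(kym, np.arange(-0.24, 0.25, 0.02))
            assert rate == pytest.approx(true_v, abs=0.005)
            assert abs(rate - oracle) <= 0.02  # oracle grid is coarser

    def test_matches_radon_orientation_on_small_kymograph(self):
        kym = _make_streak_kymograph(64, 64, 0.03, dt=1.0, seed=4)
        rate, _ = ky.measure_retrograde_flow(
            kym, [(0.0, 63.0)], max_rate_um_s=0.1, step_um_s=0.0025
        )
        d = kym.data - kym.data.mean()
        angles = np.linspace(45.0, 135.0, 361)
        sino = radon(d, theta=angles)
        ang = angles[np.argmax(sino.var(axis=0))]
        # Streak line: position change per column = tan(angle from vertical).
        slope_px = np.tan(np.deg2rad(ang - 90.0))
        radon_rate = abs(slope_px) * kym.spatial_step_um / kym.time_step_s
        assert rate == pytest.approx(radon_rate, abs=0.01)
        assert rate == pytest.approx(0.03, abs=0.005)

    def test_static_streaks_give_zero_rate(self):
        kym = _make_streak_kymograph(64, 8, 0.0, seed=5)
        rate, _ = ky.measure_retrograde_flow(kym, [(0.0, 35.0)])
        assert rate == pytest.approx(0.0, abs=0.0026)

    def test_rate_doubles_with_streak_slope(self):
        r1, _ = ky.measure_retrograde_flow(
            _make_streak_kymograph(80, 8, 0.05, seed=6), [(0.0, 35.0)]
        )
        r2, _ = ky.measure_retrograde_flow(
            _make_streak_kymograph(80, 8, 0.10, seed=6), [(0.0, 35.0)]
        )
        assert r2 == pytest.approx(2 * r1, rel=0.1)

    def test_flat_windows_are_skipped_and_all_flat_fails(self):
        kym = ky.Kymograph(np.full((40, 20), 3.0), 0.1, 5.0)
        with pytest.raises(RuntimeError, match="contrast"):
            ky.measure_retrograde_flow(kym, [(0.0, 50.0)])


class TestCycleMetrics:
    def test_period_recovery_on_sawtooth(self):
        params = syn.MotilityParams(period_s=90.0, seed=8, n_cycles=4, noise_sd=0.0, lift_profile=None)
        stack = syn.generate_lamellipodium_stack(params, syn.ImagingConfig(heights_um=(0.0,)))
        prof = ky.track_leading_edge(stack, ky.default_sampling_line(stack))
        period, intervals = ky.measure_period(prof)
        assert period == pytest.approx(90.0, abs=5.0)  # one frame interval
        assert len(intervals) >= 2

    def test_monotone_profile_has_no_cycles(self):
        prof = ky.EdgeProfile(np.linspace(0, 10, 50), np.arange(50) * 5.0)
        with pytest.raises(ky.NoCyclesError):
            ky.measure_period(prof)
        with pytest.raises(ky.NoCyclesError):
            ky.measure_persistence(prof)

    def test_persistence_recovery_on_sawtooth(self):
        params = syn.MotilityParams(
            persistence_um=1.5, period_s=90.0, seed=9, n_cycles=4, noise_sd=0.0, lift_profile=None
        )
        cfg = syn.ImagingConfig(heights_um=(0.0,), frame_interval_s=2.0)
        stack = syn.generate_lamellipodium_stack(params, cfg)
        prof = ky.track_leading_edge(stack, ky.default_sampling_line(stack))
        dl, per_cycle = ky.measure_persistence(prof)
        assert dl == pytest.approx(1.5, abs=0.1)
        assert len(per_cycle) >= 2

    def test_metrics_invariant_to_offset_and_gain(self, control_stack_h0):
        stack = control_stack_h0
        line = ky.default_sampling_line(stack)
        base_prof = ky.track_leading_edge(stack, line)
        scaled = syn.ImageStackSequence(
            frames=[{h: 3.0 * p + 50.0 for h, p in f.items()} for f in stack.frames],
            config=stack.config,
        )
        prof2 = ky.track_leading_edge(scaled, line)
        np.testing.assert_allclose(prof2.positions_um, base_prof.positions_um, atol=1e-9)
        k1 = ky.build_kymograph(stack, line)
        k2 = ky.build_kymograph(scaled, line)
        w = ky.retraction_windows(base_prof)
        r1, _ = ky.measure_retrograde_flow(k1, w)
        r2, _ = ky.measure_retrograde_flow(k2, w)
        assert r2 == pytest.approx(r1, abs=1e-6)

    def test_period_invariant_under_time_reversal(self, control_stack_h0):
        stack = control_stack_h0
        line = ky.default_sampling_line(stack)
        prof = ky.track_leading_edge(stack, line)
        rev = syn.ImageStackSequence(frames=stack.frames[::-1], config=stack.config)
        prof_r = ky.track_leading_edge(rev, line)
        t, _ = ky.measure_period(prof)
        tr, _ = ky.measure_period(prof_r)
        assert tr == pytest.approx(t, rel=0.06)
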