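"""Force pipeline tests: Hooke conversion, compensation, event typing, rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcmotility import force as fo
from gcmotility import synthetic as syn

K = (0.10, 0.08)  # trap stiffness, pN/nm


class TestDisplacementToForce:
    @pytest.mark.parametrize(
        "deflection, expected",
        [
            ((100.0, 0.0, 0.0), (10.0, 0.0, 0.0)),
            ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
            ((0.0, 0.0, 125.0), (0.0, 0.0, 10.0)),
        ],
    )
    def test_hookean_examples(self, deflection, expected):
        np.testing.assert_allclose(fo.displacement_to_force(deflection, K), expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-500, 500), min_size=3, max_size=3),
        st.floats(0.1, 10.0),
    )
    def test_linearity_under_scaling(self, d, scale):
        f1 = fo.displacement_to_force(d, K)
        f2 = fo.displacement_to_force(np.asarray(d) * scale, K)
        np.testing.assert_allclose(f2, scale * f1, rtol=1e-12, atol=1e-9)

    def test_nonpositive_stiffness_rejected(self):
        with pytest.raises(ValueError):
            fo.displacement_to_force((1.0, 0.0, 0.0), (0.0, 0.08))


class TestCompensateFeedback:
    def test_frozen_stage_identity(self):
        cfg = syn.BeadSimConfig(
            thermal_sd_nm=5.0, seed=3, event_schedule=[syn.BeadEvent(1.0, "+x", 10.0, 5.0)]
        )
        tr = syn.generate_bead_trace(cfg)
        assert not tr.stage_xy_nm.any()  # never crossed 200 nm
        comp, flags = fo.compensate_feedback(tr)
        np.testing.assert_array_equal(comp, tr.qpd_xyz_nm[:, :2])
        assert flags == []

    def test_threshold_reached_at_three_four_five_triangle(self):
        assert np.hypot(120.0, 160.0) == pytest.approx(200.0)

    def test_compensated_push_is_straight_line(self):
        cfg = syn.BeadSimConfig(
            thermal_sd_nm=0.0, event_schedule=[syn.BeadEvent(1.0, "+x", 50.0, 20.0)]
        )
        tr = syn.generate_bead_trace(cfg)
        comp, _ = fo.compensate_feedback(tr)
        sel = (tr.t_s >= 2.0) & (tr.t_s <= 20.0)
        slope = np.polyfit(tr.t_s[sel], comp[sel, 0], 1)[0]
        assert slope == pytest.approx(50.0, abs=2.0)

    def test_unexplained_stage_jump_flagged(self):
        cfg = syn.BeadSimConfig(thermal_sd_nm=0.0, duration_s=2.0)
        tr = syn.generate_bead_trace(cfg)
        tr.stage_xy_nm[20:, 0] += 300.0  # corrupt: jump without crossing
        _, flags = fo.compensate_feedback(tr)
        assert any("without threshold crossing" in f for f in flags)


def _trace_with(schedule, thermal=0.0, seed=0):
    cfg = syn.BeadSimConfig(thermal_sd_nm=thermal, seed=seed, event_schedule=schedule)
    return fo.force_trace(syn.generate_bead_trace(cfg))


class TestEventClassification:
    def test_vertical_push_rule(self):
        ft = _trace_with([syn.BeadEvent(2.0, "+z", 25.0, 5.0)])
        ev = fo.analyze_events(ft, away_vector=(1.0, 0.0, 1.0))
        assert [e.behaviour for e in ev] == ["VP"]
        assert ev[0].max_force_pn == pytest.approx(10.0, abs=1e-6)

    def test_lateral_retraction_rule(self):
        ft = _trace_with([syn.BeadEvent(2.0, "-x", 16.0, 5.0)])
        ev = fo.analyze_events(ft, away_vector=(1.0, 0.0, 0.0))
        assert [e.behaviour for e in ev] == ["LR"]
        assert ev[0].max_force_pn == pytest.approx(8.0, abs=1e-6)

    def test_all_four_behaviours_from_one_schedule(self):
        sched = [
            syn.BeadEvent(2.0, "+z", 12.0, 5.0),
            syn.BeadEvent(12.0, "-z", 12.0, 5.0),
            syn.BeadEvent(22.0, "+x", 14.0, 5.0),
            syn.BeadEvent(32.0, "-x", 14.0, 5.0),
        ]
        ev = fo.analyze_events(_trace_with(sched), away_vector=(1.0, 0.0, 1.0))
        assert [e.behaviour for e in ev] == ["VP", "VR", "LP", "LR"]

    def test_classification_invariant_to_force_scale(self):
        small = _trace_with([syn.BeadEvent(2.0, "+x", 6.0, 5.0)])
        big = _trace_with([syn.BeadEvent(2.0, "+x", 30.0, 5.0)])
        w_small = fo.detect_events(small)[0]
        w_big = fo.detect_events(big)[0]
        assert fo.classify_event(small, w_small) == fo.classify_event(big, w_big) == "LP"

    def test_subfloor_window_is_no_event(self):
        ft = _trace_with([syn.BeadEvent(2.0, "+x", 1.0, 3.0)])  # peaks at 0.3 pN
        assert fo.detect_events(ft) == []
        assert fo.classify_event(ft, (0.0, 5.0)) is None

    def test_two_events_keep_separate_maxima(self):
        sched = [
            syn.BeadEvent(2.0, "+x", 10.0, 5.0),  # 50 nm -> 5 pN
            syn.BeadEvent(12.0, "+x", 16.0, 5.0),  # 80 nm -> 8 pN
        ]
        ev = fo.analyze_events(_trace_with(sched), away_vector=(1.0, 0.0, 0.0))
        assert [round(e.max_force_pn, 6) for e in ev] == [5.0, 8.0]


class TestProtrusionRate:
    def test_identical_noiseless_ramps_recover_exact_rate(self):
        paths = []
        for seed in (0, 1):
            cfg = syn.BeadSimConfig(
                thermal_sd_nm=0.0,
                seed=seed,
                event_schedule=[syn.BeadEvent(2.0, "+x", 100.0, 8.0)],
                duration_s=14.0,
            )
            comp, _ = fo.compensate_feedback(syn.generate_bead_trace(cfg))
            paths.append(comp)
        res = fo.protrusion_rate(paths, dt_s=0.05)
        assert res.rate_nm_s == pytest.approx(100.0, abs=0.5)
        assert res.n_used == 2

    def test_mixed_rates_average_between_bounds(self):
        paths = []
        for seed, speed in enumerate((30.0, 50.0)):
            cfg = syn.BeadSimConfig(
                thermal_sd_nm=0.0,
                seed=seed,
                event_schedule=[syn.BeadEvent(2.0, "+x", speed, 10.0)],
                duration_s=16.0,
            )
            comp, _ = fo.compensate_feedback(syn.generate_bead_trace(cfg))
            paths.append(comp)
        res = fo.protrusion_rate(paths, dt_s=0.05)
        assert 30.0 <= res.rate_nm_s <= 50.0

    def test_round_trip_recovery_within_5pct_at_thermal_20nm(self):
        for speed in (50.0, 100.0):
            paths = []
            for seed in range(1, 6):
                cfg = syn.BeadSimConfig(
                    thermal_sd_nm=20.0,
                    seed=seed,
                    event_schedule=[syn.BeadEvent(2.0, "+x", speed, 8.0)],
                    duration_s=14.0,
                )
                comp, _ = fo.compensate_feedback(syn.generate_bead_trace(cfg))
                paths.append(comp)
            res = fo.protrusion_rate(paths, dt_s=0.05)
            assert res.rate_nm_s == pytest.approx(speed, rel=0.05)

    def test_flat_traces_excluded_then_failure(self):
        flat = [np.zeros((200, 2)), np.zeros((200, 2))]
        with pytest.raises(RuntimeError, match="rising phase"):
            fo.protrusion_rate(flat, dt_s=0.05)
        with pytest.raises(ValueError, match="at least 2"):
            fo.protrusion_rate([np.zeros((200, 2))], dt_s=0.05)
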