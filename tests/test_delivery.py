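import numpy as np
import pytest

from dose4d import (
    BeamGeometry,
    DeliveryMode,
    EllipseFit,
    MLCAperture,
    aperture_to_weights,
    bin_trajectory,
    deliver,
    generate_trajectory,
    project_shift,
    track_aperture,
)
from dose4d.delivery import TICK_S, TreatmentPlan, conformal_aperture


def make_test_plan(mu_per_beam=20.0, n_beams=2, n_bixels=(8, 8)):
    beams = [BeamGeometry(g, n_bixels=n_bixels) for g in (0.0, 40.0)[:n_beams]]
    segs = []
    for b in beams:
        ap = MLCAperture(np.full(n_bixels[1], -10.0), np.full(n_bixels[1], 10.0),
                         mu_per_beam)
        segs.append([ap])
    return TreatmentPlan(beams, segs, 0, "PTV", target_position=np.zeros(3))


def annotated_trajectory(a_si=7.0, duration=120.0):
    fit = EllipseFit(a_si, 0.0, a_si, 1.0, 0.2, 0.0)
    return bin_trajectory(generate_trajectory(fit, 5.0, 25.0, duration), 10)


class TestProjection:
    def test_si_maps_to_leaf_travel_everywhere(self):
        for g in (0, 40, 90, 200):
            s = project_shift(np.array([0.0, 0.0, 3.0]), BeamGeometry(g))
            np.testing.assert_allclose(s, [3.0, 0.0], atol=1e-12)

    def test_displacement_along_beam_axis_vanishes(self):
        b = BeamGeometry(0.0)  # beam along +LR
        np.testing.assert_allclose(project_shift(np.array([5.0, 0, 0]), b),
                                   [0.0, 0.0], atol=1e-12)

    def test_transverse_component_rotates_with_gantry(self):
        ap_shift = np.array([0.0, 2.0, 0.0])
        full = project_shift(ap_shift, BeamGeometry(0.0))
        none = project_shift(ap_shift, BeamGeometry(90.0))
        np.testing.assert_allclose(full, [0.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(none, [0.0, 0.0], atol=1e-12)


class TestTrackAperture:
    def test_zero_shift_identity(self):
        beam = BeamGeometry(0.0, n_bixels=(8, 8))
        ap = MLCAperture(np.full(8, -7.0), np.full(8, 7.0), 1.0)
        out, clamped = track_aperture(ap, np.zeros(2), beam)
        np.testing.assert_array_equal(out.left, ap.left)
        np.testing.assert_array_equal(out.right, ap.right)
        assert not clamped

    def test_whole_leaf_shift_translates_pattern(self):
        beam = BeamGeometry(0.0, n_bixels=(8, 8))
        left = np.full(8, 0.0)
        right = np.full(8, 0.0)
        left[2:5] = -6.0
        right[2:5] = 6.0
        ap = MLCAperture(left, right)
        out, clamped = track_aperture(ap, np.array([0.0, 2 * 5.0]), beam)
        np.testing.assert_array_equal(out.left[4:7], left[2:5])
        np.testing.assert_array_equal(out.right[4:7], right[2:5])
        assert np.all(out.right[:4] == out.left[:4])
        assert not clamped

    def test_integer_leaf_shift_matches_weight_translation(self):
        """For integer-leaf shifts the tracked weights equal the static
        weights translated on the bixel grid (leaf travel shifted by whole
        bixels too, for a grid-aligned comparison)."""
        beam = BeamGeometry(0.0, n_bixels=(8, 6))
        left = np.full(6, 0.0)
        right = np.full(6, 0.0)
        left[1:4] = -7.5
        right[1:4] = 7.5
        ap = MLCAperture(left, right)
        w0 = aperture_to_weights(ap, beam).reshape(6, 8)
        shifted, _ = track_aperture(ap, np.array([5.0, 5.0]), beam)  # 1 bixel, 1 leaf
        w1 = aperture_to_weights(shifted, beam).reshape(6, 8)
        np.testing.assert_allclose(w1[1:, 1:], w0[:-1, :-1], atol=1e-12)

    def test_out_of_travel_clamped_and_flagged(self):
        beam = BeamGeometry(0.0, n_bixels=(4, 4))
        ap = MLCAperture(np.full(4, -8.0), np.full(4, 8.0))
        out, clamped = track_aperture(ap, np.array([100.0, 0.0]), beam)
        assert clamped
        assert np.all(out.right <= beam.bixel_edges_x()[-1] + 1e-9)


class TestDeliver:
    def test_mu_per_tick_value(self):
        plan = make_test_plan()
        assert plan.dose_rate_mu_min / 60.0 * TICK_S == pytest.approx(0.36667, abs=1e-4)

    def test_mu_conservation_per_beam(self):
        plan = make_test_plan(mu_per_beam=17.3)
        traj = annotated_trajectory()
        ticks = deliver(plan, traj, DeliveryMode.STATIC)
        for b in range(2):
            total = sum(t.mu for t in ticks if t.beam_index == b)
            assert total == pytest.approx(17.3, abs=1e-9)

    def test_static_apertures_equal_planned(self):
        plan = make_test_plan()
        traj = annotated_trajectory()
        for mode in (DeliveryMode.STATIC, DeliveryMode.UNTRACKED):
            ticks = deliver(plan, traj, mode)
            for t in ticks:
                if t.mu > 0:
                    seg = plan.segments[t.beam_index][0]
                    np.testing.assert_array_equal(t.aperture.left, seg.left)
                    np.testing.assert_array_equal(t.aperture.right, seg.right)

    def test_tracked_zero_amplitude_equals_static(self):
        plan = make_test_plan()
        flat = EllipseFit(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, True)
        traj = bin_trajectory(generate_trajectory(flat, 5.0, 25.0, 120.0), 10)
        # zero-amplitude target at the planning position
        ticks_s = deliver(plan, traj, DeliveryMode.STATIC)
        ticks_t = deliver(plan, traj, DeliveryMode.TRACKED)
        assert len(ticks_s) == len(ticks_t)
        for a, b in zip(ticks_s, ticks_t):
            np.testing.assert_array_equal(a.aperture.left, b.aperture.left)
            np.testing.assert_array_equal(a.aperture.right, b.aperture.right)
            assert a.mu == b.mu and a.phase_bin == b.phase_bin

    def test_beam_off_gaps_carry_zero_mu(self):
        plan = make_test_plan()
        traj = annotated_trajectory()
        ticks = deliver(plan, traj, DeliveryMode.STATIC, gap_s=2.0)
        gap_ticks = [t for t in ticks if t.mu == 0]
        assert len(gap_ticks) == 50  # one 2 s gap between the two beams
        assert all(t.aperture.is_closed() for t in gap_ticks)

    def test_trajectory_underrun_raises(self):
        plan = make_test_plan(mu_per_beam=500.0)
        traj = annotated_trajectory(duration=20.0)
        with pytest.raises(ValueError, match="underrun"):
            deliver(plan, traj, DeliveryMode.STATIC)

    def test_unannotated_trajectory_rejected(self):
        plan = make_test_plan()
        fit = EllipseFit(0, 0, 7, 1, 0, 0)
        with pytest.raises(ValueError, match="annotated"):
            deliver(plan, generate_trajectory(fit, 5.0, 25.0, 60.0),
                    DeliveryMode.STATIC)


class TestConformalAperture:
    def test_sphere_silhouette_rounded_out(self, small_phases):
        from dose4d.structures import expand_margin

        ptv = expand_margin(small_phases.gtv[0], 1.0, "PTV")
        beam = BeamGeometry(0.0, n_bixels=(10, 10))
        ap = conformal_aperture(ptv, beam)
        open_rows = ap.right > ap.left
        assert open_rows.any()
        # widest opening in the central rows
        widths = ap.right - ap.left
        assert widths.max() == widths[open_rows][len(widths[open_rows]) // 2]

    def test_open_area_monotone_in_margin(self, small_phases):
        from dose4d.structures import expand_margin

        beam = BeamGeometry(40.0, n_bixels=(10, 10))
        areas = []
        for m in (1.0, 3.0, 5.0):
            ptv = expand_margin(small_phases.gtv[0], m, "PTV")
            w = aperture_to_weights(conformal_aperture(ptv, beam), beam)
            areas.append(w.sum())
        assert areas[0] < areas[1] < areas[2]


def test_plan_json_roundtrip(tmp_path):
    plan = make_test_plan(mu_per_beam=33.3)
    path = tmp_path / "plan.json"
    plan.to_json(path)
    back = TreatmentPlan.from_json(path)
    assert back.total_mu == pytest.approx(plan.total_mu)
    assert back.planning_phase == plan.planning_phase
    np.testing.assert_array_equal(back.segments[0][0].left, plan.segments[0][0].left)
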