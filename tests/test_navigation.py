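"""Endpoint indices, kinematics, segmentation and strategy metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import saltnav as sn
from saltnav import (AssayCounts, PlateGeometry, StateTrack, chemotaxis_index,
                     count_endpoint_areas, curving_rate, field_from_function,
                     heading_and_speed, immobility_index, per_plate_aggregate,
                     pirouette_index, segment_pirouettes, smooth_positions,
                     weathervane_index, wrap_angle)
from saltnav.trajectory import PIROUETTE, RUN

from conftest import make_track


class TestChemotaxisIndex:
    @pytest.mark.parametrize("counts,expected", [
        (AssayCounts(n_a=0, n_b=80, n_o=20, n_total=100), 1.0),
        (AssayCounts(n_a=80, n_b=0, n_o=20, n_total=100), -1.0),
        (AssayCounts(n_a=10, n_b=50, n_o=10, n_total=70), 40 / 60),
    ])
    def test_printed_formula(self, counts, expected):
        assert chemotaxis_index(counts) == pytest.approx(expected)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 20))
    def test_swapping_areas_negates_and_bounds(self, n_a, n_b, n_o):
        total = n_a + n_b + n_o + 5
        ci = chemotaxis_index(AssayCounts(n_a=n_a, n_b=n_b, n_o=n_o,
                                          n_total=total))
        swapped = chemotaxis_index(AssayCounts(n_a=n_b, n_b=n_a, n_o=n_o,
                                               n_total=total))
        assert swapped == pytest.approx(-ci)
        assert -1.0 <= ci <= 1.0

    def test_all_animals_immobile_is_undefined(self):
        with pytest.raises(ValueError):
            chemotaxis_index(AssayCounts(n_a=0, n_b=0, n_o=30, n_total=30))


class TestImmobilityIndex:
    def test_fraction_mode(self):
        assert immobility_index(AssayCounts(0, 0, 0, 50)) == 0.0
        assert immobility_index(AssayCounts(0, 0, 20, 100)) == pytest.approx(0.2)

    def test_strict_mode_reproduces_literal_difference(self):
        assert immobility_index(AssayCounts(0, 0, 20, 100), strict=True) == -80.0


class TestEndpointAreas:
    def test_all_at_block_b_centre(self, default_geometry):
        pos = np.tile(default_geometry.block_center_b, (12, 1))
        c = count_endpoint_areas(pos, default_geometry)
        assert (c.n_b, c.n_a, c.n_total) == (12, 0, 12)

    def test_origin_in_start_ellipse(self, default_geometry):
        c = count_endpoint_areas([(0.0, 0.0)], default_geometry)
        assert c.n_o == 1 and c.n_total == 1

    def test_area_boundary_is_strict_interior(self, default_geometry):
        bx, by = default_geometry.block_center_b
        inside = count_endpoint_areas([(bx - 19.999, by)], default_geometry)
        outside = count_endpoint_areas([(bx - 20.001, by)], default_geometry)
        assert inside.n_b == 1 and outside.n_b == 0

    def test_empty_input(self, default_geometry):
        c = count_endpoint_areas(np.empty((0, 2)), default_geometry)
        assert (c.n_a, c.n_b, c.n_o, c.n_total) == (0, 0, 0, 0)


class TestKinematics:
    def test_smoothing_straight_line_unchanged(self, straight_track):
        sm = smooth_positions(straight_track, 5)
        assert np.allclose(sm.positions, straight_track.positions, atol=1e-12)

    def test_smoothing_reduces_zigzag_amplitude(self):
        n = 41
        zig = np.column_stack([0.1 * np.arange(n),
                               0.5 * (-1.0) ** np.arange(n)])
        sm = smooth_positions(make_track(zig), 3)
        # moving-average gain of a period-2 oscillation over 3 samples: 1/3
        interior = slice(1, n - 1)
        assert np.allclose(np.abs(sm.positions[interior, 1]), 0.5 / 3,
                           atol=1e-12)

    def test_smoothing_window_one_is_identity(self, straight_track):
        assert smooth_positions(straight_track, 1) is straight_track

    def test_smoothing_window_validation(self, straight_track):
        with pytest.raises(ValueError):
            smooth_positions(straight_track, 4)
        with pytest.raises(ValueError):
            smooth_positions(straight_track, 63)

    def test_heading_and_speed_eastward(self, straight_track):
        bearing, speed, signed = heading_and_speed(straight_track)
        assert np.allclose(bearing[:-1], 0.0, atol=1e-9)
        assert np.allclose(speed[:-1], 100.0)
        assert np.allclose(signed[:-1], 100.0)

    def test_stationary_speed_zero_bearing_undefined(self):
        track = make_track(np.zeros((5, 2)))
        bearing, speed, _ = heading_and_speed(track)
        assert np.all(np.isnan(bearing[:-1]))
        assert np.allclose(speed[:-1], 0.0)

    def test_square_path_bearings(self):
        square = make_track([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]])
        bearing, _, _ = heading_and_speed(square)
        assert np.allclose(bearing[:-1], [0.0, 90.0, 180.0, -90.0])

    def test_signed_velocity_from_reversal_flags(self, straight_track):
        flags = np.zeros(straight_track.n, dtype=bool)
        flags[3] = True
        _, _, signed = heading_and_speed(straight_track, reversal_flags=flags)
        assert signed[3] == pytest.approx(-100.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            heading_and_speed(make_track([[0.0, 0.0]]))

    def test_curving_rate_straight_is_zero(self, straight_track):
        c = curving_rate(straight_track)
        assert np.allclose(c[1:-1], 0.0, atol=1e-9)

    def test_curving_rate_on_circle(self):
        r = 2.0
        ang = np.linspace(0, 2 * np.pi, 120)
        circ = make_track(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
        c = curving_rate(circ)
        # CCW circle: constant 360 / (2 pi r) deg/mm (chord approximation)
        expected = 360.0 / (2 * np.pi * r)
        assert np.allclose(c[1:-1], expected, rtol=5e-4)
        mirrored = make_track(np.column_stack([circ.positions[:, 0],
                                               -circ.positions[:, 1]]))
        assert np.allclose(curving_rate(mirrored)[1:-1], -expected, rtol=5e-4)


class TestSegmentation:
    def test_straight_path_has_no_bouts(self, straight_track):
        st_ = segment_pirouettes(straight_track)
        assert st_.bouts == []
        assert not np.any(st_.labels == PIROUETTE)

    def test_single_flip_yields_one_bout(self):
        xs = np.concatenate([0.1 * np.arange(20),
                             0.1 * 19 - 0.1 * np.arange(1, 20)])
        track = make_track(np.column_stack([xs, np.zeros(39)]))
        st_ = segment_pirouettes(track)
        assert len(st_.bouts) == 1
        start, end = st_.bouts[0]
        assert start <= 20 <= end + 1       # flip is at sample 20
        assert st_.labels[20] == PIROUETTE or st_.labels[19] == PIROUETTE

    def test_two_flips_within_merge_gap_form_one_bout(self):
        # flip at sample 10 and again at sample 13 (3 s apart < 8 s gap)
        xs = [0.1 * i for i in range(11)]
        xs += [xs[-1] - 0.1 * i for i in range(1, 4)]
        xs += [xs[-1] + 0.1 * i for i in range(1, 11)]
        track = make_track(np.column_stack([xs, np.zeros(len(xs))]))
        st_ = segment_pirouettes(track, merge_gap=8.0)
        assert len(st_.bouts) == 1

    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            sn.Trajectory("bad", [0.0, 1.0, 3.0],
                          [[0, 0], [1, 0], [2, 0]])


def _make_state(labels):
    return StateTrack(np.asarray(labels, dtype=np.int8))


class TestPirouetteIndex:
    def test_equal_probabilities_give_zero(self):
        labels = np.array([PIROUETTE] + [RUN] * 9 + [PIROUETTE] + [RUN] * 9)
        dcdt = np.array([-0.1] * 10 + [0.1] * 10)
        times = np.arange(100.0, 120.0)
        res = pirouette_index([_make_state(labels)], [dcdt], [times])
        assert res.pirouette_index == pytest.approx(0.0)

    def test_constructed_contrast(self):
        # P_neg = 0.3, P_pos = 0.1 by construction -> index 0.2
        labels = np.array([PIROUETTE] * 3 + [RUN] * 7
                          + [PIROUETTE] * 1 + [RUN] * 9)
        dcdt = np.array([-0.2] * 10 + [0.2] * 10)
        times = np.arange(100.0, 120.0)
        res = pirouette_index([_make_state(labels)], [dcdt], [times])
        assert res.pirouette_index == pytest.approx(0.2)
        assert (res.p_pirouette_neg, res.p_pirouette_pos) == (0.3, 0.1)

    def test_single_sign_rank_is_undefined(self):
        labels = np.array([RUN] * 10)
        dcdt = np.full(10, 0.05)
        with pytest.raises(ValueError, match="empty"):
            pirouette_index([_make_state(labels)], [dcdt],
                            [np.arange(100.0, 110.0)])

    def test_matches_brute_force_counting(self):
        """Index equals direct per-sample counting on a random instance,
        honouring the range limit, window and zero-exclusion."""
        rng = np.random.default_rng(5)
        n = 600
        labels = rng.choice([RUN, PIROUETTE], n, p=[0.85, 0.15])
        dcdt = rng.normal(0, 0.3, n)
        times = np.arange(n, dtype=float)
        res = pirouette_index([_make_state(labels)], [dcdt], [times],
                              range_limit=0.3, window=(40.0, 540.0))
        sel = [(l, d) for l, d, t in zip(labels, dcdt, times)
               if 40 <= t <= 540 and abs(d) <= 0.3 and d != 0]
        p_neg = np.mean([l == PIROUETTE for l, d in sel if d < 0])
        p_pos = np.mean([l == PIROUETTE for l, d in sel if d > 0])
        assert res.pirouette_index == pytest.approx(p_neg - p_pos, abs=1e-12)
        assert -1.0 <= res.pirouette_index <= 1.0


class TestWeathervaneIndex:
    def _series(self, slope, noise_sd, n=500, seed=0):
        rng = np.random.default_rng(seed)
        dcdn = rng.uniform(-1.5, 1.5, n)
        curv = np.empty(n)
        curv[0] = np.nan
        curv[1:] = slope * dcdn[:-1]        # turn i responds to step i-1
        if noise_sd:
            curv[1:] += rng.normal(0, noise_sd, n - 1)
        times = np.arange(100.0, 100.0 + n)
        return [curv], [dcdn], [_make_state(np.full(n, RUN))], [times]

    def test_noiseless_regression_recovers_slope(self):
        res = weathervane_index(*self._series(2.0, 0.0),
                                window=(100.0, 600.0))
        assert res.weathervane_index == pytest.approx(2.0, abs=1e-9)

    def test_noisy_slope_within_confidence_interval(self):
        res = weathervane_index(*self._series(2.0, 5.0, seed=1),
                                window=(100.0, 600.0))
        assert abs(res.weathervane_index - 2.0) < 1.96 * res.weathervane_stderr * 1.5

    def test_scaling_regressor_scales_slope_inversely(self):
        curv, dcdn, states, times = self._series(2.0, 0.0)
        res = weathervane_index([curv[0]], [dcdn[0] / 4.0], states, times,
                                window=(100.0, 600.0))
        assert res.weathervane_index == pytest.approx(8.0, abs=1e-6)

    def test_degenerate_regressor_rejected(self):
        n = 100
        const = [np.full(n, 0.5)]
        curv = [np.ones(n)]
        with pytest.raises(ValueError, match="variance"):
            weathervane_index(curv, const, [_make_state(np.full(n, RUN))],
                              [np.arange(100.0, 100.0 + n)],
                              window=(100.0, 300.0))

    def test_pirouette_samples_excluded(self):
        curv, dcdn, _, times = self._series(2.0, 0.0)
        labels = np.full(curv[0].size, RUN)
        labels[200:300] = PIROUETTE
        curv[0][200:300] = 500.0            # pirouette turns are wild
        res = weathervane_index(curv, dcdn, [_make_state(labels)], times,
                                window=(100.0, 600.0))
        assert res.weathervane_index == pytest.approx(2.0, abs=1e-9)


class TestAggregation:
    def test_single_plate(self):
        mean, sem = per_plate_aggregate([0.42])
        assert mean == 0.42 and np.isnan(sem)

    def test_identical_plates(self):
        mean, sem = per_plate_aggregate([0.3, 0.3, 0.3])
        assert mean == pytest.approx(0.3) and sem == 0.0

    def test_two_plates(self):
        mean, sem = per_plate_aggregate([0.1, 0.3])
        assert mean == pytest.approx(0.2)
        assert sem == pytest.approx(0.1)


class TestFrameInvariance:
    def test_indices_invariant_under_rotation_and_translation(self):
        """Rotating and translating tracks together with the field leaves
        the strategy indices unchanged."""
        rng = np.random.default_rng(3)
        n = 700
        # persistent walker: heading wanders slowly, occasional sharp turn
        dtheta = rng.normal(0, 10.0, n)
        dtheta[rng.uniform(size=n) < 0.03] += 150.0
        theta = np.radians(np.cumsum(dtheta))
        pos = np.cumsum(0.1 * np.column_stack([np.cos(theta),
                                               np.sin(theta)]), axis=0)
        track = make_track(pos)
        field = field_from_function(lambda x, y: 1.2 * x + 60.0, extent=80.0)

        ang = np.radians(40.0)
        R = np.array([[np.cos(ang), -np.sin(ang)],
                      [np.sin(ang), np.cos(ang)]])
        shift = np.array([5.0, -3.0])
        track_r = make_track(pos @ R.T + shift)
        rot_field = field_from_function(
            lambda x, y: 1.2 * ((x - shift[0]) * np.cos(ang)
                                + (y - shift[1]) * np.sin(ang)) + 60.0,
            extent=80.0)

        out, out_r = {}, {}
        for key, tr, fl in (("orig", track, field), ("rot", track_r, rot_field)):
            states = [sn.segment_pirouettes(tr)]
            dcdt = [sn.experienced_dCdt(fl, tr)]
            dcdn = [sn.experienced_dCdn(fl, tr)]
            curv = [curving_rate(tr)]
            d = {}
            d["pir"] = pirouette_index(states, dcdt, [tr.times]).pirouette_index
            d["wv"] = weathervane_index(curv, dcdn, states,
                                        [tr.times]).weathervane_index
            (out if key == "orig" else out_r).update(d)
        assert out_r["pir"] == pytest.approx(out["pir"], abs=0.02)
        assert out_r["wv"] == pytest.approx(out["wv"], rel=0.05, abs=0.5)

    def test_wrap_angle(self):
        assert wrap_angle(190.0) == pytest.approx(-170.0)
        assert wrap_angle(-190.0) == pytest.approx(170.0)
        assert wrap_angle(180.0) == pytest.approx(180.0)
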