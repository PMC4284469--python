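"""Plate simulator: stepping rules, trails, encounters, growth, spirals,
rasters and spread statistics."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from phormidium import simulate as sim
from phormidium.kinetics import KineticParams, params_for_agar

from conftest import single_filament_state


class TestAgarToParams:
    def test_anchor_15(self):
        sub = sim.agar_to_params(1.5)
        assert sub.kinetics.v_term == pytest.approx(0.169)
        assert sub.kinetics.tau == pytest.approx(99.0)
        assert not sub.submerged

    def test_anchor_20(self):
        sub = sim.agar_to_params(2.0)
        assert sub.kinetics.v_term == pytest.approx(0.148)
        assert sub.kinetics.tau == pytest.approx(108.0)

    def test_submerged_below_threshold(self):
        assert sim.agar_to_params(0.7).submerged
        assert not sim.agar_to_params(1.1).submerged

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            sim.agar_to_params(5.0)


class TestStep:
    def test_straight_euler_advance(self, constant_speed_params):
        """kappa=0, no trails: tip moves n*v*dt along the heading, body straight."""
        state = single_filament_state(constant_speed_params, kappa=0.0,
                                      seed_trail=False)
        for _ in range(100):
            sim.step(state, 5.0)
        tip = state.filaments[0].leading_tip()
        assert tip == pytest.approx([100.0, 0.0], abs=1e-9)
        assert np.allclose(state.filaments[0].vertices[:, 1], 0.0)

    def test_virgin_substrate_curvature_gives_circular_arc(
        self, constant_speed_params
    ):
        """Heading change equals kappa * path length; trajectory radius 1/kappa."""
        kappa = 0.01
        state = single_filament_state(constant_speed_params, kappa=kappa,
                                      length=20.0)
        tips = []
        for _ in range(1600):
            sim.step(state, 1.0)
            tips.append(state.filaments[0].leading_tip().copy())
        tips = np.asarray(tips)
        # least-squares circle through the tip trajectory
        A = np.c_[2 * tips[:, 0], 2 * tips[:, 1], np.ones(len(tips))]
        b = (tips**2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        radius = math.sqrt(sol[2] + sol[0] ** 2 + sol[1] ** 2)
        assert radius == pytest.approx(1.0 / kappa, rel=0.01)
        # body winding ~ kappa * body length (counterclockwise positive)
        fil = state.filaments[0]
        assert sim.winding_angle(fil.vertices) == pytest.approx(
            kappa * fil.length, rel=0.05
        )

    def test_backward_half_cycle_retraces_forward_trail(self):
        """Sheath guidance: the reversed tip follows the stored trail within
        one deposit radius."""
        p = KineticParams(v_term=0.15, v_max=0.3, tau=99.0,
                          period_min=400.0, period_max=400.0)
        state = single_filament_state(p, kappa=0.005, length=30.0,
                                      next_reversal=400.0, seed=1)
        forward = []
        for _ in range(80):
            sim.step(state, 5.0)
            forward.append(state.filaments[0].leading_tip().copy())
        backward = []
        for _ in range(80):
            sim.step(state, 5.0)
            backward.append(state.filaments[0].leading_tip().copy())
        fil = state.filaments[0]
        trail = np.vstack([fil.vertices, np.asarray(forward)])
        d, _ = cKDTree(trail).query(np.asarray(backward))
        assert d.max() < state.trails.radius

    def test_arc_length_conserved(self, anchor_params_15):
        state = single_filament_state(anchor_params_15, kappa=0.01,
                                      next_reversal=300.0)
        L0 = state.filaments[0].length
        for _ in range(300):
            sim.step(state, 4.0)
        assert state.filaments[0].length == pytest.approx(L0, abs=1e-6)

    def test_unstable_dt_rejected(self, anchor_params_15):
        state = single_filament_state(anchor_params_15)
        with pytest.raises(ValueError):
            sim.step(state, 10.0)  # 0.385 * 10 > deposit radius 2.5

    def test_clock_and_phase_advance(self, constant_speed_params):
        state = single_filament_state(constant_speed_params)
        sim.step(state, 2.0)
        sim.step(state, 2.0)
        assert state.clock == pytest.approx(4.0)
        assert state.filaments[0].phase == pytest.approx(4.0)


class TestResolveEncounter:
    def _two_filament_state(self, obstacle_x=3.0):
        p = KineticParams(v_term=0.2, v_max=0.2, tau=100.0)
        f1 = sim.make_filament((0, 0), 0.0, 30.0, p, fid=0, next_reversal=1e12)
        # obstacle body spans y in [-30, 30] at x = obstacle_x
        f2 = sim.make_filament((obstacle_x, 30.0), math.pi / 2, 60.0, p,
                               fid=1, next_reversal=1e12)
        sub = sim.SubstrateParams(p, 0.0, False, 1.5)
        return sim.PlateState([f1, f2], sim.SheathTrailStore(2.5), sub, 0.0,
                              np.random.default_rng(0),
                              foreign_trails_block=False)

    def test_perpendicular_obstacle_forces_left_turn(self):
        state = self._two_filament_state()
        f1 = state.filaments[0]
        heading, turn = sim.resolve_encounter(
            state, f1, f1.leading_tip(), np.array([1.0, 0.0]), 1.0
        )
        assert heading is not None
        assert turn > 0  # counterclockwise
        cross = heading[1] * 1.0 - heading[0] * 0.0
        assert cross >= 0

    def test_no_intersection_identity(self):
        state = self._two_filament_state(obstacle_x=500.0)
        f1 = state.filaments[0]
        heading, turn = sim.resolve_encounter(
            state, f1, f1.leading_tip(), np.array([1.0, 0.0]), 1.0
        )
        assert turn == 0.0
        assert heading == pytest.approx([1.0, 0.0])

    def test_fully_enclosed_filament_stalls(self):
        p = KineticParams(v_term=0.2, v_max=0.2, tau=100.0)
        f1 = sim.make_filament((0, 0), 0.0, 3.0, p, fid=0, next_reversal=1e12)
        theta = np.linspace(0, 2 * math.pi, 100)
        ring = sim.Filament(
            vertices=np.column_stack([3.0 * np.cos(theta), 3.0 * np.sin(theta)]),
            direction=1, phase=0.0, next_reversal=1e12, params=p, fid=1,
        )
        sub = sim.SubstrateParams(p, 0.0, False, 1.5)
        state = sim.PlateState([f1, ring], sim.SheathTrailStore(2.5), sub, 0.0,
                               np.random.default_rng(0),
                               foreign_trails_block=False)
        heading, _ = sim.resolve_encounter(
            state, f1, f1.leading_tip(), np.array([1.0, 0.0]), 2.0
        )
        assert heading is None  # stall is a valid outcome
        tip_before = f1.leading_tip().copy()
        sim.step(state, 5.0)
        assert f1.leading_tip() == pytest.approx(tip_before)


class TestGrow:
    def test_one_doubling_time_doubles_length(self, constant_speed_params):
        fil = sim.make_filament((0, 0), 0.0, 50.0, constant_speed_params)
        sim.grow(fil, 600.0, 600.0)
        assert fil.length == pytest.approx(100.0, abs=1e-6)

    def test_zero_dt_identity(self, constant_speed_params):
        fil = sim.make_filament((0, 0), 0.0, 50.0, constant_speed_params)
        verts = fil.vertices.copy()
        sim.grow(fil, 0.0, 600.0)
        assert np.array_equal(fil.vertices, verts)

    def test_arc_length_matches_analytic_growth(self, constant_speed_params):
        fil = sim.make_filament((0, 0), 0.0, 37.0, constant_speed_params)
        dt, td = 250.0, 700.0
        sim.grow(fil, dt, td, kappa=0.01)
        assert fil.length == pytest.approx(37.0 * 2 ** (dt / td), abs=1e-6)

    def test_symmetric_extension(self, constant_speed_params):
        fil = sim.make_filament((0, 0), 0.0, 50.0, constant_speed_params)
        head0, tail0 = fil.vertices[-1].copy(), fil.vertices[0].copy()
        sim.grow(fil, 600.0, 600.0)
        head_ext = np.hypot(*(fil.vertices[-1] - head0))
        tail_ext = np.hypot(*(fil.vertices[0] - tail0))
        assert head_ext == pytest.approx(tail_ext, rel=1e-6)

    def test_segment_spacing_invariant(self, constant_speed_params):
        fil = sim.make_filament((0, 0), 0.0, 20.0, constant_speed_params,
                                segment_length=2.0)
        sim.grow(fil, 900.0, 600.0, kappa=0.02, segment_length=2.0)
        d = np.diff(fil.vertices, axis=0)
        assert np.all(np.hypot(d[:, 0], d[:, 1]) <= 2.0 + 1e-9)


class TestDetectSpirals:
    def _state_with_vertices(self, vertices, submerged=False):
        p = KineticParams(v_term=0.2, v_max=0.2, tau=100.0)
        fil = sim.Filament(vertices=np.asarray(vertices, dtype=float),
                           direction=1, phase=0.0, next_reversal=1e12,
                           params=p, fid=0)
        sub = sim.SubstrateParams(p, 0.0, submerged, 1.5)
        return sim.PlateState([fil], sim.SheathTrailStore(2.5), sub, 0.0,
                              np.random.default_rng(0))

    def test_straight_filament_not_spiral(self):
        verts = np.column_stack([np.linspace(0, 100, 51), np.zeros(51)])
        recs = sim.detect_spirals(self._state_with_vertices(verts))
        assert recs[0].winding_rad == pytest.approx(0.0)
        assert not recs[0].is_spiral

    def test_archimedean_spiral_three_turns(self):
        theta = np.linspace(0, 6 * math.pi, 600)
        r = 5.0 + 2.0 * theta
        verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        recs = sim.detect_spirals(self._state_with_vertices(verts))
        assert recs[0].winding_rad == pytest.approx(6 * math.pi, rel=0.02)
        assert recs[0].is_spiral

    def test_single_circle_below_two_turn_threshold(self):
        theta = np.linspace(0, 2 * math.pi, 200)
        verts = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta)])
        recs = sim.detect_spirals(self._state_with_vertices(verts), min_turns=2)
        assert abs(recs[0].winding_rad) == pytest.approx(2 * math.pi, rel=0.02)
        assert not recs[0].is_spiral

    def test_submerged_disables_classification(self):
        theta = np.linspace(0, 6 * math.pi, 600)
        r = 5.0 + 2.0 * theta
        verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        state = self._state_with_vertices(verts, submerged=True)
        assert sim.detect_spirals(state) == []


class TestRasterize:
    def test_empty_plate(self):
        p = KineticParams(v_term=0.2, v_max=0.2, tau=100.0)
        state = sim.PlateState([], sim.SheathTrailStore(2.5),
                               sim.SubstrateParams(p, 0.0, False, 1.5), 0.0,
                               np.random.default_rng(0), plate_radius=50.0)
        raster = sim.rasterize(state, 1.0)
        assert not raster.pixels.any()

    def test_stadium_area_of_straight_filament(self, constant_speed_params):
        L, w = 200.0, 5.0
        fil = sim.make_filament((0, 0), 0.0, L, constant_speed_params, width=w)
        sub = sim.SubstrateParams(constant_speed_params, 0.0, False, 1.5)
        state = sim.PlateState([fil], sim.SheathTrailStore(2.5), sub, 0.0,
                               np.random.default_rng(0))
        px = 0.25
        raster = sim.rasterize(state, px)
        area = raster.pixels.sum() * px * px
        expected = L * w + math.pi * (w / 2) ** 2  # stadium
        assert area == pytest.approx(expected, rel=0.01)

    def test_spread_of_straight_filament_from_one_end(self, constant_speed_params):
        L = 300.0
        fil = sim.make_filament((0, 0), 0.0, L, constant_speed_params, width=2.0)
        sub = sim.SubstrateParams(constant_speed_params, 0.0, False, 1.5)
        state = sim.PlateState([fil], sim.SheathTrailStore(2.5), sub, 0.0,
                               np.random.default_rng(0))
        raster = sim.rasterize(state, 0.5)
        # head is at (0,0); body extends to (-L, 0)
        mean, sd = sim.radial_spread_stats(raster, (0.0, 0.0))
        assert mean == pytest.approx(L / 2, rel=0.02)

    def test_deterministic(self, constant_speed_params):
        state = single_filament_state(constant_speed_params)
        r1 = sim.rasterize(state, 1.0)
        r2 = sim.rasterize(state, 1.0)
        assert np.array_equal(r1.pixels, r2.pixels)


class TestRadialSpreadStats:
    def _raster_from_mask(self, mask, px=1.0):
        mask = np.asarray(mask, dtype=bool)
        return sim.Raster(pixels=mask, pixel_size=px, x_min=0.0,
                          y_max=mask.shape[0] * px)

    def test_single_pixel_three_four_five(self):
        mask = np.zeros((10, 10), dtype=bool)
        # pixel center (3.5, 5.5) relative to origin (0.5, 1.5): offset (3, 4)
        mask[4, 3] = True  # center x=3.5, y=10-4.5=5.5
        raster = self._raster_from_mask(mask)
        mean, sd = sim.radial_spread_stats(raster, (0.5, 1.5))
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(0.0)

    def test_circle_of_pixels_constant_distance(self):
        n = 401
        mask = np.zeros((n, n), dtype=bool)
        theta = np.linspace(0, 2 * math.pi, 2000)
        r = 150.0
        cols = np.clip((n / 2 + r * np.cos(theta)).astype(int), 0, n - 1)
        rows = np.clip((n / 2 + r * np.sin(theta)).astype(int), 0, n - 1)
        mask[rows, cols] = True
        raster = self._raster_from_mask(mask)
        center = (n / 2.0, n - n / 2.0)
        mean, sd = sim.radial_spread_stats(raster, center)
        assert mean == pytest.approx(r, rel=0.01)
        assert sd < 0.01 * r  # rasterization tolerance

    def test_filled_disk_moments(self):
        """Continuous disk: mean = 2R/3, SD = R*sqrt(1/2 - 4/9)."""
        n = 801
        R = 350.0
        yy, xx = np.mgrid[0:n, 0:n]
        cx = cy = n / 2.0
        mask = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= R * R
        raster = self._raster_from_mask(mask)
        mean, sd = sim.radial_spread_stats(raster, (cx, n - cy))
        assert mean == pytest.approx(2 * R / 3, rel=0.005)
        assert sd == pytest.approx(R * math.sqrt(0.5 - 4.0 / 9.0), rel=0.01)

    def test_empty_mask_rejected(self):
        raster = self._raster_from_mask(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            sim.radial_spread_stats(raster, (0, 0))


class TestTrailStore:
    def test_query_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        store = sim.SheathTrailStore(radius=2.5)
        pts = rng.uniform(-50, 50, (2000, 2))
        for k, p in enumerate(pts):
            store.deposit(p, (1.0, 0.0), owner=k % 3)
        for q in rng.uniform(-50, 50, (20, 2)):
            got = store.query(q, 7.0)
            want = np.nonzero(np.hypot(*(pts - q).T) <= 7.0)[0]
            assert np.array_equal(got, want)


class TestChirality:
    def test_winding_positive_for_nearly_all_filaments(self):
        """Counterclockwise chirality: on virgin substrate with kappa > 0,
        accumulated winding is positive for >95% of filaments."""
        n_fil = 100
        pos_count = 0
        params = params_for_agar(1.5)
        for k in range(n_fil):
            state = sim.desk_scale_state(seed=5000 + k)
            sim.run_plate(state, 1200.0, 5.0, doubling_time=3600.0)
            if sim.winding_angle(state.filaments[0].vertices) > 0:
                pos_count += 1
        assert pos_count / n_fil > 0.95
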