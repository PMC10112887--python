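"""Orientation, director coarse-graining, defect detection/tracking,
neighbour graphs, Lewis's law, and extrusion–defect statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from extrudesim.dynamics import DynamicsParams, ExtrusionEvent
from extrudesim.lattice import LatticeSpec, MonolayerState, make_droplet, make_substrate
from extrudesim.topology import (
    ANISOTROPY_MASK,
    DefectPoint,
    DefectTrack,
    basal_plane_index,
    basal_projection,
    cell_orientation,
    coarse_grain_director,
    coordination_history,
    detect_defects,
    lewis_law_stats,
    min_distance_series,
    min_distance_static,
    neighbor_graph,
    overlap_integral,
    total_charge,
    track_defects,
)


def ellipse_footprint(a, b, angle, n=48):
    """Binary ellipse footprint with semi-axes a, b rotated by *angle*."""
    x = np.arange(n)[:, None] - n / 2
    y = np.arange(n)[None, :] - n / 2
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float)


class TestCellOrientation:
    def test_ellipse_along_x(self):
        ang, s = cell_orientation(ellipse_footprint(12, 6, 0.0))
        assert abs(ang) < 0.02
        assert s > 0.3

    def test_disc_is_isotropic(self):
        ang, s = cell_orientation(ellipse_footprint(9, 9, 0.0))
        assert s < ANISOTROPY_MASK

    def test_rotated_ellipse_recovers_angle(self):
        """Analytic moment tensor of a rotated ellipse: angle to within 1 deg."""
        target = np.deg2rad(40)
        ang, s = cell_orientation(ellipse_footprint(14, 7, target))
        assert abs(ang - target) < np.deg2rad(1.0)
        # anisotropy of a sharp ellipse: (a^2-b^2)/(a^2+b^2)
        assert s == pytest.approx((14**2 - 7**2) / (14**2 + 7**2), rel=0.05)

    def test_empty_footprint_raises(self):
        with pytest.raises(ValueError):
            cell_orientation(np.zeros((8, 8)))


def synthetic_defect_cells(lattice, charge, core, n_cells=64, seed=0, psi0=0.0):
    """Cell orientations sampled from an ideal +/-1/2 defect pattern."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, [lattice.nx, lattice.ny], (n_cells, 2))
    ang = np.arctan2(pos[:, 1] - core[1], pos[:, 0] - core[0])
    orient = charge * ang + psi0
    return orient, pos


class TestDirectorField:
    def test_uniform_orientations_give_uniform_field(self):
        lat = LatticeSpec(48, 48, 16)
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 48, (30, 2))
        beta = 0.7
        d = coarse_grain_director([beta] * 30, pos, lat, ell_dir=8.0)
        ok = ~d.mask
        assert ok.any()
        diff = np.abs(((d.angle[ok] - beta) + np.pi / 2) % np.pi - np.pi / 2)
        assert np.max(diff) < 1e-6
        assert np.min(d.order[ok]) > 0.99

    def test_orthogonal_pair_cancels(self):
        lat = LatticeSpec(32, 32, 16)
        pos = np.array([[16.0, 16.0], [16.0, 17.0], [17.0, 16.0]])
        d = coarse_grain_director([0.0, np.pi / 2, 0.0], pos[:3], lat, ell_dir=8.0)
        # Q tensors of the orthogonal pair cancel; order parameter is low
        centre = d.order[~d.mask]
        assert centre.min() < 0.5

    def test_needs_three_cells(self):
        lat = LatticeSpec(32, 32, 16)
        with pytest.raises(ValueError):
            coarse_grain_director([0.0], [[1.0, 1.0]], lat, 8.0)


class TestDefectDetection:
    @pytest.mark.parametrize("charge", [0.5, -0.5])
    def test_analytic_half_integer_field(self, charge):
        """Canonical +/-1/2 patterns: exact charge, position to one plaquette."""
        lat = LatticeSpec(64, 64, 16)
        core = (32.0, 32.0)
        orient, pos = synthetic_defect_cells(lat, charge, core, n_cells=400, seed=2)
        d = coarse_grain_director(orient, pos, lat, ell_dir=6.0, node_spacing=2.0)
        dets = detect_defects(d)
        # the core must be among the detections; spurious boundary pairs sum to 0
        near = [p for p in dets if np.hypot(p.position[0] - 32, p.position[1] - 32) <= 2 * d.spacing]
        assert len(near) == 1
        assert near[0].charge == charge

    def test_plus_half_orientation_is_recovered(self):
        lat = LatticeSpec(64, 64, 16)
        orient, pos = synthetic_defect_cells(lat, 0.5, (32.0, 32.0), 400, seed=3)
        d = coarse_grain_director(orient, pos, lat, ell_dir=6.0, node_spacing=2.0)
        dets = [p for p in detect_defects(d) if p.charge > 0
                and np.hypot(p.position[0] - 32, p.position[1] - 32) <= 4]
        assert dets and dets[0].psi is not None

    def test_smooth_defect_free_field_brute_force(self):
        """Random smooth field: no defects, matching a brute-force winding scan."""
        lat = LatticeSpec(64, 64, 16)
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, 64, (300, 2))
        # long-wavelength smooth orientation field (half-angle keeps it nematic-smooth)
        orient = 0.3 * np.sin(2 * np.pi * pos[:, 0] / 64) + 0.2 * np.cos(
            2 * np.pi * pos[:, 1] / 64
        )
        d = coarse_grain_director(orient, pos, lat, ell_dir=8.0, node_spacing=2.0)
        dets = detect_defects(d)
        assert total_charge(dets) == pytest.approx(0.0)
        assert len(dets) == 0

    def test_total_charge_zero_on_periodic_domain(self):
        lat = LatticeSpec(64, 64, 16)
        orient, pos = synthetic_defect_cells(lat, 0.5, (20.0, 30.0), 500, seed=5)
        d = coarse_grain_director(orient, pos, lat, ell_dir=6.0, node_spacing=2.0)
        # periodic closure forces compensating windings elsewhere
        assert total_charge(detect_defects(d)) == pytest.approx(0.0)


class TestDefectTracking:
    def test_stationary_defect_single_track(self):
        lat = LatticeSpec(64, 64, 16)
        det = DefectPoint(0.5, (10.0, 10.0), 0.3)
        tracks = track_defects([[det]] * 10, lat, gate=8.0)
        assert len(tracks) == 1
        assert tracks[0].lifetime == 10
        assert tracks[0].charge == 0.5

    def test_two_separated_defects_no_id_switch(self):
        lat = LatticeSpec(64, 64, 16)
        frames = []
        for f in range(8):
            frames.append(
                [
                    DefectPoint(0.5, (10.0 + 0.5 * f, 10.0), 0.0),
                    DefectPoint(0.5, (40.0, 40.0 - 0.5 * f), 0.0),
                ]
            )
        tracks = track_defects(frames, lat, gate=6.0)
        assert len(tracks) == 2
        assert all(tr.lifetime == 8 for tr in tracks)
        xs = sorted(tr.positions[0][0] for tr in tracks)
        assert xs == [10.0, 40.0]

    def test_annihilating_pair_both_tracks_end(self):
        lat = LatticeSpec(64, 64, 16)
        frames = []
        k = 5
        for f in range(k):
            frames.append(
                [
                    DefectPoint(0.5, (20.0 + f, 20.0), 0.0),
                    DefectPoint(-0.5, (30.0 - f, 20.0), None),
                ]
            )
        frames.append([])  # annihilation
        frames.append([])
        tracks = track_defects(frames, lat, gate=4.0)
        assert len(tracks) == 2
        assert all(tr.death == k - 1 for tr in tracks)

    def test_opposite_charges_never_link(self):
        lat = LatticeSpec(64, 64, 16)
        frames = [
            [DefectPoint(0.5, (10.0, 10.0), 0.0)],
            [DefectPoint(-0.5, (10.5, 10.0), None)],
        ]
        tracks = track_defects(frames, lat, gate=8.0)
        assert len(tracks) == 2


class TestNeighborGraph:
    def _pair_state(self, sep):
        lat = LatticeSpec(48, 32, 20)
        sub = make_substrate(lat, 2.0, z_surface=4.0)
        c0 = make_droplet(0, (18.0, 16.0, 9.0), 5.0, 2.0, lat)
        c1 = make_droplet(1, (18.0 + sep, 16.0, 9.0), 5.0, 2.0, lat)
        return MonolayerState(lat, [c0, c1], sub)

    def test_disjoint_cells_no_edge(self):
        g = neighbor_graph(self._pair_state(24.0), 1e-3)
        assert g.number_of_edges() == 0

    def test_touching_pair_edge_stable_over_thresholds(self):
        state = self._pair_state(8.5)
        direct = overlap_integral(state.cells[0], state.cells[1], state.lattice)
        assert direct > 0.1
        for thr in (1e-3, 1e-2, 1e-1):
            g = neighbor_graph(state, thr)
            assert g.has_edge(0, 1)
            assert g.nodes[0]["z"] == 1

    def test_overlap_symmetry_and_periodic_wrap(self):
        lat = LatticeSpec(48, 32, 20)
        sub = make_substrate(lat, 2.0, z_surface=4.0)
        c0 = make_droplet(0, (2.0, 16.0, 9.0), 5.0, 2.0, lat)
        c1 = make_droplet(1, (43.0, 16.0, 9.0), 5.0, 2.0, lat)  # touches across seam
        o01 = overlap_integral(c0, c1, lat)
        o10 = overlap_integral(c1, c0, lat)
        assert o01 == pytest.approx(o10, rel=1e-12)
        assert o01 > 1e-3


class TestLewisLaw:
    def _graph_with_z(self, zs):
        g = nx.Graph()
        for i, z in enumerate(zs):
            g.add_node(i, z=z)
        return g

    def test_reference_values_at_five_and_six(self):
        g = self._graph_with_z([5, 6, 6, 7])
        areas = {0: 1.0, 1: 1.2, 2: 1.1, 3: 1.4}
        df = lewis_law_stats(g, areas).set_index("z")
        assert df.loc[6, "lewis_linear"] == pytest.approx(1.0)
        assert df.loc[6, "lewis_quadratic"] == pytest.approx(1.0)
        assert df.loc[5, "lewis_linear"] == pytest.approx(0.75)
        assert df.loc[5, "lewis_quadratic"] == pytest.approx(25 / 36)

    def test_equal_areas_give_unit_ratios(self):
        g = self._graph_with_z([5, 5, 6, 7, 6])
        areas = {i: 2.5 for i in range(5)}
        df = lewis_law_stats(g, areas)
        np.testing.assert_allclose(df["area_ratio"], 1.0)

    def test_single_class_rejected(self):
        g = self._graph_with_z([6, 6])
        with pytest.raises(ValueError):
            lewis_law_stats(g, {0: 1.0, 1: 1.0})


def _dyn(R0=8.0):
    return DynamicsParams(xi=1.0, alpha=0.05, dt=0.25, n_steps=4000, R0=R0)


class TestMinDistance:
    def test_static_defect_simple_arithmetic(self):
        lat = LatticeSpec(64, 64, 16)
        dyn = _dyn()
        ev = ExtrusionEvent(0, 2000, (20.0, 20.0, 12.0))
        track = DefectTrack(0, 0.5, list(range(41)), [(32.0, 20.0)] * 41, [0.0] * 41)
        frame_steps = list(range(0, 4100, 100))
        com = np.zeros((4001, 1, 3))
        com[:, 0, :2] = [20.0, 20.0]
        df = min_distance_series([ev], [track], com, [0], frame_steps, dyn, lat)
        assert df.loc[0, "dmin_plus"] == pytest.approx(12.0 / 8.0)
        assert np.isnan(df.loc[0, "dmin_minus"])  # no -1/2 defects -> missing

    def test_minimum_at_closest_approach_brute_force(self):
        """Approaching-then-receding defect: min over all (frame, defect) pairs."""
        lat = LatticeSpec(64, 64, 16)
        dyn = _dyn()
        frame_steps = list(range(0, 4100, 100))
        xs = 40 - 0.5 * np.arange(41)  # approaches x=20 then recedes
        xs[25:] = xs[24] + 0.7 * np.arange(16)
        track = DefectTrack(0, 0.5, list(range(41)), [(float(x), 20.0) for x in xs], [0.0] * 41)
        ev = ExtrusionEvent(0, 2000, (20.0, 20.0, 12.0))
        com = np.zeros((4001, 1, 3))
        com[:, 0, :2] = [20.0, 20.0]
        df = min_distance_series([ev], [track], com, [0], frame_steps, dyn, lat)
        # brute-force oracle over in-window frames
        tau0 = dyn.tau0
        te = 2000 * dyn.dt / tau0
        best = np.inf
        for k, s in enumerate(frame_steps):
            t = s * dyn.dt / tau0
            if te - 5.625 <= t <= te + 0.625:
                best = min(best, abs(xs[k] - 20.0))
        assert df.loc[0, "dmin_plus"] == pytest.approx(best / 8.0)

    def test_translation_invariance(self):
        lat = LatticeSpec(64, 64, 16)
        dyn = _dyn()
        frame_steps = list(range(0, 4100, 100))
        for shift in (0.0, 31.0):
            track = DefectTrack(
                0, 0.5, list(range(41)), [((30.0 + shift) % 64, 20.0)] * 41, [0.0] * 41
            )
            ev = ExtrusionEvent(0, 2000, ((20.0 + shift) % 64, 20.0, 12.0))
            com = np.zeros((4001, 1, 3))
            com[:, 0, :2] = [(20.0 + shift) % 64, 20.0]
            df = min_distance_series([ev], [track], com, [0], frame_steps, dyn, lat)
            assert df.loc[0, "dmin_plus"] == pytest.approx(10.0 / 8.0)

    def test_static_null_events_match_series_for_static_cell(self):
        lat = LatticeSpec(64, 64, 16)
        dyn = _dyn()
        frame_steps = list(range(0, 4100, 100))
        track = DefectTrack(0, 0.5, list(range(41)), [(44.0, 20.0)] * 41, [0.0] * 41)
        df = min_distance_static(
            np.array([[20.0, 20.0]]), [2000], [track], frame_steps, dyn, lat
        )
        assert df.loc[0, "dmin_plus"] == pytest.approx(24.0 / 8.0)


class TestCoordinationHistory:
    def _graphs(self, zs_per_frame):
        gs = []
        for z in zs_per_frame:
            g = nx.Graph()
            g.add_node(0, z=z)
            gs.append(g)
        return gs

    def test_constant_coordination(self):
        dyn = _dyn()
        graphs = self._graphs([5] * 41)
        ev = ExtrusionEvent(0, 3000, (0, 0, 0))
        df = coordination_history([ev], graphs, list(range(0, 4100, 100)), dyn)
        assert df.loc[0, "z_bar"] == pytest.approx(5.0)

    def test_equally_weighted_average(self):
        dyn = DynamicsParams(xi=1.0, alpha=0.05, dt=0.25, n_steps=300, R0=8.0)
        # tau0=160; window (-2.5, .3125) in t~ -> steps (te-1600, te+200)
        graphs = self._graphs([6, 6, 5, 5])
        frame_steps = [0, 100, 200, 300]
        ev = ExtrusionEvent(0, 280, (0, 0, 0))
        df = coordination_history(
            [ev], graphs, frame_steps, dyn, window=(-0.3, 0.05)
        )
        # window covers steps [232-ish..308]: frame 300 only... use wide window
        df = coordination_history([ev], graphs, frame_steps, dyn, window=(-10, 10))
        assert df.loc[0, "z_bar"] == pytest.approx(5.5)

    def test_clipped_window_flagged(self):
        dyn = _dyn()
        graphs = self._graphs([6] * 5)
        ev = ExtrusionEvent(0, 100, (0, 0, 0))
        df = coordination_history([ev], graphs, [0, 100, 200, 300, 400], dyn)
        assert bool(df.loc[0, "clipped"])
        assert df.loc[0, "z_bar"] == pytest.approx(6.0)


class TestBasalProjection:
    def test_footprint_translates_with_cell(self):
        lat = LatticeSpec(48, 48, 20)
        sub = make_substrate(lat, 2.0, z_surface=4.0)
        k = basal_plane_index(MonolayerState(lat, [], sub))
        c0 = make_droplet(0, (20.0, 20.0, 9.0), 5.0, 2.0, lat)
        st = MonolayerState(lat, [c0], sub)
        f0 = basal_projection(st)[0]
        c1 = make_droplet(0, (27.0, 20.0, 9.0), 5.0, 2.0, lat)
        f1 = basal_projection(MonolayerState(lat, [c1], sub))[0]
        np.testing.assert_allclose(
            f0.centroid(lat) + [7.0, 0.0], f1.centroid(lat), atol=0.05
        )

    def test_detached_cell_has_empty_footprint(self):
        lat = LatticeSpec(48, 48, 20)
        sub = make_substrate(lat, 2.0, z_surface=4.0)
        c = make_droplet(0, (20.0, 20.0, 14.5), 5.0, 2.0, lat)  # floated upward
        fp = basal_projection(MonolayerState(lat, [c], sub))[0]
        assert fp.empty
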