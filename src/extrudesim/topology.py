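"""Orientation field, nematic ±1/2 defects, neighbour graph and hexatic
coordination analysis of the basal plane.

The cell orientation is the principal axis of the second-moment (shape)
tensor of each basal footprint; orientations are headless (defined modulo
pi).  A coarse-grained director field is the principal eigenvector of the
Gaussian-weighted average of the per-cell nematic tensors
Q = 2 n (x) n - I.  Defects are plaquettes of the director grid around
which the orientation winds by ±pi (charge ±1/2); the comet axis of a
+1/2 defect points along div Q at the core.

Coordination numbers come from the 3D phase-field overlap
Int phi_i^2 phi_j^2 dx: cells above a small overlap threshold are
neighbours, and cells with 5 (7) neighbours in an otherwise sixfold
packing are fivefold (sevenfold) disclinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import DynamicsParams, ExtrusionEvent
from .lattice import (
    CellField,
    LatticeSpec,
    MonolayerState,
    periodic_distance_xy,
)

__all__ = [
    "DirectorField",
    "DefectTrack",
    "basal_plane_index",
    "basal_projection",
    "cell_orientation",
    "coarse_grain_director",
    "detect_defects",
    "track_defects",
    "neighbor_graph",
    "overlap_integral",
    "lewis_law_stats",
    "min_distance_series",
    "coordination_history",
]

#: footprints with anisotropy below this carry no reliable orientation
ANISOTROPY_MASK = 0.05


# --------------------------------------------------------------------------
# basal footprints and per-cell orientation
# --------------------------------------------------------------------------

def basal_plane_index(state: MonolayerState) -> int:
    """First lattice plane above the substrate midpoint surface."""
    return int(np.floor(state.substrate.z_surface / state.lattice.a0)) + 1


@dataclass
class Footprint:
    """Basal-plane slice of one cell's field, on its x/y subdomain."""

    cell_id: int
    values: np.ndarray  # (sx, sy)
    offset: tuple[int, int]
    empty: bool

    def centroid(self, lattice: LatticeSpec) -> np.ndarray:
        """phi-weighted centroid in unwrapped coordinates, mapped into the box."""
        w = self.values
        tot = w.sum()
        a0 = lattice.a0
        x = (self.offset[0] + np.arange(w.shape[0])) * a0
        y = (self.offset[1] + np.arange(w.shape[1])) * a0
        cx = float((w.sum(axis=1) * x).sum() / tot) % (lattice.nx * a0)
        cy = float((w.sum(axis=0) * y).sum() / tot) % (lattice.ny * a0)
        return np.array([cx, cy])

    def area(self, lattice: LatticeSpec, level: float = 0.5) -> float:
        """Projected area of the phi >= level region."""
        return float(np.count_nonzero(self.values >= level)) * lattice.a0**2


def basal_projection(state: MonolayerState, empty_level: float = 0.5) -> dict[int, Footprint]:
    """Extract each cell's field on the basal plane.

    A cell whose basal slice never reaches ``empty_level`` (e.g. an
    extruded cell that lost substrate contact) is flagged empty/masked.
    """
    k = basal_plane_index(state)
    out: dict[int, Footprint] = {}
    for c in state.cells:
        sl = np.array(c.phi[:, :, k])
        out[c.id] = Footprint(c.id, sl, c.offset, empty=bool(sl.max() < empty_level))
    return out


def cell_orientation(footprint: Footprint | np.ndarray) -> tuple[float, float]:
    """Orientation (mod pi) and anisotropy of a basal footprint.

    Angle of the principal eigenvector of the second-moment tensor about
    the phi-weighted centroid; anisotropy is the normalised eigenvalue
    difference in [0, 1] (0 for a perfect disc, flagged unreliable below
    ANISOTROPY_MASK).
    """
    w = footprint.values if isinstance(footprint, Footprint) else np.asarray(footprint, float)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("empty footprint has no orientation")
    nx_, ny_ = w.shape
    x = np.arange(nx_)[:, None]
    y = np.arange(ny_)[None, :]
    cx = (w * x).sum() / tot
    cy = (w * y).sum() / tot
    mxx = (w * (x - cx) ** 2).sum() / tot
    myy = (w * (y - cy) ** 2).sum() / tot
    mxy = (w * (x - cx) * (y - cy)).sum() / tot
    angle = 0.5 * np.arctan2(2 * mxy, mxx - myy)
    tr = mxx + myy
    diff = np.hypot(mxx - myy, 2 * mxy)
    anisotropy = float(diff / tr) if tr > 0 else 0.0
    return float(angle), anisotropy


# --------------------------------------------------------------------------
# coarse-grained director field and defects
# --------------------------------------------------------------------------

@dataclass
class DirectorField:
    """Headless orientation field on a regular basal grid.

    ``angle`` is defined modulo pi; ``order`` is the magnitude of the
    averaged nematic tensor (0 = isotropic); masked nodes had no cells in
    range.
    """

    xs: np.ndarray  # node x coordinates (n_x,)
    ys: np.ndarray  # node y coordinates (n_y,)
    angle: np.ndarray  # (n_x, n_y)
    order: np.ndarray  # (n_x, n_y)
    mask: np.ndarray  # True where undefined
    qxx: np.ndarray
    qxy: np.ndarray
    lattice: LatticeSpec

    @property
    def spacing(self) -> float:
        return float(self.xs[1] - self.xs[0]) if len(self.xs) > 1 else self.lattice.a0


def coarse_grain_director(
    orientations: Sequence[float],
    positions: Sequence[Sequence[float]],
    lattice: LatticeSpec,
    ell_dir: float,
    anisotropies: Sequence[float] | None = None,
    node_spacing: float | None = None,
) -> DirectorField:
    """Average per-cell nematic tensors Q = 2 n(x)n - I on a regular grid.

    Cells within ~3 ell_dir of a node contribute with Gaussian weight
    exp(-d^2 / (2 ell_dir^2)) using periodic distances; cells flagged
    isotropic (anisotropy < ANISOTROPY_MASK) are excluded.  Nodes with
    negligible total weight are masked.
    """
    if len(orientations) < 3:
        raise ValueError("need at least 3 oriented cells")
    if node_spacing is None:
        node_spacing = max(lattice.a0, ell_dir / 4.0)
    pos = np.asarray(positions, float)[:, :2]
    ang = np.asarray(orientations, float)
    if anisotropies is not None:
        keep = np.asarray(anisotropies, float) >= ANISOTROPY_MASK
        pos, ang = pos[keep], ang[keep]
    Lx, Ly, _ = lattice.extent
    nxn = int(round(Lx / node_spacing))
    nyn = int(round(Ly / node_spacing))
    xs = np.arange(nxn) * node_spacing
    ys = np.arange(nyn) * node_spacing
    dx = xs[:, None] - pos[None, :, 0]
    dx -= Lx * np.round(dx / Lx)
    dy = ys[:, None] - pos[None, :, 1]
    dy -= Ly * np.round(dy / Ly)
    d2 = dx[:, None, :] ** 2 + dy[None, :, :] ** 2  # (nxn, nyn, ncell)
    w = np.exp(-d2 / (2 * ell_dir**2))
    w[d2 > (3 * ell_dir) ** 2] = 0.0
    wsum = w.sum(axis=2)
    qxx = np.tensordot(w, np.cos(2 * ang), axes=(2, 0))
    qxy = np.tensordot(w, np.sin(2 * ang), axes=(2, 0))
    mask = wsum < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        order = np.hypot(qxx, qxy) / wsum
    order[mask] = 0.0
    angle = 0.5 * np.arctan2(qxy, qxx)
    angle[mask] = np.nan
    return DirectorField(xs, ys, angle, order, mask, qxx, qxy, lattice)


def _wrap_nematic(d: np.ndarray | float):
    """Re-wrap an orientation difference into (-pi/2, pi/2]."""
    return -((-np.asarray(d) + np.pi / 2) % np.pi - np.pi / 2)


@dataclass(frozen=True)
class DefectPoint:
    charge: float  # +0.5 or -0.5
    position: tuple[float, float]
    psi: float | None  # comet axis, +1/2 only


def detect_defects(director: DirectorField, order_min: float = 0.0) -> list[DefectPoint]:
    """Find ±1/2 defects as plaquettes with winding ±pi.

    The winding number around each grid plaquette is the sum of
    nematically re-wrapped orientation differences along the loop; the
    sub-grid position is the plaquette centre.  The +1/2 comet axis psi is
    the direction of div Q evaluated at the core.
    """
    ang = director.angle
    mask = director.mask | (director.order < order_min)
    nxn, nyn = ang.shape
    Lx, Ly, _ = director.lattice.extent
    h = director.spacing
    out: list[DefectPoint] = []
    a00 = ang
    a10 = np.roll(ang, -1, 0)
    a11 = np.roll(np.roll(ang, -1, 0), -1, 1)
    a01 = np.roll(ang, -1, 1)
    bad = mask | np.roll(mask, -1, 0) | np.roll(np.roll(mask, -1, 0), -1, 1) | np.roll(mask, -1, 1)
    wind = (
        _wrap_nematic(a10 - a00)
        + _wrap_nematic(a11 - a10)
        + _wrap_nematic(a01 - a11)
        + _wrap_nematic(a00 - a01)
    )
    wind[bad] = 0.0
    hits = np.argwhere(np.abs(wind) > np.pi / 2)
    for i, j in hits:
        # winding is a multiple of pi; rare +/-2pi plaquettes are integer
        # defects and must carry their full charge for exact neutrality
        charge = 0.5 * int(np.round(wind[i, j] / np.pi))
        if charge == 0.0:
            continue
        x = (director.xs[i] + h / 2) % Lx
        y = (director.ys[j] + h / 2) % Ly
        psi = None
        if charge == 0.5:
            psi = _plus_half_axis(director, i, j)
        out.append(DefectPoint(float(charge), (float(x), float(y)), psi))
    return out


def _plus_half_axis(director: DirectorField, i: int, j: int) -> float:
    """Comet orientation from div Q around plaquette (i, j), central diffs."""
    qxx = np.cos(2 * director.angle)
    qxy = np.sin(2 * director.angle)
    h = director.spacing

    def at(f, ii, jj):
        return f[ii % f.shape[0], jj % f.shape[1]]

    # average div Q over the four plaquette corners
    div_x = 0.0
    div_y = 0.0
    for ci, cj in ((i, j), (i + 1, j), (i, j + 1), (i + 1, j + 1)):
        dqxx_dx = (at(qxx, ci + 1, cj) - at(qxx, ci - 1, cj)) / (2 * h)
        dqxy_dy = (at(qxy, ci, cj + 1) - at(qxy, ci, cj - 1)) / (2 * h)
        dqxy_dx = (at(qxy, ci + 1, cj) - at(qxy, ci - 1, cj)) / (2 * h)
        dqxx_dy = (at(qxx, ci, cj + 1) - at(qxx, ci, cj - 1)) / (2 * h)
        div_x += dqxx_dx + dqxy_dy
        div_y += dqxy_dx - dqxx_dy
    return float(np.arctan2(div_y, div_x))


def total_charge(detections: Iterable[DefectPoint]) -> float:
    return float(sum(d.charge for d in detections))


# --------------------------------------------------------------------------
# defect tracking
# --------------------------------------------------------------------------

@dataclass
class DefectTrack:
    """One defect followed from nucleation (birth) to annihilation (death)."""

    track_id: int
    charge: float
    frames: list[int] = field(default_factory=list)
    positions: list[tuple[float, float]] = field(default_factory=list)
    psis: list[float | None] = field(default_factory=list)

    @property
    def birth(self) -> int:
        return self.frames[0]

    @property
    def death(self) -> int:
        return self.frames[-1]

    @property
    def lifetime(self) -> int:
        return self.death - self.birth + 1


def track_defects(
    per_frame: Sequence[Sequence[DefectPoint]],
    lattice: LatticeSpec,
    gate: float,
    frame_indices: Sequence[int] | None = None,
) -> list[DefectTrack]:
    """Greedy nearest-neighbour frame-to-frame linking, same charge only.

    Detections within ``gate`` (periodic in-plane distance) of a live
    track's last position extend it; unmatched detections start new
    tracks; unmatched tracks end.
    """
    if len(per_frame) < 2:
        raise ValueError("need at least 2 frames of detections")
    if frame_indices is None:
        frame_indices = list(range(len(per_frame)))
    tracks: list[DefectTrack] = []
    live: list[DefectTrack] = []
    next_id = 0
    for f_idx, dets in zip(frame_indices, per_frame):
        pairs = []
        for ti, tr in enumerate(live):
            for di, det in enumerate(dets):
                if det.charge != tr.charge:
                    continue
                d = periodic_distance_xy(det.position, tr.positions[-1], lattice)
                if d <= gate:
                    pairs.append((d, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        survivors = []
        for d, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = live[ti]
            det = dets[di]
            tr.frames.append(f_idx)
            tr.positions.append(det.position)
            tr.psis.append(det.psi)
            survivors.append(tr)
        for di, det in enumerate(dets):
            if di in used_d:
                continue
            tr = DefectTrack(next_id, det.charge, [f_idx], [det.position], [det.psi])
            next_id += 1
            tracks.append(tr)
            survivors.append(tr)
        live = survivors
    return tracks


# --------------------------------------------------------------------------
# neighbour graph / coordination / Lewis's law
# --------------------------------------------------------------------------

def overlap_integral(ci: CellField, cj: CellField, lattice: LatticeSpec) -> float:
    """3D overlap Int phi_i^2 phi_j^2 dx over the subdomain intersection."""
    ix_i, iy_i = ci.x_indices(lattice), ci.y_indices(lattice)
    ix_j, iy_j = cj.x_indices(lattice), cj.y_indices(lattice)
    # positions of cj's lattice columns inside ci's subdomain
    loc_x_i = {int(g): k for k, g in enumerate(ix_i)}
    loc_y_i = {int(g): k for k, g in enumerate(iy_i)}
    sel_i_x, sel_j_x = [], []
    for k, g in enumerate(ix_j):
        if int(g) in loc_x_i:
            sel_j_x.append(k)
            sel_i_x.append(loc_x_i[int(g)])
    sel_i_y, sel_j_y = [], []
    for k, g in enumerate(iy_j):
        if int(g) in loc_y_i:
            sel_j_y.append(k)
            sel_i_y.append(loc_y_i[int(g)])
    if not sel_i_x or not sel_i_y:
        return 0.0
    a = ci.phi[np.ix_(sel_i_x, sel_i_y, np.arange(ci.phi.shape[2]))]
    b = cj.phi[np.ix_(sel_j_x, sel_j_y, np.arange(cj.phi.shape[2]))]
    return float(np.sum(a**2 * b**2)) * lattice.a0**3


def neighbor_graph(state: MonolayerState, overlap_threshold: float = 1e-2) -> nx.Graph:
    """Adjacency over cell ids with phase-field overlap weights.

    Edge (i, j) iff Int phi_i^2 phi_j^2 dx > overlap_threshold; node
    attribute ``z`` is the coordination number, with fivefold/sevenfold
    disclination labels.
    """
    g = nx.Graph()
    cells = state.cells
    for c in cells:
        g.add_node(c.id)
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            w = overlap_integral(cells[a], cells[b], state.lattice)
            if w > overlap_threshold:
                g.add_edge(cells[a].id, cells[b].id, weight=w)
    for cid in g.nodes:
        z = g.degree(cid)
        g.nodes[cid]["z"] = z
        g.nodes[cid]["disclination"] = (
            "fivefold" if z == 5 else "sevenfold" if z == 7 else None
        )
    return g


def lewis_law_stats(graph: nx.Graph, areas: Mapping[int, float]) -> pd.DataFrame:
    """Empirical normalised mean area per coordination class vs Lewis's laws.

    Returns a table with columns z, n_cells, area_ratio (A_z / A over
    cells present in *areas*), lewis_linear = (z-2)/4 and
    lewis_quadratic = (z/6)^2.
    """
    zs = {cid: graph.nodes[cid]["z"] for cid in graph.nodes if cid in areas}
    if len(set(zs.values())) < 2:
        raise ValueError("need at least two distinct coordination classes")
    mean_all = float(np.mean([areas[cid] for cid in zs]))
    rows = []
    for z in sorted(set(zs.values())):
        cls = [areas[cid] for cid, zz in zs.items() if zz == z]
        rows.append(
            {
                "z": z,
                "n_cells": len(cls),
                "area_ratio": float(np.mean(cls)) / mean_all,
                "lewis_linear": (z - 2) / 4.0,
                "lewis_quadratic": (z / 6.0) ** 2,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# extrusion–defect distance and coordination statistics
# --------------------------------------------------------------------------

def min_distance_series(
    events: Sequence[ExtrusionEvent],
    tracks: Sequence[DefectTrack],
    com_history: np.ndarray,
    cell_ids: Sequence[int],
    frame_steps: Sequence[int],
    dyn_params: DynamicsParams,
    lattice: LatticeSpec,
    window: tuple[float, float] = (-5.625, 0.625),
) -> pd.DataFrame:
    """Normalised minimum extrusion–defect distance per event and charge.

    For each extrusion event, over snapshot frames with normalised time
    t~ - t~_e inside ``window``, the minimum periodic in-plane distance
    between the extruding cell's per-frame COM and any defect of each
    charge, divided by R0.  Charges absent from the window yield NaN
    (missing, not zero).
    """
    R0 = dyn_params.R0
    tau0 = dyn_params.tau0
    dt = dyn_params.dt
    frame_steps = np.asarray(frame_steps)
    # per-frame defect positions by charge
    by_frame: dict[int, dict[float, list[tuple[float, float]]]] = {}
    for tr in tracks:
        for f, p in zip(tr.frames, tr.positions):
            by_frame.setdefault(f, {}).setdefault(tr.charge, []).append(p)
    rows = []
    id_index = {cid: k for k, cid in enumerate(cell_ids)}
    for ev in events:
        te_norm = ev.t_e * dt / tau0
        tnorm = frame_steps * dt / tau0
        in_win = (tnorm >= te_norm + window[0]) & (tnorm <= te_norm + window[1])
        dmin = {0.5: np.inf, -0.5: np.inf}
        for f_pos, step in zip(np.where(in_win)[0], frame_steps[in_win]):
            com = com_history[step, id_index[ev.cell_id], :2]
            frame_dets = by_frame.get(int(f_pos), {})
            for q, plist in frame_dets.items():
                for p in plist:
                    d = periodic_distance_xy(com, p, lattice)
                    if d < dmin.get(q, np.inf):
                        dmin[q] = d
        rows.append(
            {
                "cell_id": ev.cell_id,
                "t_e": ev.t_e,
                "dmin_plus": dmin[0.5] / R0 if np.isfinite(dmin[0.5]) else np.nan,
                "dmin_minus": dmin[-0.5] / R0 if np.isfinite(dmin[-0.5]) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "t_e", "dmin_plus", "dmin_minus"])


def min_distance_static(
    positions: np.ndarray,
    times: Sequence[int],
    tracks: Sequence[DefectTrack],
    frame_steps: Sequence[int],
    dyn_params: DynamicsParams,
    lattice: LatticeSpec,
    window: tuple[float, float] = (-5.625, 0.625),
) -> pd.DataFrame:
    """d~min for surrogate events at fixed positions (Poisson-null pipeline).

    Same windowed minimum as :func:`min_distance_series` but each event
    keeps a static in-plane position (there is no cell to follow).
    """
    R0, tau0, dt = dyn_params.R0, dyn_params.tau0, dyn_params.dt
    frame_steps = np.asarray(frame_steps)
    tnorm = frame_steps * dt / tau0
    by_frame: dict[int, dict[float, list[tuple[float, float]]]] = {}
    for tr in tracks:
        for f, p in zip(tr.frames, tr.positions):
            by_frame.setdefault(f, {}).setdefault(tr.charge, []).append(p)
    rows = []
    for pos, t_e in zip(np.asarray(positions, float), times):
        te_norm = t_e * dt / tau0
        in_win = (tnorm >= te_norm + window[0]) & (tnorm <= te_norm + window[1])
        dmin = {0.5: np.inf, -0.5: np.inf}
        for f_pos in np.where(in_win)[0]:
            for q, plist in by_frame.get(int(f_pos), {}).items():
                for p in plist:
                    d = periodic_distance_xy(pos, p, lattice)
                    if d < dmin.get(q, np.inf):
                        dmin[q] = d
        rows.append(
            {
                "t_e": int(t_e),
                "dmin_plus": dmin[0.5] / R0 if np.isfinite(dmin[0.5]) else np.nan,
                "dmin_minus": dmin[-0.5] / R0 if np.isfinite(dmin[-0.5]) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["t_e", "dmin_plus", "dmin_minus"])


def coordination_history(
    events: Sequence[ExtrusionEvent],
    graphs: Sequence[nx.Graph],
    frame_steps: Sequence[int],
    dyn_params: DynamicsParams,
    window: tuple[float, float] = (-2.5, 0.3125),
) -> pd.DataFrame:
    """Time-averaged coordination z̄ of each extruding cell over the window.

    Windows clipped by the start (or end) of the trajectory are averaged
    over the available frames and flagged ``clipped``.
    """
    tau0 = dyn_params.tau0
    dt = dyn_params.dt
    frame_steps = np.asarray(frame_steps)
    tnorm = frame_steps * dt / tau0
    rows = []
    for ev in events:
        te_norm = ev.t_e * dt / tau0
        lo, hi = te_norm + window[0], te_norm + window[1]
        in_win = (tnorm >= lo) & (tnorm <= hi)
        zs = [
            graphs[k].nodes[ev.cell_id]["z"]
            for k in np.where(in_win)[0]
            if ev.cell_id in graphs[k].nodes
        ]
        clipped = bool(tnorm[0] > lo or tnorm[-1] < hi)
        rows.append(
            {
                "cell_id": ev.cell_id,
                "t_e": ev.t_e,
                "z_bar": float(np.mean(zs)) if zs else np.nan,
                "n_frames": len(zs),
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "t_e", "z_bar", "n_frames", "clipped"])
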