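"""Coarse-grained 3D mechanical stress fields of the monolayer.

From the pointwise traction density T(x) = sum_i phi_i(x) grad Pi(x)
(Pi the scalar of the isotropic interaction tensor), the stress in each
coarse voxel of side ell_stress centred at x0 is the symmetrised sum

    sigma_ij = 1/(2 Vcg) sum_{m in Vcg} ( T_i(x_m) e_j^n + T_j(x_m) e_i^n ),

with unit vectors e^n = (x0 - x_m)/|x0 - x_m| and Vcg = ell_stress^3.
Compression is negative throughout (sigma_iso < 0 = compressive).
Derived maps: isotropic stress sigma_iso = tr(sigma)/3 (a 2D in-plane
trace/2 variant is available for comparison with planar experiments) and
the out-of-plane shear sigma_xz, each optionally normalised by the
frame's maximum absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from ._fd import central_gradient
from .energetics import EnergyParams, all_functional_derivatives
from .lattice import LatticeSpec, MonolayerState
from .topology import DefectTrack

__all__ = [
    "StressField",
    "traction_density",
    "coarse_grained_stress",
    "isotropic_and_shear_maps",
    "cell_stress_series",
    "defect_frame_average",
]


@dataclass
class StressField:
    """Symmetric 3x3 stress tensor per coarse voxel.

    ``tensor`` has shape (ncx, ncy, ncz, 3, 3); ``block`` is the voxel
    side in lattice points; voxel (I, J, K) covers lattice points
    [I*block, (I+1)*block) etc.
    """

    tensor: np.ndarray
    block: int
    lattice: LatticeSpec
    frame: int = 0

    def upsample(self, component: np.ndarray) -> np.ndarray:
        """Broadcast a per-voxel scalar back to lattice resolution."""
        b = self.block
        up = np.repeat(np.repeat(np.repeat(component, b, 0), b, 1), b, 2)
        return up[: self.lattice.nx, : self.lattice.ny, : self.lattice.nz]


def traction_density(state: MonolayerState, params: EnergyParams) -> np.ndarray:
    """T(x) = sum_i phi_i(x) grad Pi(x) on the full lattice, shape (nx,ny,nz,3)."""
    _, pi = all_functional_derivatives(state, params)
    gx, gy, gz = central_gradient(pi, True, True, state.lattice.a0)
    sum_phi, _ = state.sum_fields()
    return np.stack([sum_phi * gx, sum_phi * gy, sum_phi * gz], axis=-1)


def coarse_grained_stress(
    T: np.ndarray, lattice: LatticeSpec, ell_stress: float, frame: int = 0
) -> StressField:
    """Coarse-grain the traction density into voxel stress tensors.

    The lattice is tiled with cubes of side ell_stress; within each cube
    the symmetrised outer product of T with the unit vector toward the
    cube centre is summed (the centre point itself, where the unit vector
    is undefined, is excluded; for even block sizes the centre falls
    between lattice points and no exclusion is needed) and scaled by
    1/(2 Vcg).
    """
    a0 = lattice.a0
    if ell_stress < 2 * a0:
        raise ValueError("ell_stress must be at least 2*a0")
    b = int(round(ell_stress / a0))
    nx, ny, nz = lattice.shape
    ncx, ncy, ncz = nx // b, ny // b, nz // b
    Tc = T[: ncx * b, : ncy * b, : ncz * b]
    # relative positions of lattice points within a voxel, toward the centre
    offs = (np.arange(b) + 0.5) * a0 - b * a0 / 2.0  # position minus centre
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    rel = np.stack([ox, oy, oz], axis=-1)  # x_m - x0
    norm = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = -rel / norm[..., None]  # e^n = (x0 - x_m)/|x0 - x_m|
    e[norm == 0] = 0.0  # excluded singular point (odd block sizes only)

    blocks = Tc.reshape(ncx, b, ncy, b, ncz, b, 3).transpose(0, 2, 4, 1, 3, 5, 6)
    # outer product T_i e_j summed over in-voxel points
    te = np.einsum("IJKabci,abcj->IJKij", blocks, e)
    vcg = (b * a0) ** 3
    sigma = (te + np.swapaxes(te, -1, -2)) / (2.0 * vcg)
    return StressField(sigma, b, lattice, frame)


def isotropic_and_shear_maps(
    field: StressField, normalized: bool = False, plane_trace: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """sigma_iso (trace/3, or in-plane trace/2) and sigma_xz per voxel.

    With ``normalized`` each map is divided by its maximum absolute value
    (an all-zero field stays zero by convention).
    """
    t = field.tensor
    if plane_trace:
        iso = (t[..., 0, 0] + t[..., 1, 1]) / 2.0
    else:
        iso = np.trace(t, axis1=-2, axis2=-1) / 3.0
    xz = t[..., 0, 2]
    if normalized:
        iso = iso / m if (m := float(np.max(np.abs(iso)))) > 0 else iso * 0.0
        xz = xz / m2 if (m2 := float(np.max(np.abs(xz)))) > 0 else xz * 0.0
    return iso, xz


def cell_stress_series(
    snapshots: Sequence[MonolayerState],
    stress_fields: Sequence[StressField],
    frame_steps: Sequence[int],
    events,
    dyn_params,
    window: tuple[float, float] = (-2.5, 0.3125),
    level: float = 0.5,
):
    """Per-event time series of cell-averaged normalised stresses.

    For each frame in the window around an extrusion, sigma_iso (and
    sigma_xz) averaged over the extruding cell's region R_i = {phi_i >=
    level}, divided by the average over the union region R of all cells.
    Frames where the cell has fully detached (empty R_i) truncate the
    series with a flag; windows extending past the trajectory are
    truncated and flagged.
    """
    import pandas as pd

    tau0, dt = dyn_params.tau0, dyn_params.dt
    tnorm = np.asarray(frame_steps) * dt / tau0
    rows = []
    for ev in events:
        te_norm = ev.t_e * dt / tau0
        lo, hi = te_norm + window[0], te_norm + window[1]
        idx = np.where((tnorm >= lo) & (tnorm <= hi))[0]
        truncated = bool(len(idx) == 0 or tnorm[0] > lo or tnorm[-1] < hi)
        for k in idx:
            state = snapshots[k]
            sf = stress_fields[k]
            iso, xz = isotropic_and_shear_maps(sf)
            iso_up = sf.upsample(iso)
            xz_up = sf.upsample(xz)
            union = np.zeros(state.lattice.shape, dtype=bool)
            target = None
            for c in state.cells:
                full_mask = np.zeros(state.lattice.shape, dtype=bool)
                ixs, iys = c.x_indices(state.lattice), c.y_indices(state.lattice)
                full_mask[np.ix_(ixs, iys, np.arange(state.lattice.nz))] = c.phi >= level
                union |= full_mask
                if c.id == ev.cell_id:
                    target = full_mask
            if target is None or not target.any():
                truncated = True
                break
            denom_iso = float(iso_up[union].mean())
            denom_xz = float(xz_up[union].mean())
            rows.append(
                {
                    "cell_id": ev.cell_id,
                    "t_e": ev.t_e,
                    "t_norm_rel": float(tnorm[k] - te_norm),
                    "iso_ratio": float(iso_up[target].mean()) / denom_iso
                    if denom_iso != 0
                    else np.nan,
                    "xz_ratio": float(xz_up[target].mean()) / denom_xz
                    if denom_xz != 0
                    else np.nan,
                    "truncated": truncated,
                }
            )
    return pd.DataFrame(
        rows, columns=["cell_id", "t_e", "t_norm_rel", "iso_ratio", "xz_ratio", "truncated"]
    )


def defect_frame_average(
    tracks: Sequence[DefectTrack],
    iso_frames: Sequence[np.ndarray],
    lattice: LatticeSpec,
    L: float,
    resolution: float = 1.0,
) -> np.ndarray:
    """Ensemble-average basal sigma_iso in the co-moving frame of +1/2 defects.

    For every frame of every +1/2 track, the basal-plane isotropic stress
    (``iso_frames``: one 2D lattice-resolution map per trajectory frame)
    is sampled on a square window of side L centred on the defect and
    rotated so the comet axis points along +x (bilinear interpolation,
    periodic wrap).  The accumulated maps are averaged and normalised by
    the maximum absolute value.
    """
    n = max(2, int(round(L / resolution)))
    u = np.linspace(-L / 2, L / 2, n)
    ux, uy = np.meshgrid(u, u, indexing="ij")
    acc = np.zeros((n, n))
    cnt = 0
    for tr in tracks:
        if tr.charge <= 0:
            continue
        for f, (x, y), psi in zip(tr.frames, tr.positions, tr.psis):
            if psi is None or f >= len(iso_frames):
                continue
            c, s = np.cos(psi), np.sin(psi)
            # window coords rotated so +x is the comet axis
            gx = (x + c * ux - s * uy) / lattice.a0
            gy = (y + s * ux + c * uy) / lattice.a0
            vals = map_coordinates(
                iso_frames[f], [gx, gy], order=1, mode="grid-wrap"
            )
            acc += vals
            cnt += 1
    if cnt == 0:
        raise ValueError("no +1/2 track frames with orientation available")
    mean = acc / cnt
    m = float(np.max(np.abs(mean)))
    return mean / m if m > 0 else mean
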