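"""Lattice geometry, the static substrate field, and per-cell field bookkeeping.

The monolayer lives in a cuboid that is periodic in x and y and bounded in
z.  Each cell carries its own phase field phi_i in [0, 1]; for performance
phi_i is stored on a rectangular x/y subdomain (with a recorded, periodic-
aware offset) spanning the full z extent.  The substrate is a static,
z-only phase field phi_w.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._fd import laplacian_1d_z
from ._kernels import (
    HAVE_NUMBA,
    gather_kernel,
    scatter_add_kernel,
    sum_fields_kernel,
)

__all__ = [
    "LatticeSpec",
    "SubstrateField",
    "CellField",
    "MonolayerState",
    "GeometryError",
    "DegenerateCellError",
    "make_substrate",
    "initialize_monolayer",
    "center_of_mass",
    "periodic_delta",
    "periodic_distance_xy",
]

#: phase-field values below this are treated as numerically zero support
SUPPORT_EPS = 1e-6


class GeometryError(ValueError):
    """Raised for invalid lattice / placement geometry."""


class DegenerateCellError(ValueError):
    """Raised when an operation meets an empty (all-zero) cell field."""


@dataclass(frozen=True)
class LatticeSpec:
    """Rectangular grid, periodic in x/y, bounded in z, spacing ``a0``."""

    nx: int = 320
    ny: int = 320
    nz: int = 64
    a0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 8:
            raise GeometryError("lattice needs at least 8 points per axis")
        if self.a0 <= 0:
            raise GeometryError("grid spacing a0 must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def extent(self) -> tuple[float, float, float]:
        return (self.nx * self.a0, self.ny * self.a0, self.nz * self.a0)

    def wrap_delta(self, d: np.ndarray) -> np.ndarray:
        """Minimal-image convention for x/y components of displacement(s)."""
        d = np.asarray(d, dtype=float).copy()
        for axis, L in ((0, self.nx * self.a0), (1, self.ny * self.a0)):
            d[..., axis] -= L * np.round(d[..., axis] / L)
        return d


def periodic_delta(p: np.ndarray, q: np.ndarray, lattice: LatticeSpec) -> np.ndarray:
    """Minimal-image displacement p - q (z treated as plain difference)."""
    return lattice.wrap_delta(np.asarray(p, float) - np.asarray(q, float))


def periodic_distance_xy(p, q, lattice: LatticeSpec) -> float:
    """In-plane minimal-image distance between two points (x, y[, z])."""
    d = periodic_delta(np.asarray(p, float)[:2].tolist() + [0.0],
                       np.asarray(q, float)[:2].tolist() + [0.0], lattice)
    return float(np.hypot(d[0], d[1]))


@dataclass(frozen=True)
class SubstrateField:
    """Static substrate phase field; depends on z only.

    phi_w(z) = 0.5 * (1 - tanh(2 (z - z_surface) / width)): 1 deep inside
    the slab at the bottom of the box, 0 in the bulk, 0.5 on the surface
    plane (the same midpoint convention used for the cell boundary).
    """

    lattice: LatticeSpec
    z_surface: float
    width: float
    profile: np.ndarray  # (nz,)

    @property
    def profile_sq(self) -> np.ndarray:
        if "_sq" not in self.__dict__:
            object.__setattr__(self, "_sq", self.profile**2)
        return self.__dict__["_sq"]

    @property
    def profile_lap(self) -> np.ndarray:
        if "_lap" not in self.__dict__:
            object.__setattr__(self, "_lap", laplacian_1d_z(self.profile, self.lattice.a0))
        return self.__dict__["_lap"]

    def as_3d(self) -> np.ndarray:
        return np.broadcast_to(self.profile, self.lattice.shape)


def make_substrate(
    lattice: LatticeSpec, interface_width: float, z_surface: float | None = None
) -> SubstrateField:
    """Build the static substrate slab with a diffuse top surface.

    The surface plane sits a few grid points above the box floor (default
    ``2 * interface_width``) so cell fields never touch the z=0 boundary.
    """
    if interface_width < 2 * lattice.a0:
        raise GeometryError("substrate interface width must be >= 2*a0")
    if interface_width > lattice.nz * lattice.a0 / 4:
        raise GeometryError("substrate interface width too large for box height")
    if z_surface is None:
        z_surface = 2.0 * interface_width
    z = np.arange(lattice.nz) * lattice.a0
    profile = 0.5 * (1.0 - np.tanh(2.0 * (z - z_surface) / interface_width))
    return SubstrateField(lattice, float(z_surface), float(interface_width), profile)


@dataclass
class CellField:
    """Phase field of one cell on an x/y subdomain spanning the full z range.

    ``offset`` maps subdomain indices to lattice indices:
    lattice_x = (offset[0] + i) % nx, and likewise in y.  The subdomain is
    padded so that phi is ~0 (< SUPPORT_EPS) on its x/y boundary.
    """

    id: int
    phi: np.ndarray  # (sx, sy, nz)
    offset: tuple[int, int]
    theta: float = 0.0
    extruded: bool = False

    def x_indices(self, lattice: LatticeSpec) -> np.ndarray:
        return (self.offset[0] + np.arange(self.phi.shape[0])) % lattice.nx

    def y_indices(self, lattice: LatticeSpec) -> np.ndarray:
        return (self.offset[1] + np.arange(self.phi.shape[1])) % lattice.ny

    def covers_full_x(self, lattice: LatticeSpec) -> bool:
        return self.phi.shape[0] >= lattice.nx

    def covers_full_y(self, lattice: LatticeSpec) -> bool:
        return self.phi.shape[1] >= lattice.ny

    def _blocks(self, lattice: LatticeSpec):
        """Contiguous (full_x, full_y, sub_x, sub_y) slice pairs.

        The periodic window splits into at most 2x2 contiguous blocks, so
        gather/scatter work on views instead of fancy-indexed copies.
        """
        def axis_slices(offset, size, n):
            if size >= n:
                return [(slice(0, n), slice(0, n))]
            end = offset + size
            if end <= n:
                return [(slice(offset, end), slice(0, size))]
            first = n - offset
            return [
                (slice(offset, n), slice(0, first)),
                (slice(0, end - n), slice(first, size)),
            ]

        sx, sy, _ = self.phi.shape
        for fx, sx_ in axis_slices(self.offset[0], sx, lattice.nx):
            for fy, sy_ in axis_slices(self.offset[1], sy, lattice.ny):
                yield fx, fy, sx_, sy_

    def to_full(self, lattice: LatticeSpec) -> np.ndarray:
        """Embed the subdomain field on the full lattice (round-trip exact)."""
        full = np.zeros(lattice.shape)
        for fx, fy, sx_, sy_ in self._blocks(lattice):
            full[fx, fy, :] = self.phi[sx_, sy_, :]
        return full

    def scatter_add(self, target: np.ndarray, lattice: LatticeSpec, values: np.ndarray | None = None) -> None:
        """Add this cell's (or given) subdomain values into a full-lattice array."""
        v = self.phi if values is None else values
        if HAVE_NUMBA:
            scatter_add_kernel(target, v, self.offset[0], self.offset[1])
            return
        for fx, fy, sx_, sy_ in self._blocks(lattice):
            target[fx, fy, :] += v[sx_, sy_, :]

    def gather(self, source: np.ndarray, lattice: LatticeSpec) -> np.ndarray:
        """Extract the full-lattice array on this cell's subdomain."""
        sx, sy, _ = self.phi.shape
        out = np.empty((min(sx, lattice.nx), min(sy, lattice.ny), lattice.nz))
        if HAVE_NUMBA:
            gather_kernel(source, out, self.offset[0], self.offset[1])
            return out
        for fx, fy, sx_, sy_ in self._blocks(lattice):
            out[sx_, sy_, :] = source[fx, fy, :]
        return out

    @classmethod
    def from_full(cls, cell_id: int, full: np.ndarray, lattice: LatticeSpec, theta: float = 0.0) -> "CellField":
        """Store a full-lattice field as a whole-box subdomain (offset 0)."""
        return cls(cell_id, np.array(full, dtype=float), (0, 0), theta)

    def copy(self) -> "CellField":
        return CellField(self.id, self.phi.copy(), self.offset, self.theta, self.extruded)


@dataclass
class MonolayerState:
    """Complete simulator state: lattice, cells, substrate, step, RNG."""

    lattice: LatticeSpec
    cells: list[CellField]
    substrate: SubstrateField
    step: int = 0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    def __post_init__(self) -> None:
        ids = [c.id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell ids must be unique")

    @property
    def active_cells(self) -> list[CellField]:
        return [c for c in self.cells if not c.extruded]

    def sum_fields(self) -> tuple[np.ndarray, np.ndarray]:
        """Full-lattice sums (sum_i phi_i, sum_i phi_i^2) over all cells."""
        s = np.zeros(self.lattice.shape)
        s2 = np.zeros(self.lattice.shape)
        for c in self.cells:
            if HAVE_NUMBA:
                sum_fields_kernel(s, s2, c.phi, c.offset[0], c.offset[1])
            else:
                c.scatter_add(s, self.lattice)
                c.scatter_add(s2, self.lattice, c.phi**2)
        return s, s2

    def copy(self) -> "MonolayerState":
        rng = np.random.default_rng()
        rng.bit_generator.state = self.rng.bit_generator.state
        return MonolayerState(
            self.lattice, [c.copy() for c in self.cells], self.substrate, self.step, rng
        )

    def centers_of_mass(self) -> np.ndarray:
        return np.array([center_of_mass(c, self.lattice) for c in self.cells])


def _sphere_field(radius: float, width: float, center: np.ndarray, lattice: LatticeSpec,
                  offset: tuple[int, int], shape: tuple[int, int]) -> np.ndarray:
    """tanh droplet profile on a subdomain, centred at *center* (lattice units)."""
    sx, sy = shape
    a0 = lattice.a0
    x = (offset[0] + np.arange(sx)) * a0
    y = (offset[1] + np.arange(sy)) * a0
    z = np.arange(lattice.nz) * a0
    r = np.sqrt(
        (x[:, None, None] - center[0]) ** 2
        + (y[None, :, None] - center[1]) ** 2
        + (z[None, None, :] - center[2]) ** 2
    )
    return 0.5 * (1.0 - np.tanh(2.0 * (r - radius) / width))


def make_droplet(cell_id: int, center, R0: float, width: float, lattice: LatticeSpec,
                 theta: float = 0.0, pad: float | None = None) -> CellField:
    """Spherical diffuse droplet on a tight subdomain around *center*."""
    if pad is None:
        pad = 2.5 * width
    a0 = lattice.a0
    center = np.asarray(center, float)
    half = int(np.ceil((R0 + pad + 2 * width) / a0))
    cx, cy = int(round(center[0] / a0)), int(round(center[1] / a0))
    sx = min(2 * half + 1, lattice.nx)
    sy = min(2 * half + 1, lattice.ny)
    ox = (cx - sx // 2) % lattice.nx if sx < lattice.nx else 0
    oy = (cy - sy // 2) % lattice.ny if sy < lattice.ny else 0
    # evaluate in unwrapped subdomain coordinates: shift center near subdomain middle
    ux = ox + sx // 2
    ccx = center[0] + (np.round((ux * a0 - center[0]) / (lattice.nx * a0)) * lattice.nx * a0 if sx < lattice.nx else 0.0)
    uy = oy + sy // 2
    ccy = center[1] + (np.round((uy * a0 - center[1]) / (lattice.ny * a0)) * lattice.ny * a0 if sy < lattice.ny else 0.0)
    phi = _sphere_field(R0, width, np.array([ccx, ccy, center[2]]), lattice, (ox, oy), (sx, sy))
    return CellField(cell_id, phi, (ox, oy), theta)


def initialize_monolayer(
    lattice: LatticeSpec,
    n_cells: int,
    R0: float,
    seed: int,
    interface_width: float = 2.0,
    substrate: SubstrateField | None = None,
    jitter: float = 0.0,
    centers: Sequence[Sequence[float]] | None = None,
) -> MonolayerState:
    """Seed N spherical droplets on a square lattice resting on the substrate.

    Cells sit tangent to the substrate surface (center height z_s + R0) on a
    gx x gy grid filling the periodic box; polarity angles are drawn
    uniformly from [-pi, pi).  ``jitter`` adds a uniform in-plane offset of
    up to ``jitter`` grid units to each center (used by relaxation fixtures).
    Explicit ``centers`` override the grid placement.
    """
    if R0 < 4 * lattice.a0:
        raise GeometryError("R0 must be at least 4*a0 to resolve the interface")
    if substrate is None:
        substrate = make_substrate(lattice, interface_width)
    rng = np.random.default_rng(seed)
    Lx, Ly, _ = lattice.extent
    if centers is None:
        gx = max(1, int(round(np.sqrt(n_cells * Lx / Ly))))
        gy = int(np.ceil(n_cells / gx))
        # prefer an exact factorisation matching the box aspect when one exists
        if gx * gy != n_cells:
            best = None
            for cand in range(1, n_cells + 1):
                if n_cells % cand:
                    continue
                asp = abs(np.log((cand / (n_cells / cand)) / (Lx / Ly)))
                if best is None or asp < best[0]:
                    best = (asp, cand)
            gx = best[1]
            gy = n_cells // gx
        dx, dy = Lx / gx, Ly / gy
        # confluent setups may compress mildly below tangency (hexagonal row
        # spacing is 0.87 * 2R0); genuinely overcrowded requests are errors
        if min(dx, dy) < 1.6 * R0:
            raise GeometryError(
                f"{n_cells} cells of radius {R0} do not fit: grid spacing "
                f"({dx:.1f}, {dy:.1f}) < 1.6*R0"
            )
        z0 = substrate.z_surface + R0
        centers = [
            ((i + 0.5) * dx, (j + 0.5) * dy, z0)
            for j in range(gy)
            for i in range(gx)
        ][:n_cells]
        if jitter > 0:
            centers = [
                (
                    (c[0] + rng.uniform(-jitter, jitter)) % Lx,
                    (c[1] + rng.uniform(-jitter, jitter)) % Ly,
                    c[2],
                )
                for c in centers
            ]
    elif len(centers) != n_cells:
        raise GeometryError("number of explicit centers must equal n_cells")

    thetas = rng.uniform(-np.pi, np.pi, size=n_cells)
    # seed at a non-overlapping radius; in compressed (confluent) setups the
    # volume constraint inflates cells gently instead of starting from
    # violently overlapping droplets
    seed_radius = R0
    if len(centers) > 1:
        pts = np.asarray(centers, float)
        d = pts[:, None, :] - pts[None, :, :]
        d = lattice.wrap_delta(d.reshape(-1, 3)).reshape(d.shape)
        dist = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        seed_radius = min(R0, float(dist.min()) / 2.0)
    cells = [
        make_droplet(
            i, np.asarray(c, float), seed_radius, interface_width, lattice,
            theta=float(thetas[i]), pad=2.5 * interface_width + (R0 - seed_radius),
        )
        for i, c in enumerate(centers)
    ]
    return MonolayerState(lattice, cells, substrate, step=0, rng=rng)


def center_of_mass(cell: CellField, lattice: LatticeSpec) -> np.ndarray:
    """phi-weighted mean position, periodic-unwrapped in x/y.

    For subdomain-stored cells the unwrapped subdomain coordinates make the
    mean unambiguous; whole-box fields fall back to a circular mean so a
    droplet straddling the seam is still centred correctly.
    """
    w = cell.phi
    tot = w.sum()
    if tot <= 0:
        raise DegenerateCellError(f"cell {cell.id}: empty phase field")
    a0 = lattice.a0
    z = float((w.sum(axis=(0, 1)) * np.arange(lattice.nz) * a0).sum() / tot)
    out = np.empty(3)
    for axis, (n_full, off, n_sub) in enumerate(
        [(lattice.nx, cell.offset[0], w.shape[0]), (lattice.ny, cell.offset[1], w.shape[1])]
    ):
        profile = w.sum(axis=tuple(i for i in range(3) if i != axis))
        if n_sub < n_full:
            coords = (off + np.arange(n_sub)) * a0
            out[axis] = float((profile * coords).sum() / tot) % (n_full * a0)
        else:
            L = n_full * a0
            ang = 2 * np.pi * (np.arange(n_full) * a0) / L
            mean_ang = np.arctan2((profile * np.sin(ang)).sum(), (profile * np.cos(ang)).sum())
            out[axis] = (mean_ang / (2 * np.pi) * L) % L
    out[2] = z
    return out
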