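"""Fused stencil kernels for the per-cell hot loops.

Numerics are identical to the numpy implementations (same discrete
operators: zero-embedded x/y boundaries on subdomain patches, zero-flux
z ends); the kernels only fuse the elementwise passes.  When numba is
unavailable the callers fall back to the numpy path.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every simulation test
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=False)
def cell_derivative_kernel(
    phi: np.ndarray,
    others_phi2: np.ndarray,
    others_lap: np.ndarray,
    phiw2: np.ndarray,
    lap_w: np.ndarray,
    c_bulk: float,  # gamma/lam * 8
    c_lap: float,  # 2 * gamma * lam
    c_vol: float,  # 4 mu / V0 * (1 - V/V0)
    c_ccr: float,  # 4 kappa_cc / lam
    c_cca: float,  # 2 omega_cc lam^2
    c_cwr: float,  # 2 kappa_cw / lam
    c_cwa: float,  # omega_cw lam^2
    inv_a0sq: float,
) -> np.ndarray:
    nx, ny, nz = phi.shape
    out = np.empty_like(phi)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = phi[i, j, k]
                # 7-point Laplacian, zero outside x/y, zero-flux in z
                lap = -4.0 * p
                if i > 0:
                    lap += phi[i - 1, j, k]
                if i < nx - 1:
                    lap += phi[i + 1, j, k]
                if j > 0:
                    lap += phi[i, j - 1, k]
                if j < ny - 1:
                    lap += phi[i, j + 1, k]
                if k > 0:
                    lap += phi[i, j, k - 1] - p
                else:
                    lap += 0.0
                if k < nz - 1:
                    lap += phi[i, j, k + 1] - p
                else:
                    lap += 0.0
                lap *= inv_a0sq
                val = c_bulk * p * (1.0 - p) * (1.0 - 2.0 * p) - c_lap * lap
                val += -c_vol * p
                val += c_ccr * p * others_phi2[i, j, k]
                val += -c_cca * (others_lap[i, j, k] - lap)
                val += c_cwr * p * phiw2[k]
                val += -c_cwa * lap_w[k]
                out[i, j, k] = val
    return out


@njit(cache=True, fastmath=False)
def upwind_update_kernel(
    phi: np.ndarray,
    deriv: np.ndarray,
    vx: float,
    vy: float,
    vz: float,
    dt: float,
    inv_a0: float,
) -> None:
    """phi += dt * (-deriv - v . grad_upwind phi), in place.

    Upwind one-sided differences; zero outside the patch in x/y,
    edge-replicated (zero-flux) in z.
    """
    nx, ny, nz = phi.shape
    old = phi.copy()
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                adv = 0.0
                if vx > 0.0:
                    left = old[i - 1, j, k] if i > 0 else 0.0
                    adv += vx * (old[i, j, k] - left) * inv_a0
                elif vx < 0.0:
                    right = old[i + 1, j, k] if i < nx - 1 else 0.0
                    adv += vx * (right - old[i, j, k]) * inv_a0
                if vy > 0.0:
                    left = old[i, j - 1, k] if j > 0 else 0.0
                    adv += vy * (old[i, j, k] - left) * inv_a0
                elif vy < 0.0:
                    right = old[i, j + 1, k] if j < ny - 1 else 0.0
                    adv += vy * (right - old[i, j, k]) * inv_a0
                if vz > 0.0:
                    below = old[i, j, k - 1] if k > 0 else old[i, j, 0]
                    adv += vz * (old[i, j, k] - below) * inv_a0
                elif vz < 0.0:
                    above = old[i, j, k + 1] if k < nz - 1 else old[i, j, nz - 1]
                    adv += vz * (above - old[i, j, k]) * inv_a0
                phi[i, j, k] += dt * (-deriv[i, j, k] - adv)


@njit(cache=True, fastmath=False)
def scatter_add_kernel(target: np.ndarray, values: np.ndarray, ox: int, oy: int) -> None:
    nx, ny, _ = target.shape
    sx, sy, sz = values.shape
    for i in range(sx):
        gi = (ox + i) % nx
        for j in range(sy):
            gj = (oy + j) % ny
            for k in range(sz):
                target[gi, gj, k] += values[i, j, k]


@njit(cache=True, fastmath=False)
def sum_fields_kernel(s: np.ndarray, s2: np.ndarray, phi: np.ndarray, ox: int, oy: int) -> None:
    """Accumulate phi and phi^2 into the global sums in one pass."""
    nx, ny, _ = s.shape
    sx, sy, sz = phi.shape
    for i in range(sx):
        gi = (ox + i) % nx
        for j in range(sy):
            gj = (oy + j) % ny
            for k in range(sz):
                p = phi[i, j, k]
                s[gi, gj, k] += p
                s2[gi, gj, k] += p * p


@njit(cache=True, fastmath=False)
def gather_kernel(source: np.ndarray, out: np.ndarray, ox: int, oy: int) -> None:
    nx, ny, _ = source.shape
    sx, sy, sz = out.shape
    for i in range(sx):
        gi = (ox + i) % nx
        for j in range(sy):
            gj = (oy + j) % ny
            for k in range(sz):
                out[i, j, k] = source[gi, gj, k]


@njit(cache=True, fastmath=False)
def sum_sq_kernel(phi: np.ndarray) -> float:
    total = 0.0
    flat = phi.ravel()
    for i in range(flat.size):
        total += flat[i] * flat[i]
    return total


@njit(cache=True, fastmath=False)
def patch_scan_kernel(phi: np.ndarray, level: float, ring: int):
    """Body (phi > level) centroid in patch indices + edge-proximity flags.

    Returns (weight, ci, cj, near_xlo, near_xhi, near_ylo, near_yhi).
    """
    sx, sy, sz = phi.shape
    w = 0.0
    ci = 0.0
    cj = 0.0
    xlo = False
    xhi = False
    ylo = False
    yhi = False
    for i in range(sx):
        for j in range(sy):
            for k in range(sz):
                p = phi[i, j, k]
                if p > level:
                    w += p
                    ci += p * i
                    cj += p * j
                    if i < ring:
                        xlo = True
                    if i >= sx - ring:
                        xhi = True
                    if j < ring:
                        ylo = True
                    if j >= sy - ring:
                        yhi = True
    if w > 0.0:
        ci /= w
        cj /= w
    return w, ci, cj, xlo, xhi, ylo, yhi


@njit(cache=True, fastmath=False)
def traction_reduce_kernel(
    phi: np.ndarray, gx: np.ndarray, gy: np.ndarray, gz: np.ndarray, dv: float
) -> np.ndarray:
    """t = dV * sum phi * (gx, gy, gz) over the patch (gathered gradients)."""
    nx, ny, nz = phi.shape
    tx = 0.0
    ty = 0.0
    tz = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p = phi[i, j, k]
                tx += p * gx[i, j, k]
                ty += p * gy[i, j, k]
                tz += p * gz[i, j, k]
    out = np.empty(3)
    out[0] = tx * dv
    out[1] = ty * dv
    out[2] = tz * dv
    return out
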