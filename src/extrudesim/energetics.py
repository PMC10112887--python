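"""Free energy of the multi-phase-field monolayer and its functional derivatives.

The energy has six contributions per cell: a Cahn–Hilliard term that
stabilises a diffuse interface of width lambda, a soft volume constraint
around V0 = (4/3) pi R0^3, steric cell–cell and cell–wall repulsion
(kappa terms, quadratic overlap of phi^2 profiles) and cell–cell /
cell–wall adhesion (omega terms, gradient–gradient coupling, which lowers
the energy of two overlapping diffuse interfaces with anti-parallel
gradients and therefore acts as attraction):

    F = sum_i gamma/lambda  Int 4 phi_i^2 (1-phi_i)^2 + lambda^2 |grad phi_i|^2
      + sum_i mu (1 - (1/V0) Int phi_i^2)^2
      + sum_i sum_{j!=i} kappa_cc/lambda Int phi_i^2 phi_j^2
      + sum_i sum_{j!=i} omega_cc lambda^2 Int grad phi_i . grad phi_j
      + sum_i kappa_cw/lambda Int phi_i^2 phi_w^2
      + sum_i omega_cw lambda^2 Int grad phi_i . grad phi_w

Gradient terms are discretised with forward differences so that the
analytic functional derivative below is the *exact* variation of the
discrete energy (see _fd).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fd import grad_energy, laplacian
from ._kernels import HAVE_NUMBA, cell_derivative_kernel, sum_sq_kernel
from .lattice import CellField, MonolayerState

__all__ = [
    "EnergyParams",
    "EnergyBreakdown",
    "NumericalStateError",
    "free_energy",
    "cell_volume_proxy",
    "functional_derivative",
    "all_functional_derivatives",
]


class NumericalStateError(RuntimeError):
    """Raised when fields carry non-finite or blown-up values."""


def target_volume(R0: float) -> float:
    return 4.0 / 3.0 * np.pi * R0**3


@dataclass(frozen=True)
class EnergyParams:
    """All couplings of the free energy, in lattice units.

    gamma : interface stiffness (cell stiffness)
    lam   : interface width lambda
    mu    : compressibility modulus of the soft volume constraint
    V0    : target cell volume, default (4/3) pi R0^3 with R0 = 8
    kappa_cc, kappa_cw : cell–cell / cell–wall repulsion strengths
    omega_cc, omega_cw : cell–cell / cell–wall adhesion strengths

    The adhesion ratio Omega = omega_cc / omega_cw is always derived,
    never stored.
    """

    gamma: float = 0.01
    lam: float = 3.0
    mu: float = 40.0
    V0: float = field(default_factory=lambda: target_volume(8.0))
    kappa_cc: float = 0.25
    kappa_cw: float = 0.15
    omega_cc: float = 0.001
    omega_cw: float = 0.0025

    def __post_init__(self) -> None:
        for name in ("gamma", "lam", "mu", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # kappas may be zero so wall-free / non-interacting fixtures exist
        for name in ("kappa_cc", "kappa_cw", "omega_cc", "omega_cw"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def omega_ratio(self) -> float:
        """Omega = omega_cc / omega_cw, the relative cell–cell adhesion."""
        if self.omega_cw == 0:
            return np.inf if self.omega_cc > 0 else 0.0
        return self.omega_cc / self.omega_cw

    @classmethod
    def from_ratio(cls, omega_cw: float, omega_ratio: float, **kwargs) -> "EnergyParams":
        return cls(omega_cw=omega_cw, omega_cc=omega_ratio * omega_cw, **kwargs)


@dataclass(frozen=True)
class EnergyBreakdown:
    cahn_hilliard: float
    volume: float
    cc_repulsion: float
    cc_adhesion: float
    cw_repulsion: float
    cw_adhesion: float

    @property
    def total(self) -> float:
        return (
            self.cahn_hilliard
            + self.volume
            + self.cc_repulsion
            + self.cc_adhesion
            + self.cw_repulsion
            + self.cw_adhesion
        )


def cell_volume_proxy(cell: CellField, a0: float = 1.0) -> float:
    """Int phi_i^2 dx — the volume measure inside the soft constraint."""
    return float(np.sum(cell.phi**2)) * a0**3


def free_energy(state: MonolayerState, params: EnergyParams) -> EnergyBreakdown:
    """Evaluate every term of the free energy by midpoint quadrature.

    Pairwise sums are evaluated through the identities
    sum_{i != j} phi_i^2 phi_j^2 = (sum phi_i^2)^2 - sum phi_i^4 and
    sum_{i != j} grad phi_i . grad phi_j = |grad sum phi_i|^2 - sum |grad phi_i|^2,
    so the cost is linear in N.
    """
    lat = state.lattice
    a0 = lat.a0
    dV = a0**3
    g, lam, mu = params.gamma, params.lam, params.mu

    sum_phi, sum_phi2 = state.sum_fields()
    if not np.isfinite(sum_phi).all():
        raise NumericalStateError("non-finite phase-field values")

    e_ch = 0.0
    e_vol = 0.0
    e_cwr = 0.0
    e_cwa = 0.0
    sum_grad_sq = 0.0  # sum_i Int |grad phi_i|^2
    sum_phi4_int = 0.0
    phiw = state.substrate.profile  # (nz,)
    phiw2 = phiw**2
    for c in state.cells:
        wx, wy = c.covers_full_x(lat), c.covers_full_y(lat)
        phi = c.phi
        own_grad = grad_energy(phi, wx, wy, a0)
        sum_grad_sq += own_grad
        e_ch += g / lam * (4.0 * float(np.sum(phi**2 * (1 - phi) ** 2)) * dV + lam**2 * own_grad)
        vol = float(np.sum(phi**2)) * dV
        e_vol += mu * (1.0 - vol / params.V0) ** 2
        sum_phi4_int += float(np.sum(phi**4)) * dV
        e_cwr += params.kappa_cw / lam * float(np.sum(phi**2 * phiw2[None, None, :])) * dV
        # wall gradient is z-only; keeping only z bonds is exact and avoids
        # spurious zero-padding differences on subdomain edges
        e_cwa += (
            params.omega_cw
            * lam**2
            * float(np.sum(np.diff(phi, axis=2) * np.diff(phiw)[None, None, :]))
            * a0
        )

    total_grad_sq = grad_energy(sum_phi, True, True, a0)
    e_cca = params.omega_cc * lam**2 * (total_grad_sq - sum_grad_sq)
    e_ccr = params.kappa_cc / lam * (float(np.sum(sum_phi2**2)) * dV - sum_phi4_int)

    return EnergyBreakdown(e_ch, e_vol, e_ccr, e_cca, e_cwr, e_cwa)


def _cell_derivative(
    cell: CellField,
    state: MonolayerState,
    params: EnergyParams,
    sum_phi2: np.ndarray,
    lap_sum_phi: np.ndarray,
) -> np.ndarray:
    lat = state.lattice
    a0 = lat.a0
    g, lam = params.gamma, params.lam
    wx, wy = cell.covers_full_x(lat), cell.covers_full_y(lat)
    phi = cell.phi
    vol = (sum_sq_kernel(phi) if HAVE_NUMBA else float(np.sum(phi**2))) * a0**3

    if HAVE_NUMBA and not wx and not wy:
        # fused stencil pass; identical discrete operators
        others_phi2 = cell.gather(sum_phi2, lat)
        others_phi2 -= phi**2
        return cell_derivative_kernel(
            phi,
            others_phi2,
            cell.gather(lap_sum_phi, lat),
            state.substrate.profile_sq,
            state.substrate.profile_lap,
            g / lam * 8.0,
            2.0 * g * lam,
            4.0 * params.mu / params.V0 * (1.0 - vol / params.V0),
            4.0 * params.kappa_cc / lam,
            2.0 * params.omega_cc * lam**2,
            2.0 * params.kappa_cw / lam,
            params.omega_cw * lam**2,
            1.0 / (a0 * a0),
        )

    lap_phi = laplacian(phi, wx, wy, a0)
    out = g / lam * (8.0 * phi * (1 - phi) * (1 - 2 * phi)) - 2.0 * g * lam * lap_phi

    out += -4.0 * params.mu / params.V0 * (1.0 - vol / params.V0) * phi

    others_phi2 = cell.gather(sum_phi2, lat) - phi**2
    out += 4.0 * params.kappa_cc / lam * phi * others_phi2

    others_lap = cell.gather(lap_sum_phi, lat) - lap_phi
    out += -2.0 * params.omega_cc * lam**2 * others_lap

    phiw2 = state.substrate.profile_sq
    out += 2.0 * params.kappa_cw / lam * phi * phiw2[None, None, :]
    out += -params.omega_cw * lam**2 * state.substrate.profile_lap[None, None, :]
    return out


def functional_derivative(state: MonolayerState, params: EnergyParams, cell_id: int) -> np.ndarray:
    """delta F / delta phi_i on the cell's subdomain (analytic variation)."""
    cell = next((c for c in state.cells if c.id == cell_id), None)
    if cell is None:
        raise KeyError(f"unknown cell id {cell_id}")
    sum_phi, sum_phi2 = state.sum_fields()
    lap_sum = laplacian(sum_phi, True, True, state.lattice.a0)
    return _cell_derivative(cell, state, params, sum_phi2, lap_sum)


def all_functional_derivatives(
    state: MonolayerState, params: EnergyParams
) -> tuple[list[np.ndarray], np.ndarray]:
    """delta F / delta phi_i for every cell, plus the total interaction scalar.

    Returns (per-cell derivative fields on their subdomains, Pi) where
    Pi(x) = sum_i -dF/dphi_i assembled on the full lattice — the scalar of
    the isotropic interaction tensor Pi_int entering the traction.
    """
    lat = state.lattice
    sum_phi, sum_phi2 = state.sum_fields()
    if not np.isfinite(sum_phi).all():
        raise NumericalStateError("non-finite phase-field values")
    lap_sum = laplacian(sum_phi, True, True, lat.a0)
    derivs: list[np.ndarray] = []
    pi = np.zeros(lat.shape)
    for c in state.cells:
        d = _cell_derivative(c, state, params, sum_phi2, lap_sum)
        derivs.append(d)
        c.scatter_add(pi, lat, -d)
    return derivs, pi
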