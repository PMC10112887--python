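"""Overdamped active dynamics of the monolayer and extrusion detection.

Each cell field obeys  d phi_i/dt + v_i . grad phi_i = -dF/dphi_i  with a
single rigid velocity per cell from the overdamped force balance

    xi v_i = t_i + alpha p_i,   t_i = Int phi_i grad(Pi) dx,

where Pi(x) = sum_j -dF/dphi_j is the scalar of the isotropic interaction
tensor and p_i = (cos theta_i, sin theta_i, 0) the in-plane polarity.
Polarity realigns toward the interaction force (contact inhibition of
locomotion):  d theta_i = -J |t_i| dtheta dt + sqrt(2 Dr dt) N(0,1), with
dtheta the signed angle from the in-plane traction to p_i.

An extrusion event is recorded the first time a cell's vertical
center-of-mass displacement relative to the median of the still-attached
cells exceeds R0/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._fd import central_gradient, upwind_gradient
from ._kernels import (
    HAVE_NUMBA,
    patch_scan_kernel,
    traction_reduce_kernel,
    upwind_update_kernel,
)
from .energetics import (
    EnergyParams,
    NumericalStateError,
    all_functional_derivatives,
    free_energy,
)
from .lattice import (
    CellField,
    DegenerateCellError,
    LatticeSpec,
    MonolayerState,
    center_of_mass,
)

__all__ = [
    "DynamicsParams",
    "ExtrusionEvent",
    "StabilityError",
    "SimulationResult",
    "interaction_traction",
    "cell_velocity",
    "advance_fields",
    "update_polarity",
    "detect_extrusions",
    "ExtrusionDetector",
    "run_simulation",
]


class StabilityError(RuntimeError):
    """Raised when the explicit scheme violates its CFL bound."""


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the overdamped dynamics, in lattice units.

    xi    : cell–substrate friction
    alpha : polarity (self-propulsion) force strength
    J     : CIL alignment rate constant
    Dr    : rotational diffusivity of the polarity angle
    dt    : explicit Euler time step
    n_steps : number of steps of a production run
    R0    : initial cell radius (sets tau0 and the extrusion threshold)
    """

    xi: float = 1.0
    alpha: float = 0.05
    J: float = 0.005
    Dr: float = 1e-4
    dt: float = 0.25
    n_steps: int = 29_000
    R0: float = 8.0
    seed: int = 0
    remove_extruded: bool = False
    #: subdivide a step when the advection CFL number would exceed cfl_target
    adaptive: bool = False
    cfl_target: float = 0.4

    def __post_init__(self) -> None:
        if self.xi <= 0 or self.dt < 0:
            raise ValueError("xi must be positive and dt non-negative")
        if self.alpha < 0 or self.J < 0 or self.Dr < 0:
            raise ValueError("alpha, J, Dr must be non-negative")

    @property
    def tau0(self) -> float:
        """Intrinsic time unit xi R0 / alpha used to normalise times."""
        if self.alpha == 0:
            return np.inf
        return self.xi * self.R0 / self.alpha


@dataclass(frozen=True)
class ExtrusionEvent:
    cell_id: int
    t_e: int  # time step of detection
    position: tuple[float, float, float]

    def t_e_normalized(self, params: DynamicsParams) -> float:
        return self.t_e * params.dt / params.tau0


def interaction_traction(
    state: MonolayerState, energy_params: EnergyParams, cell_id: int
) -> np.ndarray:
    """t_i = Int phi_i grad(Pi) dx for one cell (Pi = sum_j -dF/dphi_j)."""
    idx = next((k for k, c in enumerate(state.cells) if c.id == cell_id), None)
    if idx is None:
        raise KeyError(f"unknown cell id {cell_id}")
    _, pi = all_functional_derivatives(state, energy_params)
    return _tractions_from_pi(state, pi)[idx]


def _tractions_from_pi(state: MonolayerState, pi: np.ndarray) -> np.ndarray:
    lat = state.lattice
    grads = central_gradient(pi, True, True, lat.a0)
    dV = lat.a0**3
    t = np.zeros((len(state.cells), 3))
    for k, c in enumerate(state.cells):
        gx, gy, gz = (c.gather(g, lat) for g in grads)
        if HAVE_NUMBA:
            t[k] = traction_reduce_kernel(c.phi, gx, gy, gz, dV)
        else:
            for axis, g in enumerate((gx, gy, gz)):
                t[k, axis] = float(np.sum(c.phi * g)) * dV
    return t


def cell_velocity(t_i: np.ndarray, theta_i: float, params: DynamicsParams) -> np.ndarray:
    """v_i = (t_i + alpha p_i) / xi; polarity is strictly in-plane."""
    p = np.array([np.cos(theta_i), np.sin(theta_i), 0.0])
    return (np.asarray(t_i, float) + params.alpha * p) / params.xi


#: phase-field level whose support defines the cell body for patch bookkeeping
BODY_LEVEL = 0.25


def _scan_patch(phi: np.ndarray, ring: int):
    """Body centroid + edge-proximity flags (numpy fallback of the kernel)."""
    body = phi > BODY_LEVEL
    if not body.any():
        return 0.0, 0.0, 0.0, False, False, False, False
    w = np.where(body, phi, 0.0)
    tot = w.sum()
    sx, sy, _ = phi.shape
    ci = float((w.sum(axis=(1, 2)) * np.arange(sx)).sum() / tot)
    cj = float((w.sum(axis=(0, 2)) * np.arange(sy)).sum() / tot)
    return (
        tot, ci, cj,
        bool(body[:ring].any()), bool(body[-ring:].any()),
        bool(body[:, :ring].any()), bool(body[:, -ring:].any()),
    )


def _maintain_subdomain(cell: CellField, lat: LatticeSpec, margin: int = 4, ring: int = 3) -> None:
    """Keep the moving patch centred on the cell body and large enough.

    The patch travels with the cell (values shifted out — the small
    adhesion wetting halo — are dropped; newly entered area starts at
    zero) and grows by ``margin`` on any side the phi > 0.25 body
    approaches; it falls back to whole-box storage if it would span an
    axis.
    """
    phi = cell.phi
    sx, sy, _ = phi.shape
    scan = patch_scan_kernel(phi, BODY_LEVEL, ring) if HAVE_NUMBA else _scan_patch(phi, ring)
    w, ci, cj, xlo, xhi, ylo, yhi = scan
    if w <= 0.0:
        return

    # recenter by whole grid units once drifted by >= 2
    shift_x = int(round(ci - (sx - 1) / 2)) if sx < lat.nx else 0
    shift_y = int(round(cj - (sy - 1) / 2)) if sy < lat.ny else 0
    if abs(shift_x) >= 2 or abs(shift_y) >= 2:
        new = np.zeros_like(phi)
        xs_src = slice(max(0, shift_x), sx + min(0, shift_x))
        xs_dst = slice(max(0, -shift_x), sx + min(0, -shift_x))
        ys_src = slice(max(0, shift_y), sy + min(0, shift_y))
        ys_dst = slice(max(0, -shift_y), sy + min(0, -shift_y))
        new[xs_dst, ys_dst] = phi[xs_src, ys_src]
        cell.phi = phi = new
        cell.offset = (
            (cell.offset[0] + shift_x) % lat.nx,
            (cell.offset[1] + shift_y) % lat.ny,
        )

    grow = [
        margin if (xlo and sx < lat.nx) else 0,
        margin if (xhi and sx < lat.nx) else 0,
        margin if (ylo and sy < lat.ny) else 0,
        margin if (yhi and sy < lat.ny) else 0,
    ]
    if not any(grow):
        return
    nsx = sx + grow[0] + grow[1]
    nsy = sy + grow[2] + grow[3]
    if nsx >= lat.nx or nsy >= lat.ny:
        cell.phi = cell.to_full(lat)
        cell.offset = (0, 0)
        return
    new = np.zeros((nsx, nsy, phi.shape[2]))
    new[grow[0] : grow[0] + sx, grow[2] : grow[2] + sy] = phi
    cell.phi = new
    cell.offset = ((cell.offset[0] - grow[0]) % lat.nx, (cell.offset[1] - grow[2]) % lat.ny)


def advance_fields(
    state: MonolayerState,
    energy_params: EnergyParams,
    dyn_params: DynamicsParams,
    tractions: np.ndarray | None = None,
    derivs_pi: tuple[list[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """One explicit Euler step of the field equation for every cell, in place.

    Returns the per-cell tractions used for the step (needed afterwards by
    the polarity update).  ``dt = 0`` leaves the state bit-identical.
    """
    lat = state.lattice
    dt = dyn_params.dt
    derivs, pi = derivs_pi if derivs_pi is not None else all_functional_derivatives(
        state, energy_params
    )
    if tractions is None:
        tractions = _tractions_from_pi(state, pi)
    if dt == 0.0:
        state.step += 0
        return tractions

    def velocities_of(tr):
        vels = [cell_velocity(tr[k], c.theta, dyn_params) for k, c in enumerate(state.cells)]
        vmax = max(float(np.max(np.abs(v))) for v in vels)
        return vels, vmax

    velocities, vmax = velocities_of(tractions)
    n_sub = 1
    if dyn_params.adaptive:
        n_sub = int(np.ceil(vmax * dt / (dyn_params.cfl_target * lat.a0))) or 1
        if n_sub > 50:
            raise StabilityError(
                f"step {state.step}: needed {n_sub} substeps (max|v|={vmax:.3g}); "
                "reduce dt or couplings"
            )
    elif vmax * dt / lat.a0 >= 1.0:
        raise StabilityError(
            f"CFL violation at step {state.step}: max|v| dt/a0 = {vmax * dt / lat.a0:.3f}"
        )
    dt_sub = dt / n_sub

    removed = dyn_params.remove_extruded
    for sub in range(n_sub):
        if sub > 0:  # refresh forces between substeps
            derivs, pi = all_functional_derivatives(state, energy_params)
            tractions = _tractions_from_pi(state, pi)
            velocities, _ = velocities_of(tractions)
        for k, c in enumerate(state.cells):
            if removed and c.extruded:
                continue
            wx, wy = c.covers_full_x(lat), c.covers_full_y(lat)
            v = velocities[k]
            if HAVE_NUMBA and not wx and not wy:
                upwind_update_kernel(
                    c.phi, derivs[k], float(v[0]), float(v[1]), float(v[2]),
                    dt_sub, 1.0 / lat.a0,
                )
            else:
                adv = upwind_gradient(c.phi, v, wx, wy, lat.a0)
                c.phi += dt_sub * (-derivs[k] - adv)
            if np.max(np.abs(c.phi)) > 2.0:
                raise NumericalStateError(
                    f"phase field of cell {c.id} blew up at step {state.step}"
                )
            _maintain_subdomain(c, lat)
    state.step += 1
    return tractions


def _wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap to (-pi, pi]; exact -pi maps to +pi (deterministic tie-break)."""
    w = -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)
    return w


def update_polarity(
    state: MonolayerState, dyn_params: DynamicsParams, tractions: np.ndarray
) -> None:
    """CIL alignment + rotational diffusion for every polarity angle, in place.

    dtheta is the signed angle from the in-plane traction direction to the
    polarity; the drift -J |t| dtheta rotates the polarity toward the net
    interaction force.  Noise follows the Ito convention with increment
    sqrt(2 Dr dt) N(0, 1).
    """
    dt = dyn_params.dt
    if dt == 0.0:
        return
    noise = state.rng.standard_normal(len(state.cells))
    for k, c in enumerate(state.cells):
        t = tractions[k]
        tmag = float(np.linalg.norm(t))
        if tmag > 0.0 and np.hypot(t[0], t[1]) > 0.0:
            angle_t = np.arctan2(t[1], t[0])
            dtheta = float(_wrap_angle(c.theta - angle_t))
            drift = -dyn_params.J * tmag * dtheta
        else:
            drift = 0.0
        c.theta = float(
            _wrap_angle(c.theta + dt * drift + np.sqrt(2.0 * dyn_params.Dr * dt) * noise[k])
        )


class ExtrusionDetector:
    """Streaming R0/2 criterion on relative vertical COM displacement.

    Feed per-frame z centers of mass; a cell whose z-COM exceeds the median
    z-COM of the still-attached cells by more than R0/2 generates exactly
    one event and is excluded from the median thereafter.
    """

    def __init__(self, cell_ids: Sequence[int], R0: float):
        self.cell_ids = list(cell_ids)
        self.R0 = float(R0)
        self.extruded: set[int] = set()
        self.events: list[ExtrusionEvent] = []

    def update(self, step: int, coms: np.ndarray) -> list[ExtrusionEvent]:
        """coms: (n_cells, 3) array aligned with cell_ids. Returns new events."""
        active = [k for k, cid in enumerate(self.cell_ids) if cid not in self.extruded]
        if not active:
            return []
        med = float(np.median(coms[active, 2]))
        new = []
        for k in active:
            if coms[k, 2] - med > self.R0 / 2.0:
                ev = ExtrusionEvent(self.cell_ids[k], step, tuple(map(float, coms[k])))
                self.extruded.add(self.cell_ids[k])
                new.append(ev)
        self.events.extend(new)
        return new


def detect_extrusions(
    frames: Sequence[np.ndarray],
    cell_ids: Sequence[int],
    R0: float,
    frame_steps: Sequence[int] | None = None,
) -> list[ExtrusionEvent]:
    """Scan a trajectory of per-frame COM arrays for extrusion events."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames of centers of mass")
    if frame_steps is None:
        frame_steps = list(range(len(frames)))
    det = ExtrusionDetector(cell_ids, R0)
    for step, coms in zip(frame_steps, frames):
        det.update(step, np.asarray(coms, float))
    return det.events


@dataclass
class SimulationResult:
    """Everything a production run returns, ready for the analysis stack."""

    config: dict
    snapshots: list[MonolayerState]
    snapshot_steps: list[int]
    com_history: np.ndarray  # (n_steps+1, n_cells, 3)
    theta_history: np.ndarray  # (n_steps+1, n_cells)
    events: list[ExtrusionEvent]
    energy_log: pd.DataFrame
    dyn_params: DynamicsParams
    energy_params: EnergyParams

    @property
    def final_state(self) -> MonolayerState:
        return self.snapshots[-1]

    def events_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": e.cell_id,
                "t_e": e.t_e,
                "t_e_normalized": e.t_e_normalized(self.dyn_params),
                "x": e.position[0],
                "y": e.position[1],
                "z": e.position[2],
            }
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=["cell_id", "t_e", "t_e_normalized", "x", "y", "z"])


def run_simulation(
    state: MonolayerState,
    energy_params: EnergyParams,
    dyn_params: DynamicsParams,
    snapshot_every: int = 50,
    energy_every: int = 0,
    callback: Callable[[MonolayerState, int], None] | None = None,
) -> SimulationResult:
    """Advance the coupled field + polarity dynamics for n_steps.

    Snapshots (deep copies of the state) are kept every ``snapshot_every``
    steps; centers of mass and polarity angles are recorded every step.
    The energy breakdown is logged every ``energy_every`` steps (0 = off).
    Extrusion detection runs online; extruded cells are flagged and, when
    ``remove_extruded`` is set, dropped from the dynamics (their fields
    frozen) while remaining in all event records.
    """
    n_cells = len(state.cells)
    cell_ids = [c.id for c in state.cells]
    n_steps = dyn_params.n_steps
    com_hist = np.empty((n_steps + 1, n_cells, 3))
    theta_hist = np.empty((n_steps + 1, n_cells))
    snapshots = [state.copy()]
    snapshot_steps = [state.step]
    detector = ExtrusionDetector(cell_ids, dyn_params.R0)
    energy_rows = []

    def record_energy(step: int) -> None:
        eb = free_energy(state, energy_params)
        energy_rows.append(
            {
                "step": step,
                "cahn_hilliard": eb.cahn_hilliard,
                "volume": eb.volume,
                "cc_repulsion": eb.cc_repulsion,
                "cc_adhesion": eb.cc_adhesion,
                "cw_repulsion": eb.cw_repulsion,
                "cw_adhesion": eb.cw_adhesion,
                "total": eb.total,
            }
        )

    def safe_coms(previous: np.ndarray | None) -> np.ndarray:
        out = np.empty((n_cells, 3))
        for k, c in enumerate(state.cells):
            if dyn_params.remove_extruded and c.extruded and previous is not None:
                out[k] = previous[k]  # field frozen/zeroed at removal
                continue
            try:
                out[k] = center_of_mass(c, state.lattice)
            except DegenerateCellError:
                # a fully eliminated cell (field ground away after extrusion)
                # keeps its last COM; it stays flagged, never silently dropped
                if previous is None:
                    raise
                out[k] = previous[k]
                c.extruded = True
        return out

    coms = safe_coms(None)
    com_hist[0] = coms
    theta_hist[0] = [c.theta for c in state.cells]
    detector.update(state.step, coms)
    if energy_every:
        record_energy(state.step)

    for n in range(1, n_steps + 1):
        tractions = advance_fields(state, energy_params, dyn_params)
        update_polarity(state, dyn_params, tractions)
        coms = safe_coms(coms)
        com_hist[n] = coms
        theta_hist[n] = [c.theta for c in state.cells]
        for ev in detector.update(state.step, coms):
            cell = state.cells[cell_ids.index(ev.cell_id)]
            cell.extruded = True
            if dyn_params.remove_extruded:
                cell.phi[:] = 0.0
        if energy_every and n % energy_every == 0:
            record_energy(state.step)
        if n % snapshot_every == 0 or n == n_steps:
            snapshots.append(state.copy())
            snapshot_steps.append(state.step)
        if callback is not None:
            callback(state, state.step)

    return SimulationResult(
        config={},
        snapshots=snapshots,
        snapshot_steps=snapshot_steps,
        com_history=com_hist,
        theta_history=theta_hist,
        events=detector.events,
        energy_log=pd.DataFrame(energy_rows),
        dyn_params=dyn_params,
        energy_params=energy_params,
    )
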