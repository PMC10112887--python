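"""Configuration, scenarios, parameter sweeps, and standard-format writers.

Configs are flat key–value YAML files; every key has a documented default
and unknown keys are rejected.  Checkpoints are HDF5 (one file per
snapshot); tabular outputs (events, defect tracks, adjacency, energy
logs, histograms) are CSV with a schema-version comment line; volumetric
exports are legacy ASCII VTK structured points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .dynamics import DynamicsParams, ExtrusionEvent, SimulationResult, run_simulation
from .energetics import EnergyParams, target_volume
from .lattice import (
    LatticeSpec,
    MonolayerState,
    SubstrateField,
    CellField,
    initialize_monolayer,
    make_substrate,
)

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "ConfigError",
    "Scenario",
    "load_config",
    "save_config",
    "make_scenario",
    "build_state",
    "run_from_config",
    "run_sweep",
    "save_checkpoint",
    "load_checkpoint",
    "write_csv",
    "read_csv",
    "export_tracks",
    "write_vtk_volume",
]

SCHEMA_VERSION = 1

#: adhesion values used in the reference parameter sweep
REFERENCE_OMEGA_CW = (0.0015, 0.002, 0.0025)
REFERENCE_OMEGA_RATIO = (0.2, 0.4, 0.6)


class ConfigError(ValueError):
    """Raised for missing, unknown or out-of-range configuration keys."""


@dataclass
class RunConfig:
    """Flat, serialisable record of one simulation + analysis setup."""

    # lattice / geometry
    nx: int = 320
    ny: int = 320
    nz: int = 64
    a0: float = 1.0
    n_cells: int = 400
    R0: float = 8.0
    jitter: float = 0.0
    # energy couplings
    gamma: float = 0.01
    lam: float = 2.0
    mu: float = 40.0
    kappa_cc: float = 0.25
    kappa_cw: float = 0.15
    omega_cw: float = 0.0025
    omega_ratio: float = 0.4  # Omega = omega_cc / omega_cw
    # dynamics
    xi: float = 1.0
    alpha: float = 0.05
    J: float = 0.005
    Dr: float = 1e-4
    dt: float = 0.25
    n_steps: int = 29_000
    relax_steps: int = 400  # passive (alpha=0) pre-relaxation
    remove_extruded: bool = False
    adaptive_dt: bool = True
    seed: int = 0
    # analysis
    ell_dir: float | None = None  # default R0
    ell_stress: float | None = None  # default R0/4
    overlap_threshold: float = 1e-2
    dmin_window: tuple[float, float] = (-5.625, 0.625)
    zbar_window: tuple[float, float] = (-2.5, 0.3125)
    # output cadence
    snapshot_every: int = 50
    energy_every: int = 0

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ConfigError("xi must be positive")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        for key in ("gamma", "mu", "kappa_cc", "kappa_cw", "R0", "a0"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive")
        if self.omega_cw < 0 or self.omega_ratio < 0:
            raise ConfigError("omega_cw and omega_ratio must be non-negative")
        if self.omega_cw and self.omega_cw not in REFERENCE_OMEGA_CW:
            warnings.warn(
                f"omega_cw={self.omega_cw} outside the reference sweep {REFERENCE_OMEGA_CW}",
                stacklevel=2,
            )
        if self.omega_ratio and self.omega_ratio not in REFERENCE_OMEGA_RATIO:
            warnings.warn(
                f"omega_ratio={self.omega_ratio} outside the reference sweep "
                f"{REFERENCE_OMEGA_RATIO}",
                stacklevel=2,
            )

    # ---- derived parameter records -------------------------------------
    def lattice(self) -> LatticeSpec:
        return LatticeSpec(self.nx, self.ny, self.nz, self.a0)

    def energy_params(self) -> EnergyParams:
        return EnergyParams(
            gamma=self.gamma,
            lam=self.lam,
            mu=self.mu,
            V0=target_volume(self.R0),
            kappa_cc=self.kappa_cc,
            kappa_cw=self.kappa_cw,
            omega_cc=self.omega_ratio * self.omega_cw,
            omega_cw=self.omega_cw,
        )

    def dynamics_params(self, alpha: float | None = None, n_steps: int | None = None) -> DynamicsParams:
        return DynamicsParams(
            xi=self.xi,
            alpha=self.alpha if alpha is None else alpha,
            J=self.J,
            Dr=self.Dr,
            dt=self.dt,
            n_steps=self.n_steps if n_steps is None else n_steps,
            R0=self.R0,
            seed=self.seed,
            remove_extruded=self.remove_extruded,
            adaptive=self.adaptive_dt,
        )

    @property
    def ell_dir_value(self) -> float:
        return self.R0 if self.ell_dir is None else self.ell_dir

    @property
    def ell_stress_value(self) -> float:
        return max(2 * self.a0, self.R0 / 4) if self.ell_stress is None else self.ell_stress


_TUPLE_KEYS = {"dmin_window", "zbar_window"}


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a flat YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in _TUPLE_KEYS & set(raw):
        raw[key] = tuple(raw[key])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    d = asdict(config)
    for key in _TUPLE_KEYS:
        d[key] = list(d[key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def build_state(config: RunConfig, centers=None) -> MonolayerState:
    """Initial monolayer for a config (droplets on a grid, on the substrate)."""
    lat = config.lattice()
    sub = make_substrate(lat, config.lam, z_surface=2.0 * config.lam)
    return initialize_monolayer(
        lat,
        config.n_cells,
        config.R0,
        seed=config.seed,
        interface_width=config.lam,
        substrate=sub,
        jitter=config.jitter,
        centers=centers,
    )


def run_from_config(
    config: RunConfig, state: MonolayerState | None = None
) -> SimulationResult:
    """Passive pre-relaxation followed by the production run."""
    if state is None:
        state = build_state(config)
    ep = config.energy_params()
    if config.relax_steps > 0:
        run_simulation(
            state,
            ep,
            config.dynamics_params(alpha=0.0, n_steps=config.relax_steps),
            snapshot_every=max(1, config.relax_steps),
        )
        state.step = 0
    result = run_simulation(
        state,
        ep,
        config.dynamics_params(),
        snapshot_every=config.snapshot_every,
        energy_every=config.energy_every,
    )
    result.config = asdict(config)
    return result


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------

@dataclass
class Scenario:
    name: str
    config: RunConfig
    state: MonolayerState


def make_scenario(name: str, seed: int = 0) -> Scenario:
    """Named, seed-deterministic study setups.

    passive_hex_relax       12 passive cells from a jittered square start in a
                            hexagon-commensurate box; relaxes to sixfold packing.
    two_cell_adhesion       two droplets in contact; Omega tunable afterwards.
    small_active_monolayer  25 confluent active cells on a reduced grid with
                            the reference adhesion ratios.
    reference_scale             the full-scale setup (320x320x64, 400 cells,
                            29,000 steps) — constructible, not run in tests.
    """
    if name == "passive_hex_relax":
        # box commensurate with a 3 x 4 staggered (hexagonal) packing of R0=6;
        # cells are seeded near the triangular arrangement with substantial
        # jitter and must relax back into sixfold coordination
        cfg = RunConfig(
            nx=39, ny=45, nz=28, n_cells=12, R0=6.0, jitter=2.0,
            alpha=0.0, J=0.0, Dr=0.0, n_steps=2500, relax_steps=0,
            snapshot_every=250, seed=seed, overlap_threshold=2e-2,
        )
        lat = cfg.lattice()
        sub = make_substrate(lat, cfg.lam, z_surface=2.0 * cfg.lam)
        rng = np.random.default_rng(seed)
        dx, dy = cfg.nx / 3.0, cfg.ny / 4.0
        z0 = sub.z_surface + cfg.R0
        centers = []
        for r in range(4):
            off = (dx / 2.0) * (r % 2)
            for c in range(3):
                centers.append((
                    ((c + 0.5) * dx + off + rng.uniform(-cfg.jitter, cfg.jitter)) % cfg.nx,
                    ((r + 0.5) * dy + rng.uniform(-cfg.jitter, cfg.jitter)) % cfg.ny,
                    z0,
                ))
        state = initialize_monolayer(
            lat, 12, cfg.R0, seed=seed, interface_width=cfg.lam,
            substrate=sub, centers=centers,
        )
        return Scenario(name, cfg, state)
    if name == "two_cell_adhesion":
        cfg = RunConfig(
            nx=48, ny=32, nz=24, n_cells=2, R0=6.0,
            alpha=0.0, J=0.0, Dr=0.0, n_steps=800, relax_steps=0,
            snapshot_every=200, seed=seed,
        )
        lat = cfg.lattice()
        sub = make_substrate(lat, cfg.lam, z_surface=2.0 * cfg.lam)
        z0 = sub.z_surface + cfg.R0
        centers = [(18.0, 16.0, z0), (29.0, 16.0, z0)]  # 11 < 2 R0 apart
        state = initialize_monolayer(
            lat, 2, cfg.R0, seed=seed, interface_width=cfg.lam,
            substrate=sub, centers=centers,
        )
        return Scenario(name, cfg, state)
    if name == "small_active_monolayer":
        cfg = RunConfig(
            nx=60, ny=60, nz=28, n_cells=25, R0=6.0,
            n_steps=6000, relax_steps=400, snapshot_every=60,
            seed=seed, energy_every=0,
        )
        return Scenario(name, cfg, build_state(cfg))
    if name == "reference_scale":
        cfg = RunConfig(seed=seed)
        return Scenario(name, cfg, build_state(cfg))
    raise ConfigError(f"unknown scenario {name!r}")


# --------------------------------------------------------------------------
# parameter sweep
# --------------------------------------------------------------------------

def sweep_seed(master_seed: int, case_index: int, realization: int) -> int:
    """Documented seed derivation: one independent stream per (case, realization)."""
    ss = np.random.SeedSequence([master_seed, case_index, realization])
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(
    base_config: RunConfig,
    omega_cw_values: Sequence[float] = REFERENCE_OMEGA_CW,
    omega_ratio_values: Sequence[float] = REFERENCE_OMEGA_RATIO,
    n_realizations: int = 4,
    seed: int = 0,
    out_dir: str | Path | None = None,
    execute: bool = True,
) -> pd.DataFrame:
    """Enumerate (and optionally execute) the adhesion parameter sweep.

    Runs the grid {omega_cw} x {Omega} x realizations with derived seeds.
    The returned manifest records every run's parameters, seed and output
    path; completed runs (events file already present) are skipped on
    re-execution.
    """
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    case = 0
    for wcw in omega_cw_values:
        for ratio in omega_ratio_values:
            for real in range(n_realizations):
                run_seed = sweep_seed(seed, case, real)
                cfg = RunConfig(
                    **{
                        **asdict(base_config),
                        "omega_cw": wcw,
                        "omega_ratio": ratio,
                        "seed": run_seed,
                    }
                )
                tag = f"wcw{wcw:g}_om{ratio:g}_r{real}"
                path = out_dir / tag if out_dir else None
                status = "pending"
                n_events = np.nan
                if path is not None and (path / "events.csv").exists():
                    status = "skipped"
                elif execute:
                    result = run_from_config(cfg)
                    n_events = len(result.events)
                    status = "done"
                    if path is not None:
                        path.mkdir(parents=True, exist_ok=True)
                        write_csv(result.events_frame(), path / "events.csv")
                        save_config(cfg, path / "config.yaml")
                rows.append(
                    {
                        "case": case,
                        "realization": real,
                        "omega_cw": wcw,
                        "omega_ratio": ratio,
                        "seed": run_seed,
                        "out": str(path) if path else "",
                        "status": status,
                        "n_events": n_events,
                    }
                )
            case += 1
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# writers / readers
# --------------------------------------------------------------------------

def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with a schema-version comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# extrudesim-schema {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_checkpoint(state: MonolayerState, path: str | Path) -> None:
    """One HDF5 file per snapshot: per-cell subdomains, substrate, RNG state."""
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.attrs["step"] = state.step
        f.attrs["lattice"] = json.dumps(asdict(state.lattice))
        f.attrs["rng_state"] = json.dumps(state.rng.bit_generator.state)
        sub = f.create_group("substrate")
        sub.create_dataset("profile", data=state.substrate.profile)
        sub.attrs["z_surface"] = state.substrate.z_surface
        sub.attrs["width"] = state.substrate.width
        cells = f.create_group("cells")
        for c in state.cells:
            g = cells.create_group(str(c.id))
            g.create_dataset("phi", data=c.phi, compression="gzip", compression_opts=4)
            g.attrs["offset"] = c.offset
            g.attrs["theta"] = c.theta
            g.attrs["extruded"] = c.extruded


def load_checkpoint(path: str | Path) -> MonolayerState:
    with h5py.File(path, "r") as f:
        lat = LatticeSpec(**json.loads(f.attrs["lattice"]))
        sub = SubstrateField(
            lat,
            float(f["substrate"].attrs["z_surface"]),
            float(f["substrate"].attrs["width"]),
            f["substrate/profile"][...],
        )
        cells = []
        for key in sorted(f["cells"], key=int):
            g = f["cells"][key]
            cells.append(
                CellField(
                    int(key),
                    g["phi"][...],
                    tuple(int(v) for v in g.attrs["offset"]),
                    float(g.attrs["theta"]),
                    bool(g.attrs["extruded"]),
                )
            )
        rng = np.random.default_rng()
        rng.bit_generator.state = json.loads(f.attrs["rng_state"])
        return MonolayerState(lat, cells, sub, int(f.attrs["step"]), rng)


def export_tracks(
    out_dir: str | Path,
    events: Sequence[ExtrusionEvent] | None = None,
    dyn_params: DynamicsParams | None = None,
    defect_tracks=None,
    graphs=None,
    frame_steps: Sequence[int] | None = None,
) -> dict[str, Path]:
    """Write events / defect tracks / adjacency tables as schema-stamped CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if events is not None:
        rows = [
            {
                "cell_id": e.cell_id,
                "t_e": e.t_e,
                "t_e_normalized": e.t_e_normalized(dyn_params) if dyn_params else np.nan,
                "x": e.position[0],
                "y": e.position[1],
                "z": e.position[2],
            }
            for e in events
        ]
        df = pd.DataFrame(rows, columns=["cell_id", "t_e", "t_e_normalized", "x", "y", "z"])
        p = out_dir / "events.csv"
        write_csv(df, p)
        written["events"] = p
    if defect_tracks is not None:
        rows = []
        for tr in defect_tracks:
            for frame, (x, y), psi in zip(tr.frames, tr.positions, tr.psis):
                rows.append(
                    {
                        "track_id": tr.track_id,
                        "charge": tr.charge,
                        "frame": frame,
                        "x": x,
                        "y": y,
                        "psi": np.nan if psi is None else psi,
                    }
                )
        df = pd.DataFrame(rows, columns=["track_id", "charge", "frame", "x", "y", "psi"])
        p = out_dir / "defect_tracks.csv"
        write_csv(df, p)
        written["defect_tracks"] = p
    if graphs is not None:
        rows = []
        steps = frame_steps if frame_steps is not None else range(len(graphs))
        for step, g in zip(steps, graphs):
            for i, j, data in g.edges(data=True):
                rows.append(
                    {"frame": step, "i": i, "j": j, "weight": data.get("weight", np.nan)}
                )
        df = pd.DataFrame(rows, columns=["frame", "i", "j", "weight"])
        p = out_dir / "adjacency.csv"
        write_csv(df, p)
        written["adjacency"] = p
    return written


def write_vtk_volume(state: MonolayerState, path: str | Path) -> None:
    """Legacy ASCII VTK structured points: global phi = max_i phi_i + cell ids."""
    lat = state.lattice
    phi_max = np.zeros(lat.shape)
    owner = np.full(lat.shape, -1, dtype=int)
    for c in state.cells:
        full = c.to_full(lat)
        better = full > phi_max
        phi_max[better] = full[better]
        owner[better & (full > 0.5)] = c.id
    nx, ny, nz = lat.shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"extrudesim volume (schema {SCHEMA_VERSION}) step {state.step}\n")
        f.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {lat.a0} {lat.a0} {lat.a0}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write("SCALARS phi float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, phi_max.transpose(2, 1, 0).reshape(-1, 1), fmt="%.5g")
        f.write("SCALARS cell_id int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, owner.transpose(2, 1, 0).reshape(-1, 1), fmt="%d")
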