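"""End-to-end analysis of a simulation: orientation/defect/coordination and
stress fields per snapshot, extrusion statistics, and the Poisson-null
correlation test.  Composes the topology, stress and stats operations; the
individual operations remain the public API for finer control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import SimulationResult
from .stats import CorrelationTestReport, extrusion_defect_test, generate_null_events
from .stress import (
    coarse_grained_stress,
    defect_frame_average,
    isotropic_and_shear_maps,
    traction_density,
)
from .topology import (
    DefectPoint,
    DefectTrack,
    DirectorField,
    basal_plane_index,
    basal_projection,
    cell_orientation,
    coarse_grain_director,
    detect_defects,
    min_distance_series,
    min_distance_static,
    neighbor_graph,
    track_defects,
)

__all__ = ["FrameAnalysis", "TrajectoryAnalysis", "analyze_trajectory", "null_correlation_test"]


@dataclass
class FrameAnalysis:
    """Per-snapshot analysis products."""

    step: int
    director: DirectorField | None
    defects: list[DefectPoint]
    graph: nx.Graph
    areas: dict[int, float]
    basal_iso: np.ndarray | None  # basal-plane sigma_iso at lattice resolution


@dataclass
class TrajectoryAnalysis:
    """Everything the statistics of a run are built from."""

    frames: list[FrameAnalysis]
    frame_steps: list[int]
    tracks: list[DefectTrack]
    dmin: pd.DataFrame
    zbar: pd.DataFrame
    result: SimulationResult

    def coordination_numbers(self) -> np.ndarray:
        """Pooled coordination numbers over all frames and cells."""
        return np.array(
            [fr.graph.nodes[n]["z"] for fr in self.frames for n in fr.graph.nodes]
        )


def analyze_trajectory(
    result: SimulationResult,
    ell_dir: float | None = None,
    ell_stress: float | None = None,
    overlap_threshold: float = 1e-2,
    with_stress: bool = True,
    dmin_window: tuple[float, float] = (-5.625, 0.625),
    zbar_window: tuple[float, float] = (-2.5, 0.3125),
    director_spacing: float | None = None,
) -> TrajectoryAnalysis:
    """Run the full analysis stack over a simulation's snapshots."""
    dyn = result.dyn_params
    R0 = dyn.R0
    if ell_dir is None:
        ell_dir = R0
    if ell_stress is None:
        ell_stress = max(2.0, R0 / 4)
    frames: list[FrameAnalysis] = []
    detections: list[list[DefectPoint]] = []
    for state, step in zip(result.snapshots, result.snapshot_steps):
        lat = state.lattice
        feet = basal_projection(state)
        angs, poss, anis, areas = [], [], [], {}
        for c in state.cells:
            fp = feet[c.id]
            if fp.empty:
                continue
            a, s = cell_orientation(fp)
            angs.append(a)
            anis.append(s)
            poss.append(fp.centroid(lat))
            areas[c.id] = fp.area(lat)
        director = None
        dets: list[DefectPoint] = []
        if len(angs) >= 3:
            director = coarse_grain_director(
                angs, poss, lat, ell_dir, anisotropies=anis, node_spacing=director_spacing
            )
            dets = detect_defects(director)
        graph = neighbor_graph(state, overlap_threshold)
        basal_iso = None
        if with_stress:
            T = traction_density(state, result.energy_params)
            sf = coarse_grained_stress(T, lat, ell_stress, frame=step)
            iso, _ = isotropic_and_shear_maps(sf)
            k = basal_plane_index(state)
            basal_iso = sf.upsample(iso)[:, :, k]
        frames.append(FrameAnalysis(step, director, dets, graph, areas, basal_iso))
        detections.append(dets)

    lattice = result.snapshots[0].lattice
    if len(detections) >= 2:
        tracks = track_defects(detections, lattice, gate=R0)
    else:
        tracks = []
    cell_ids = [c.id for c in result.snapshots[0].cells]
    dmin = min_distance_series(
        result.events, tracks, result.com_history, cell_ids,
        result.snapshot_steps, dyn, lattice, window=dmin_window,
    )
    from .topology import coordination_history

    zbar = coordination_history(
        result.events, [fr.graph for fr in frames], result.snapshot_steps,
        dyn, window=zbar_window,
    )
    return TrajectoryAnalysis(frames, list(result.snapshot_steps), tracks, dmin, zbar, result)


def null_correlation_test(
    analysis: TrajectoryAnalysis,
    n_realizations: int = 5,
    seed: int = 0,
    charge: str = "plus",
    alpha: float = 0.05,
) -> CorrelationTestReport:
    """KS test of simulated d~min against Poisson-null surrogate events.

    Surrogate extrusions are placed uniformly on the basal plane with
    Poisson counts at the observed intensity and uniform times; their
    d~min is measured against the *same* defect tracks as the simulation.
    """
    result = analysis.result
    dyn = result.dyn_params
    lattice = result.snapshots[0].lattice
    col = f"dmin_{charge}"
    sim = analysis.dmin[col].dropna().to_numpy()
    if len(sim) == 0:
        raise ValueError("no finite simulated d~min values")
    Lx, Ly, _ = lattice.extent
    null_sets = generate_null_events(
        max(1, len(analysis.dmin)), (Lx, Ly), dyn.n_steps, n_realizations, seed
    )
    null_dmins = []
    for ns in null_sets:
        df = min_distance_static(
            ns.positions, ns.times, analysis.tracks, analysis.frame_steps, dyn, lattice
        )
        null_dmins.append(df[col].dropna().to_numpy())
    return extrusion_defect_test(sim, null_dmins, alpha=alpha)


def defect_stress_map(
    analysis: TrajectoryAnalysis, L: float | None = None
) -> np.ndarray:
    """Ensemble defect-frame averaged basal sigma_iso map (comet axis -> +x)."""
    result = analysis.result
    if L is None:
        L = 1.5 * result.dyn_params.R0
    iso_frames = [fr.basal_iso for fr in analysis.frames]
    if any(f is None for f in iso_frames):
        raise ValueError("stress maps were not computed for this analysis")
    lattice = result.snapshots[0].lattice
    return defect_frame_average(analysis.tracks, iso_frames, lattice, L)
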