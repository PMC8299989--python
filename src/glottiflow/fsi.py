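"""Simplified fluid-structure interaction of vocal-fold vibration.

The two folds are represented by one mirror-symmetric wall of lateral-only
oscillators on the medial-surface grid: each node carries a mass, a linear
restoring spring toward the prephonatory position and a dashpot, with
nearest-neighbour elastic coupling that supports a mucosal-wave-like phase
lag along the flow direction.  Anterior/posterior edge columns are anchored.

Coupling is staggered and explicit: each step rebuilds the airway channel
from the nodal positions, solves the quasi-steady flow (plain Bernoulli with
``fr = 0``, or the learned-resistance model through the self-consistent
loop), applies the sectional pressures as nodal loads and advances the solid
with a symplectic-Euler update plus contact enforcement (the gap never drops
below the contact floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .dnn import TrainedModel
from .flow import (
    ConvergenceError,
    FlowSolution,
    NoRealSolutionError,
    pressure_distribution,
    solve_flow_rate,
    solve_self_consistent,
)
from .geometry import FluidProperties, FlowConditions, discretize_channel
from .shapes import AirwayChannel, MedialSurface, PrephonatoryParams, extrude_airway, _taper

__all__ = [
    "SolidWallModel",
    "FSIState",
    "FSITrace",
    "BlowUpError",
    "NoCycleError",
    "step_solid",
    "run_fsi",
    "extract_cycle_shapes",
    "analyze_trace",
    "mechanical_energy",
    "VOCAL_FOLD_LAYERS",
]

#: Layered tissue properties of the reference continuum vocal-fold model
#: (cover / ligament / body), shipped as documented metadata only: the
#: simplified wall model below does not resolve layers.  Units: density
#: g/cm^3, moduli kPa.
VOCAL_FOLD_LAYERS = {
    "cover": {"rho": 1.043, "Ep": 2.01, "vp": 0.9, "Epz": 40.0, "vpz": 0.0, "Gpz": 10.0},
    "ligament": {"rho": 1.043, "Ep": 3.31, "vp": 0.9, "Epz": 66.0, "vpz": 0.0, "Gpz": 40.0},
    "body": {"rho": 1.043, "Ep": 3.99, "vp": 0.9, "Epz": 80.0, "vpz": 0.0, "Gpz": 20.0},
}


class BlowUpError(RuntimeError):
    """Solid displacement exceeded the physical bound (instability)."""


class NoCycleError(RuntimeError):
    """No converged oscillation cycle found in the trace."""


@dataclass(frozen=True)
class SolidWallModel:
    """Lateral-only elastic wall on the medial-surface grid.

    Per-area parameters are converted to per-node values through the grid
    patch area, so refining the grid leaves the continuum dynamics
    unchanged; ``coupling_stiffness`` acts between adjacent nodes on the
    relative displacement.  The defaults oscillate near 130 Hz at a 1 kPa
    driving pressure.
    """

    geometry: PrephonatoryParams = field(
        default_factory=lambda: PrephonatoryParams(
            half_gap_inferior=0.0,
            half_gap_superior=0.0,
            initial_half_gap_dx=0.002,
            mesh_resolution=0.03,
        )
    )
    ny: int = 9
    nz: int = 15
    mass_per_area: float = 0.15  # g/cm^2
    stiffness_per_area: float = 1.0e5  # dyn/cm^3
    damping_per_area: float = 8.0  # dyn*s/cm^3
    coupling_stiffness: float = 50.0  # dyn/cm per node pair
    contact_floor_gap: float = 1e-3  # cm (full gap)

    def __post_init__(self) -> None:
        if self.mass_per_area <= 0 or self.stiffness_per_area <= 0:
            raise ValueError("mass and stiffness must be > 0")
        if self.damping_per_area < 0 or self.coupling_stiffness < 0:
            raise ValueError("damping and coupling must be >= 0")

    @property
    def y_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.geometry.medial_thickness_T, self.ny)

    @property
    def z_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.geometry.fold_length_L, self.nz)

    @property
    def patch_area(self) -> float:
        dy = self.geometry.medial_thickness_T / (self.ny - 1)
        dz = self.geometry.fold_length_L / (self.nz - 1)
        return dy * dz

    @property
    def node_mass(self) -> float:
        return self.mass_per_area * self.patch_area

    @property
    def node_stiffness(self) -> float:
        return self.stiffness_per_area * self.patch_area

    @property
    def node_damping(self) -> float:
        return self.damping_per_area * self.patch_area

    @cached_property
    def _rest_half_gap(self) -> np.ndarray:
        p = self.geometry
        y, z = self.y_grid, self.z_grid
        h = p.half_gap_inferior + (p.half_gap_superior - p.half_gap_inferior) * (
            y / p.medial_thickness_T
        )
        g = _taper(z, p.fold_length_L)[None, :] * (
            h[:, None] + p.initial_half_gap_dx
        )
        g.setflags(write=False)
        return g

    def rest_half_gap(self) -> np.ndarray:
        """Prephonatory half-gap field on the solid grid (tapered)."""
        return self._rest_half_gap


@dataclass
class FSIState:
    """Nodal kinematics plus the current channel/flow snapshot."""

    u: np.ndarray  # lateral displacement (ny, nz), cm; positive opens
    v: np.ndarray  # lateral velocity, cm/s
    time: float = 0.0
    channel: Optional[AirwayChannel] = None
    flow: Optional[FlowSolution] = None


@dataclass
class FSITrace:
    """Uniformly sampled waveforms plus per-step displacement snapshots."""

    times: np.ndarray
    Q: np.ndarray
    min_area: np.ndarray
    displacements: np.ndarray  # (n_steps, ny, nz)
    solid: SolidWallModel
    dt: float
    flow_mode: str
    n_sections: int


def _build_channel(solid: SolidWallModel, u: np.ndarray) -> AirwayChannel:
    g = solid.rest_half_gap() + u
    g = np.maximum(g, 0.5 * solid.contact_floor_gap)
    surf = MedialSurface(solid.y_grid, solid.z_grid, -g, g)
    return extrude_airway(surf, solid.geometry)


def _laplacian(u: np.ndarray) -> np.ndarray:
    """Sum of (neighbour - self) over the 4-neighbourhood (edge-aware)."""
    lap = np.zeros_like(u)
    lap[1:, :] += u[:-1, :] - u[1:, :]
    lap[:-1, :] += u[1:, :] - u[:-1, :]
    lap[:, 1:] += u[:, :-1] - u[:, 1:]
    lap[:, :-1] += u[:, 1:] - u[:, :-1]
    return lap


def step_solid(
    state: FSIState,
    pressures: np.ndarray,
    dt: float,
    solid: SolidWallModel,
) -> FSIState:
    """One symplectic-Euler step of the wall under nodal pressure loads.

    ``pressures`` is the gauge aerodynamic pressure at each node (ny, nz) in
    dyn/cm^2; a positive intraglottal pressure pushes the folds apart.
    After the update, displacements are clamped so the gap never penetrates
    the contact floor, and clamped nodes have their velocity zeroed.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt >= 0.1 * np.sqrt(solid.node_mass / solid.node_stiffness):
        raise ValueError("dt violates the stability bound 0.1*sqrt(m/k)")
    m = solid.node_mass
    force = (
        pressures * solid.patch_area
        - solid.node_stiffness * state.u
        - solid.node_damping * state.v
        + solid.coupling_stiffness * _laplacian(state.u)
    )
    v = state.v + dt * force / m
    u = state.u + dt * v
    # anterior/posterior anchoring
    u[:, 0] = 0.0
    u[:, -1] = 0.0
    v[:, 0] = 0.0
    v[:, -1] = 0.0
    # contact enforcement against the floor gap; nodes whose rest gap is
    # already below the floor (the tapered fold ends) are geometrically
    # closed and handled by the channel builder's gap floor instead
    rest = solid.rest_half_gap()
    u_min = 0.5 * solid.contact_floor_gap - rest
    clamped = (u < u_min) & (rest >= 0.5 * solid.contact_floor_gap)
    u = np.where(clamped, u_min, u)
    v = np.where(clamped, 0.0, v)
    if np.max(np.abs(u)) > 1.0:
        raise BlowUpError("nodal displacement exceeded 1 cm")
    return FSIState(u=u, v=v, time=state.time + dt)


def _node_pressures(
    solid: SolidWallModel, flow: FlowSolution, Y: np.ndarray
) -> np.ndarray:
    p_nodes = np.interp(solid.y_grid, Y, flow.pressures_P)
    return np.repeat(p_nodes[:, None], solid.nz, axis=1)


def mechanical_energy(state: FSIState, solid: SolidWallModel) -> float:
    """Kinetic + spring + coupling elastic energy of the wall, erg."""
    kin = 0.5 * solid.node_mass * np.sum(state.v**2)
    spr = 0.5 * solid.node_stiffness * np.sum(state.u**2)
    u = state.u
    cpl = 0.5 * solid.coupling_stiffness * (
        np.sum((u[1:, :] - u[:-1, :]) ** 2) + np.sum((u[:, 1:] - u[:, :-1]) ** 2)
    )
    return float(kin + spr + cpl)


def run_fsi(
    solid: SolidWallModel,
    fluid: FluidProperties,
    conditions: FlowConditions,
    flow_mode: str = "bernoulli",
    model: TrainedModel | None = None,
    duration: float = 0.1,
    dt: float = 1e-5,
    n_sections: int = 32,
) -> FSITrace:
    """Run the staggered FSI loop and record the full trace.

    ``flow_mode`` selects plain Bernoulli (``fr = 0``) or the
    learned-resistance model (``dnn_bernoulli``, requires ``model``).  A
    flow step whose self-consistent loop fails is carried with the previous
    resistance profile.
    """
    if flow_mode not in ("bernoulli", "dnn_bernoulli"):
        raise ValueError("flow_mode must be 'bernoulli' or 'dnn_bernoulli'")
    if flow_mode == "dnn_bernoulli" and model is None:
        raise ValueError("dnn_bernoulli mode requires a trained model")
    n_steps = int(round(duration / dt))
    state = FSIState(
        u=np.zeros((solid.ny, solid.nz)), v=np.zeros((solid.ny, solid.nz))
    )
    times = np.arange(n_steps) * dt
    Q = np.empty(n_steps)
    min_area = np.empty(n_steps)
    disp = np.empty((n_steps, solid.ny, solid.nz))
    prev_fr: np.ndarray | None = None
    for k in range(n_steps):
        channel = _build_channel(solid, state.u)
        dchan = discretize_channel(channel, n_sections)
        if flow_mode == "bernoulli":
            q = solve_flow_rate(dchan, np.zeros(dchan.n), fluid, conditions)
            sol = pressure_distribution(
                dchan, np.zeros(dchan.n), fluid, conditions, q
            )
        else:
            try:
                sol = solve_self_consistent(dchan, fluid, conditions, model)
                prev_fr = sol.fr
            except (ConvergenceError, NoRealSolutionError):
                fr = prev_fr if prev_fr is not None else np.zeros(dchan.n)
                if fr.size != dchan.n:
                    fr = np.zeros(dchan.n)
                q = solve_flow_rate(dchan, fr, fluid, conditions)
                sol = pressure_distribution(dchan, fr, fluid, conditions, q)
        Q[k] = sol.Q
        min_area[k] = float(dchan.A.min())
        disp[k] = state.u
        pressures = _node_pressures(solid, sol, dchan.Y)
        state = step_solid(state, pressures, dt, solid)
    return FSITrace(
        times=times,
        Q=Q,
        min_area=min_area,
        displacements=disp,
        solid=solid,
        dt=dt,
        flow_mode=flow_mode,
        n_sections=n_sections,
    )


def _cycle_peaks(trace: FSITrace, transient_fraction: float = 0.4) -> np.ndarray:
    start = int(transient_fraction * trace.Q.size)
    q = trace.Q[start:]
    span = float(q.max() - q.min())
    if span <= 1e-12 * max(abs(float(q.max())), 1.0):
        raise NoCycleError("flow-rate trace is flat; no oscillation cycle")
    peaks, _ = find_peaks(q, prominence=0.1 * span)
    if peaks.size < 2:
        raise NoCycleError("fewer than two flow-rate peaks after the transient")
    return peaks + start


def analyze_trace(trace: FSITrace) -> dict:
    """Peak flow, mean flow, fundamental frequency and cycle steadiness."""
    peaks = _cycle_peaks(trace)
    periods = np.diff(trace.times[peaks])
    amps = trace.Q[peaks]
    last = amps[-4:]
    steadiness = float((last.max() - last.min()) / max(last.mean(), 1e-12))
    i0 = peaks[0]
    q_late = trace.Q[i0:]
    swing = float(q_late.max() - q_late.min())
    return {
        "peak_Q": float(q_late.max()),
        "mean_Q": float(q_late.mean()),
        "f0_hz": float(1.0 / np.median(periods)),
        "n_cycles": int(peaks.size - 1),
        "amplitude_steadiness": steadiness,
        "relative_swing": swing / max(float(q_late.mean()), 1e-12),
        # sustained = steady cycle-to-cycle peak amplitude (within 5%) over
        # at least four cycles, with a swing guard that rejects the residual
        # numerical ripple of a decayed static equilibrium (a few % of mean)
        "sustained": bool(
            steadiness < 0.05 and peaks.size >= 4 and swing > 0.05 * q_late.mean()
        ),
    }


def extract_cycle_shapes(trace: FSITrace, n_samples: int = 92) -> list[AirwayChannel]:
    """Channels at ``n_samples`` uniform instants across the last full cycle.

    The cycle is bounded by the last two flow-rate peaks of the converged
    oscillation; the shapes feed the training-set builder exactly like the
    synthetic corpus.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    peaks = _cycle_peaks(trace)
    i1, i2 = peaks[-2], peaks[-1]
    if n_samples == 1:
        sample_idx = np.array([(i1 + i2) // 2])
    else:
        sample_idx = np.unique(
            np.round(np.linspace(i1, i2, n_samples, endpoint=False)).astype(int)
        )
    return [_build_channel(trace.solid, trace.displacements[k]) for k in sample_idx]
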