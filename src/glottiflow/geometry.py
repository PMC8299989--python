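"""Cross-section discretization and nondimensional feature extraction.

A channel is discretized into ``n + 1`` uniformly spaced planar cross
sections spanning the contraction entry through the glottal exit.  Each
section's open flow area and wetted perimeter are integrated from the gridded
gap field, supporting multi-channel configurations (partial vocal-fold
contact splitting the glottis into disjoint openings).  From the discretized
channel, eight dimensionless features per section are extracted: normalized
position, area and hydraulic diameter, upstream and downstream diameter
slopes, shape change rate, pressure-drop coefficient, and Reynolds number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .shapes import AirwayChannel

__all__ = [
    "CrossSection",
    "DiscretizedChannel",
    "FluidProperties",
    "FlowConditions",
    "FEATURE_COLUMNS",
    "DegenerateChannelError",
    "InfiniteFeatureError",
    "discretize_channel",
    "compute_feature_matrix",
    "section_table_csv",
]

#: fixed feature column order (matches the training-matrix layout)
FEATURE_COLUMNS = (
    "Y_star",
    "A_star",
    "D_star",
    "alpha_plus",
    "alpha_minus",
    "dS_star",
    "dP_star",
    "Re",
)


class DegenerateChannelError(ValueError):
    """Raised when the channel is fully closed at every station."""


class InfiniteFeatureError(ValueError):
    """Raised when a feature (pressure-drop coefficient) is requested at Q=0."""


@dataclass(frozen=True)
class FluidProperties:
    """Air properties in CGS units."""

    density_rho: float = 1.145e-3  # g/cm^3
    kinematic_viscosity_nu: float = 1.655e-1  # cm^2/s

    def __post_init__(self) -> None:
        if self.density_rho <= 0 or self.kinematic_viscosity_nu <= 0:
            raise ValueError("fluid properties must be positive")


@dataclass(frozen=True)
class FlowConditions:
    """Prescribed boundary pressures in dyn/cm^2 (1 kPa = 1e4 dyn/cm^2)."""

    inlet_pressure_Ps: float = 1.0e4
    outlet_pressure_Pc: float = 0.0

    def __post_init__(self) -> None:
        if self.inlet_pressure_Ps <= self.outlet_pressure_Pc:
            raise ValueError("require Ps > Pc")

    @property
    def delta_P(self) -> float:
        return self.inlet_pressure_Ps - self.outlet_pressure_Pc


@dataclass(frozen=True)
class CrossSection:
    index_i: int
    position_Y: float
    area_A: float
    wetted_perimeter_Pe: float
    hydraulic_diameter_D: float
    spacing_L: float


@dataclass
class DiscretizedChannel:
    """``n + 1`` uniform cross sections from contraction entry to glottal exit.

    Attributes
    ----------
    Y, A, Pe, D : ndarray, shape (n + 1,)
        Station positions, open areas, wetted perimeters and hydraulic
        diameters (``D = 4 A / Pe``).
    spacing : float
        Uniform station spacing ``L_i``.
    inlet_area_As, exit_area_An, expansion_area_Ac : float
        Contraction-entry area, glottal-exit area and expansion(-outlet)
        area used by the pressure-recovery term.
    """

    Y: np.ndarray
    A: np.ndarray
    Pe: np.ndarray
    D: np.ndarray
    spacing: float
    inlet_area_As: float
    exit_area_An: float
    expansion_area_Ac: float
    area_floor: float = 1e-4

    @property
    def n(self) -> int:
        return self.Y.size - 1

    @property
    def reference_Y0(self) -> float:
        return float(self.Y[0])

    @property
    def reference_A0(self) -> float:
        return float(self.A[0])

    @property
    def reference_D0(self) -> float:
        return float(self.D[0])

    @property
    def reference_L0(self) -> float:
        return self.spacing

    @property
    def sections(self) -> list[CrossSection]:
        return [
            CrossSection(i, float(self.Y[i]), float(self.A[i]), float(self.Pe[i]),
                         float(self.D[i]), self.spacing)
            for i in range(self.Y.size)
        ]


def _section_area_perimeter(
    width: np.ndarray, z: np.ndarray, area_floor: float
) -> tuple[float, float]:
    """Open area and wetted perimeter of one section from gap-width samples.

    The section is the planar region between the two walls ``x = +-g(z)``
    (``width = 2 g``).  Disjoint open intervals (multi-channel sections) each
    contribute two wall curves plus the vertical closures at abrupt interval
    ends; a closed section falls back to a square slit of ``area_floor``.
    """
    open_mask = width > 0.0
    if not open_mask.any():
        s = np.sqrt(area_floor)
        return area_floor, 4.0 * s
    area = 0.0
    perim = 0.0
    # maximal runs of consecutive open samples
    idx = np.flatnonzero(np.diff(np.concatenate(([0], open_mask.view(np.int8), [0]))))
    half = 0.5 * width
    for a, b in zip(idx[::2], idx[1::2]):  # run = samples [a, b)
        if b - a == 1:
            dz = z[1] - z[0]
            area += width[a] * dz
            perim += 2.0 * dz + 2.0 * width[a]
            continue
        zs, ws, hs = z[a:b], width[a:b], half[a:b]
        area += float(np.trapezoid(ws, zs))
        wall = np.sum(np.sqrt(np.diff(zs) ** 2 + np.diff(hs) ** 2))
        perim += 2.0 * float(wall) + float(ws[0] + ws[-1])
    area = max(area, area_floor)
    return area, perim


def discretize_channel(
    channel: AirwayChannel, n_sections: int = 128, area_floor: float = 1e-4
) -> DiscretizedChannel:
    """Resample the channel onto ``n_sections + 1`` uniform cross sections.

    Stations span the contraction entry through the glottal exit (at the
    default geometry: 129 stations at 0.012 cm spacing).  Areas are clamped
    at ``area_floor`` so that closed/contact stations stay usable by the
    flow solver.
    """
    if n_sections < 2:
        raise ValueError("n_sections must be >= 2")
    glottis = channel.glottis_mask()
    y_start = float(channel.y_stations[0])
    y_end = float(channel.y_stations[glottis][-1]) if glottis.any() else float(
        channel.y_stations[-1]
    )
    Y = np.linspace(y_start, y_end, n_sections + 1)
    z = channel.z_grid
    # per-z-column linear interpolation of the half-gap onto the stations
    gap = np.empty((Y.size, z.size))
    for j in range(z.size):
        gap[:, j] = np.interp(Y, channel.y_stations, channel.gap_field[:, j])
    width = np.maximum(2.0 * gap, 0.0)

    A = np.empty(Y.size)
    Pe = np.empty(Y.size)
    open_mask = width > 0.0
    fully_open = open_mask.all(axis=1)
    if fully_open.any():
        # vectorized single-run path (no contact anywhere on the station)
        w = width[fully_open]
        dz = np.diff(z)
        A[fully_open] = np.maximum(
            np.sum(0.5 * (w[:, 1:] + w[:, :-1]) * dz, axis=1), area_floor
        )
        dg = 0.5 * np.diff(w, axis=1)
        walls = 2.0 * np.sum(np.sqrt(dz**2 + dg**2), axis=1)
        Pe[fully_open] = walls + w[:, 0] + w[:, -1]
    n_closed = 0
    for k in np.flatnonzero(~fully_open):
        A[k], Pe[k] = _section_area_perimeter(width[k], z, area_floor)
        if not open_mask[k].any():
            n_closed += 1
    if n_closed == Y.size:
        raise DegenerateChannelError("channel fully closed at every station")
    D = 4.0 * A / Pe

    # expansion-outlet area for the pressure-recovery term
    expansion = channel.part_labels == "expansion"
    if expansion.any():
        w_out = np.maximum(2.0 * channel.gap_field[expansion][-1], 0.0)
        Ac, _ = _section_area_perimeter(w_out, z, area_floor)
    else:
        Ac = float(A[-1])

    return DiscretizedChannel(
        Y=Y,
        A=A,
        Pe=Pe,
        D=D,
        spacing=float(Y[1] - Y[0]),
        inlet_area_As=float(A[0]),
        exit_area_An=float(A[-1]),
        expansion_area_Ac=Ac,
        area_floor=area_floor,
    )


def _feature_array(
    channel: DiscretizedChannel,
    fluid: FluidProperties,
    conditions: FlowConditions,
    Q: float,
) -> np.ndarray:
    """Feature matrix as a plain (n, 8) array; see compute_feature_matrix."""
    if Q < 0:
        raise ValueError("Q must be >= 0")
    if Q == 0.0:
        raise InfiniteFeatureError(
            "pressure-drop coefficient is infinite at Q = 0; "
            "use the self-consistent solver"
        )
    Y, A, D = channel.Y, channel.A, channel.D
    n = channel.n
    L = channel.spacing
    rho, nu = fluid.density_rho, fluid.kinematic_viscosity_nu

    sl = slice(0, n)  # feature rows: sections 0 .. n-1
    Y_star = (Y[sl] - Y[0]) / (Y[n - 1] - Y[0])
    A_star = A[sl] / A[0]
    D_star = D[sl] / D[0]

    dD = np.diff(D)  # dD[i] = D_{i+1} - D_i
    alpha_plus = np.empty(n)
    alpha_plus[1:] = dD[: n - 1] / L
    alpha_plus[0] = alpha_plus[1]  # one-sided copy at the inlet
    alpha_minus = dD[:n] / L

    dS_star = np.empty(n)
    dS_star[1:] = L * np.diff(A)[: n - 1] / (L * A[0])
    dS_star[0] = 0.0

    dP_star = conditions.delta_P / (0.5 * rho * (Q / A[sl]) ** 2)
    Re = Q * D[sl] / (A[sl] * nu)
    return np.column_stack(
        [Y_star, A_star, D_star, alpha_plus, alpha_minus, dS_star, dP_star, Re]
    )


def compute_feature_matrix(
    channel: DiscretizedChannel,
    fluid: FluidProperties,
    conditions: FlowConditions,
    Q: float,
) -> pd.DataFrame:
    """Eight dimensionless features per section (rows: sections 0 .. n-1).

    Columns in fixed order: normalized position ``Y* = (Y_i - Y_0) /
    (Y_{n-1} - Y_0)``, normalized area ``A* = A_i / A_0`` and hydraulic
    diameter ``D* = D_i / D_0``, upstream slope ``alpha+ = (D_i - D_{i-1}) /
    L_i``, downstream slope ``alpha- = (D_{i+1} - D_i) / L_{i+1}``, shape
    change rate ``dS* = L_0 (A_i - A_{i-1}) / (L_i A_0)``, pressure-drop
    coefficient ``dP* = (Ps - Pc) / (rho/2 (Q/A_i)^2)`` and Reynolds number
    ``Re = Q D_i / (A_i nu)``.  The inlet row uses one-sided differences
    (``alpha+`` copied from the adjacent section, ``dS*`` set to 0).
    """
    X = _feature_array(channel, fluid, conditions, Q)
    return pd.DataFrame(X, columns=list(FEATURE_COLUMNS))


def section_table_csv(channel: DiscretizedChannel, path) -> None:
    """Write the raw section table (position, area, perimeter, diameter)."""
    pd.DataFrame(
        {
            "y_cm": channel.Y,
            "area_cm2": channel.A,
            "perimeter_cm": channel.Pe,
            "diameter_cm": channel.D,
        }
    ).to_csv(path, index=False)
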