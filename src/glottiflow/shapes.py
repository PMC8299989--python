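"""Kinematic synthesis of glottal channel geometries.

The glottal airway is modelled as a half-gap field ``g(y, z)`` between two
mirror-symmetric vocal-fold medial surfaces.  ``y`` is the inferior-superior
(airflow) direction with ``y = 0`` at the glottal entry, ``z`` is the
anterior-posterior direction along the fold length, and ``x`` is lateral with
the midplane at ``x = 0``.  All lengths are in cm (CGS units throughout the
package).

A shape is built in three stages:

1. a *prephonatory* medial surface: a linear inferior-superior half-gap
   profile (convergent when the inferior gap exceeds the superior one) with a
   cosine taper to closure at the anterior and posterior ends;
2. superposition of surface-wave vibration modes ``(m, n)`` — ``m``
   half-wavelengths along the fold length, ``n`` along the flow direction —
   applied antisymmetrically to the left and right surfaces;
3. contact resolution (interpenetrating surfaces collapse to their mean) and
   extrusion of the subglottal contraction and supraglottal expansion parts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PrephonatoryParams",
    "VibrationMode",
    "ShapeSpec",
    "MedialSurface",
    "AirwayChannel",
    "build_prephonatory",
    "modal_displacement",
    "superimpose",
    "resolve_contact",
    "extrude_airway",
    "build_channel",
    "enumerate_shape_set",
    "default_shape_set",
    "channel_to_gap_csv",
    "channel_to_mesh",
]

#: fraction of the fold length over which the half-gap tapers to closure at
#: each anterior/posterior end
TAPER_FRACTION = 0.05


class InvalidParameterError(ValueError):
    """Raised for non-physical shape parameters."""


@dataclass(frozen=True)
class PrephonatoryParams:
    """Prephonatory (at-rest) geometry of the glottal channel.

    Parameters
    ----------
    fold_length_L : float
        Anterior-posterior vocal-fold length, cm.
    medial_thickness_T : float
        Inferior-superior thickness of the medial surface (glottal channel
        length along the flow), cm.
    half_gap_inferior, half_gap_superior : float
        Half-gap at the glottal entry (y=0) and exit (y=T), cm.  Convergent
        when inferior > superior, divergent otherwise.
    initial_half_gap_dx : float
        Uniform lateral offset between each surface and the midplane, cm.
    contraction_length_Lc, expansion_length_Le : float
        Streamwise lengths of the subglottal contraction and supraglottal
        expansion parts, cm.
    contraction_inlet_halfwidth, expansion_outlet_halfwidth : float
        Lateral half-width of the channel at the contraction inlet and the
        expansion outlet, cm.
    mesh_resolution : float
        Uniform surface grid spacing, cm.
    """

    fold_length_L: float = 1.5
    medial_thickness_T: float = 0.3
    half_gap_inferior: float = 0.05
    half_gap_superior: float = 0.05
    initial_half_gap_dx: float = 0.0
    contraction_length_Lc: float = 1.236
    expansion_length_Le: float = 0.5
    contraction_inlet_halfwidth: float = 0.6
    expansion_outlet_halfwidth: float = 0.6
    mesh_resolution: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "fold_length_L",
            "medial_thickness_T",
            "mesh_resolution",
            "contraction_inlet_halfwidth",
            "expansion_outlet_halfwidth",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in (
            "half_gap_inferior",
            "half_gap_superior",
            "initial_half_gap_dx",
            "contraction_length_Lc",
            "expansion_length_Le",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.mesh_resolution > self.medial_thickness_T / 10 + 1e-12:
            raise InvalidParameterError(
                "mesh_resolution must not exceed medial_thickness_T / 10"
            )


@dataclass(frozen=True)
class VibrationMode:
    """Surface-wave vibration mode of the medial surface.

    ``m`` counts half-wavelengths along the fold length (anterior-posterior),
    ``n`` along the flow direction (inferior-superior).  ``(1, 0)`` is the
    in-phase lateral mode; ``(1, 1)`` produces the alternating
    convergent-divergent glottis of the mucosal wave.
    """

    m: int = 1
    n: int = 0
    amplitude: float = 0.05
    phase_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 0:
            raise InvalidParameterError("require m >= 1 and n >= 0")
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be >= 0")


@dataclass(frozen=True)
class ShapeSpec:
    """A prephonatory geometry plus vibration modes at one cycle phase."""

    prephonatory: PrephonatoryParams
    modes: tuple[VibrationMode, ...] = ()
    phase: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modes", tuple(self.modes))


@dataclass
class MedialSurface:
    """Left/right medial-surface lateral coordinates on a uniform (y, z) grid."""

    y_grid: np.ndarray
    z_grid: np.ndarray
    x_left: np.ndarray
    x_right: np.ndarray

    @property
    def half_gap(self) -> np.ndarray:
        return 0.5 * (self.x_right - self.x_left)


@dataclass
class AirwayChannel:
    """The full contraction + glottis + expansion channel as a half-gap field.

    ``gap_field[k, j]`` is the half-gap at station ``y_stations[k]`` and
    anterior-posterior position ``z_grid[j]``; the channel is mirror-symmetric
    about the midplane so the local full gap width is twice this value.
    """

    y_stations: np.ndarray
    z_grid: np.ndarray
    gap_field: np.ndarray
    part_labels: np.ndarray  # "contraction" | "glottis" | "expansion"

    def glottis_mask(self) -> np.ndarray:
        return self.part_labels == "glottis"


def _taper(z: np.ndarray, L: float) -> np.ndarray:
    """Cosine taper to closure within TAPER_FRACTION*L of each end of [0, L]."""
    w = TAPER_FRACTION * L
    z = np.asarray(z, dtype=float)
    t = np.ones_like(z)
    lo = z < w
    hi = z > L - w
    t[lo] = 0.5 * (1.0 - np.cos(np.pi * z[lo] / w))
    t[hi] = 0.5 * (1.0 - np.cos(np.pi * (L - z[hi]) / w))
    return t


def _grid(length: float, resolution: float) -> np.ndarray:
    n = max(int(round(length / resolution)), 1)
    return np.linspace(0.0, length, n + 1)


def build_prephonatory(params: PrephonatoryParams) -> MedialSurface:
    """Construct the prephonatory medial surface.

    The half-gap varies linearly from ``half_gap_inferior`` at the glottal
    entry to ``half_gap_superior`` at the exit, uniformly along the fold
    except for the cosine taper to closure at the anterior/posterior ends.
    """
    L, T = params.fold_length_L, params.medial_thickness_T
    y = _grid(T, params.mesh_resolution)
    z = _grid(L, params.mesh_resolution)
    h = params.half_gap_inferior + (
        params.half_gap_superior - params.half_gap_inferior
    ) * (y / T)
    g0 = _taper(z, L)[None, :] * (h[:, None] + params.initial_half_gap_dx)
    return MedialSurface(y_grid=y, z_grid=z, x_left=-g0, x_right=g0.copy())


def modal_displacement(
    mode: VibrationMode,
    y: float | np.ndarray,
    z: float | np.ndarray,
    phase: float,
    *,
    L: float,
    T: float,
) -> float | np.ndarray:
    """Lateral modal displacement at (y, z) for a given cycle phase.

    Returns ``amplitude * sin(m*pi*z/L) * cos(n*pi*y/T - phase -
    phase_offset)``; the sine factor anchors the displacement at the anterior
    and posterior ends of the fold.
    """
    return (
        mode.amplitude
        * np.sin(mode.m * np.pi * np.asarray(z) / L)
        * np.cos(mode.n * np.pi * np.asarray(y) / T - phase - mode.phase_offset)
    )


def superimpose(spec: ShapeSpec) -> MedialSurface:
    """Superimpose modal displacements on the prephonatory surface.

    The total half-gap is the prephonatory half-gap plus the sum of modal
    displacements, applied antisymmetrically: the right surface moves by
    ``+xi``, the left by ``-xi``.  The result may interpenetrate
    (``x_left > x_right``) during the closed phase; see
    :func:`resolve_contact`.
    """
    p = spec.prephonatory
    surf = build_prephonatory(p)
    yy, zz = np.meshgrid(surf.y_grid, surf.z_grid, indexing="ij")
    xi = np.zeros_like(yy)
    for mode in spec.modes:
        xi = xi + modal_displacement(
            mode, yy, zz, spec.phase, L=p.fold_length_L, T=p.medial_thickness_T
        )
    surf.x_right = surf.x_right + xi
    surf.x_left = surf.x_left - xi
    return surf


def resolve_contact(surface: MedialSurface) -> MedialSurface:
    """Collapse interpenetrating surface points to their arithmetic mean.

    Wherever ``x_left > x_right`` both coordinates are replaced by their
    mean, modelling vocal-fold contact; elsewhere the surface is unchanged.
    Afterwards ``x_right - x_left >= 0`` everywhere.
    """
    mask = surface.x_left > surface.x_right
    mean = 0.5 * (surface.x_left + surface.x_right)
    x_left = np.where(mask, mean, surface.x_left)
    x_right = np.where(mask, mean, surface.x_right)
    return MedialSurface(surface.y_grid, surface.z_grid, x_left, x_right)


def extrude_airway(surface: MedialSurface, params: PrephonatoryParams) -> AirwayChannel:
    """Extrude contraction and expansion parts from a contact-resolved surface.

    The contraction half-gap interpolates linearly (per anterior-posterior
    position) from the inlet half-width to the surface's inferior gap; the
    expansion interpolates from the superior gap to the outlet half-width.
    """
    dy = params.mesh_resolution
    g_glottis = surface.half_gap
    z = surface.z_grid
    y_parts: list[np.ndarray] = []
    g_parts: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    Lc = params.contraction_length_Lc
    if Lc > 0:
        nc = max(int(round(Lc / dy)), 1)
        yc = np.linspace(-Lc, 0.0, nc + 1)[:-1]  # glottal entry kept once
        frac = (yc + Lc) / Lc
        gc = (1.0 - frac)[:, None] * params.contraction_inlet_halfwidth + frac[
            :, None
        ] * g_glottis[0][None, :]
        y_parts.append(yc)
        g_parts.append(gc)
        labels.append(np.full(yc.size, "contraction"))

    y_parts.append(surface.y_grid)
    g_parts.append(g_glottis)
    labels.append(np.full(surface.y_grid.size, "glottis"))

    Le = params.expansion_length_Le
    if Le > 0:
        ne = max(int(round(Le / dy)), 1)
        T = surface.y_grid[-1]
        ye = np.linspace(T, T + Le, ne + 1)[1:]
        frac = (ye - T) / Le
        ge = (1.0 - frac)[:, None] * g_glottis[-1][None, :] + frac[
            :, None
        ] * params.expansion_outlet_halfwidth
        y_parts.append(ye)
        g_parts.append(ge)
        labels.append(np.full(ye.size, "expansion"))

    return AirwayChannel(
        y_stations=np.concatenate(y_parts),
        z_grid=z,
        gap_field=np.vstack(g_parts),
        part_labels=np.concatenate(labels),
    )


def build_channel(spec: ShapeSpec) -> AirwayChannel:
    """Full pipeline: superimpose, resolve contact, extrude."""
    return extrude_airway(resolve_contact(superimpose(spec)), spec.prephonatory)


def enumerate_shape_set(
    prephonatory_list: Sequence[PrephonatoryParams],
    mode_list: Sequence[VibrationMode | Sequence[VibrationMode]],
    n_phases: int,
) -> list[AirwayChannel]:
    """Cartesian product of prephonatory shapes, modes and cycle phases.

    Phases are uniformly spaced over the half-open interval ``[0, 2*pi)``;
    the channel count is ``len(prephonatory_list) * len(mode_list) *
    n_phases``.
    """
    if not prephonatory_list or not mode_list:
        raise InvalidParameterError("prephonatory_list and mode_list must be non-empty")
    if n_phases < 1:
        raise InvalidParameterError("n_phases must be >= 1")
    phases = np.linspace(0.0, 2.0 * np.pi, n_phases, endpoint=False)
    channels = []
    for pre, mode, phase in itertools.product(prephonatory_list, mode_list, phases):
        modes = (mode,) if isinstance(mode, VibrationMode) else tuple(mode)
        channels.append(build_channel(ShapeSpec(pre, modes, float(phase))))
    return channels


def default_shape_set(
    n_phases: int = 16, mesh_resolution: float = 0.01
) -> list[AirwayChannel]:
    """The default 64-shape training corpus.

    Two prephonatory geometries (convergent and divergent), the two dominant
    vibration modes (1, 0) and (1, 1), and ``n_phases`` phases over one cycle.
    """
    convergent = PrephonatoryParams(
        half_gap_inferior=0.1,
        half_gap_superior=0.02,
        mesh_resolution=mesh_resolution,
    )
    divergent = replace(
        convergent, half_gap_inferior=0.02, half_gap_superior=0.1
    )
    modes = [VibrationMode(1, 0, 0.05), VibrationMode(1, 1, 0.02)]
    return enumerate_shape_set([convergent, divergent], modes, n_phases)


def channel_to_gap_csv(channel: AirwayChannel, path) -> None:
    """Write the per-station full gap width (2x half-gap) as a long-form CSV."""
    import pandas as pd

    yy, zz = np.meshgrid(channel.y_stations, channel.z_grid, indexing="ij")
    pd.DataFrame(
        {
            "y_cm": yy.ravel(),
            "z_cm": zz.ravel(),
            "gap_cm": 2.0 * channel.gap_field.ravel(),
        }
    ).to_csv(path, index=False)


def _surface_mesh(channel: AirwayChannel):
    """Triangulate the two channel walls; returns (vertices, faces)."""
    y, z, g = channel.y_stations, channel.z_grid, channel.gap_field
    ny, nz = g.shape
    verts = []
    for sign in (+1.0, -1.0):
        yy, zz = np.meshgrid(y, z, indexing="ij")
        verts.append(np.column_stack([(sign * g).ravel(), yy.ravel(), zz.ravel()]))
    vertices = np.vstack(verts)
    faces = []
    for side in range(2):
        off = side * ny * nz
        for i in range(ny - 1):
            for j in range(nz - 1):
                a = off + i * nz + j
                b, c, d = a + 1, a + nz, a + nz + 1
                faces.extend([[a, b, d], [a, d, c]])
    return vertices, np.asarray(faces)


def channel_to_mesh(channel: AirwayChannel, path) -> None:
    """Export the channel walls as STL (via trimesh) or legacy-ASCII VTK."""
    path = str(path)
    vertices, faces = _surface_mesh(channel)
    if path.endswith(".stl"):
        import trimesh

        trimesh.Trimesh(vertices=vertices, faces=faces, process=False).export(path)
    elif path.endswith(".vtk"):
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nglottal channel walls\n")
            fh.write("ASCII\nDATASET POLYDATA\n")
            fh.write(f"POINTS {len(vertices)} float\n")
            for v in vertices:
                fh.write(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
            fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    else:
        raise ValueError("unsupported mesh format: use .stl or .vtk")
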