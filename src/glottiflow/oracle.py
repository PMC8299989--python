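"""Ground-truth section data for resistance-target computation.

Training targets for the resistance regressor are obtained by inverting the
per-segment pressure balance on *reference* section data: a table of
per-section mean pressures plus a scalar flow rate.  Two sources are
supported:

- externally computed tables (e.g. section-averaged Navier-Stokes output)
  loaded from a small CSV dialect, and
- a built-in deterministic quasi-1D viscous surrogate: laminar (Darcy)
  friction per segment plus a separation penalty on downstream divergence,

  ``fr_i = 64 L_i / (D_i Re_i) + k_sep * max(0, alpha-_i * D_i / L_i)^2``.

The surrogate is solved self-consistently (the laminar term depends on the
flow rate through ``Re``) by a bracketed scalar root-find, and the resulting
pressures/flow rate are emitted in exactly the same table form as external
data, so every downstream stage is source-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import (
    FEATURE_COLUMNS,
    DegenerateChannelError,
    DiscretizedChannel,
    FluidProperties,
    FlowConditions,
    _feature_array,
    discretize_channel,
)
from .flow import (
    ResistanceProfile,
    compute_target_fr,
    pressure_distribution,
    solve_flow_rate,
)
from .shapes import AirwayChannel

__all__ = [
    "SectionGroundTruth",
    "NSTableFormatError",
    "load_ns_table",
    "write_ns_table",
    "synthetic_fr",
    "make_ground_truth",
    "build_training_set",
    "TRAINING_COLUMNS",
]

TRAINING_COLUMNS = tuple(FEATURE_COLUMNS) + ("fr_target", "shape_id", "section_index")

#: default weight of the separation-loss term of the surrogate
K_SEP_DEFAULT = 0.5


class NSTableFormatError(ValueError):
    """Malformed ground-truth table file."""


@dataclass
class SectionGroundTruth:
    """Per-section reference data from which resistance targets are computed."""

    positions: np.ndarray
    areas: np.ndarray
    mean_pressures: np.ndarray
    Q_ref: float
    provenance: str = "synthetic_oracle"

    def __post_init__(self) -> None:
        if not (
            self.positions.size == self.areas.size == self.mean_pressures.size
        ):
            raise ValueError("ground-truth arrays must have equal length")
        if self.Q_ref <= 0:
            raise ValueError("Q_ref must be > 0")


_NS_COLUMNS = ["y_cm", "area_cm2", "mean_pressure_dyncm2"]


def load_ns_table(path) -> SectionGroundTruth:
    """Load a reference section table.

    Dialect: a metadata line ``# Q_cm3s=<value>``, then a CSV header
    ``y_cm,area_cm2,mean_pressure_dyncm2`` and one row per section with
    strictly increasing ``y_cm``.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].lstrip("# ").startswith("Q_cm3s="):
        raise NSTableFormatError(f"{path}:1: missing 'Q_cm3s=<value>' metadata line")
    try:
        Q = float(lines[0].lstrip("# ").split("=", 1)[1])
    except ValueError as exc:
        raise NSTableFormatError(f"{path}:1: unparseable flow rate") from exc
    if len(lines) < 2 or [c.strip() for c in lines[1].split(",")] != _NS_COLUMNS:
        raise NSTableFormatError(
            f"{path}:2: expected header '{','.join(_NS_COLUMNS)}'"
        )
    rows = []
    for k, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise NSTableFormatError(f"{path}:{k}: expected 3 columns")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise NSTableFormatError(f"{path}:{k}: non-numeric value") from exc
    data = np.asarray(rows)
    if data.shape[0] < 2:
        raise NSTableFormatError(f"{path}: need at least 2 section rows")
    y = data[:, 0]
    if np.any(np.diff(y) <= 0):
        k = int(np.flatnonzero(np.diff(y) <= 0)[0]) + 4
        raise NSTableFormatError(f"{path}:{k}: y_cm must be strictly increasing")
    return SectionGroundTruth(
        positions=y,
        areas=data[:, 1],
        mean_pressures=data[:, 2],
        Q_ref=Q,
        provenance="ns_file",
    )


def write_ns_table(gt: SectionGroundTruth, path) -> None:
    """Write a ground-truth table in the dialect read by :func:`load_ns_table`."""
    with open(path, "w") as fh:
        fh.write(f"# Q_cm3s={float(gt.Q_ref)!r}\n")
        fh.write(",".join(_NS_COLUMNS) + "\n")
        for y, a, p in zip(gt.positions, gt.areas, gt.mean_pressures):
            fh.write(f"{float(y)!r},{float(a)!r},{float(p)!r}\n")


def synthetic_fr(
    channel: DiscretizedChannel,
    fluid: FluidProperties,
    Q: float,
    k_sep: float = K_SEP_DEFAULT,
) -> ResistanceProfile:
    """Deterministic surrogate resistance law evaluated per segment.

    Laminar Darcy friction ``64 L / (D Re)`` plus a separation penalty that
    activates only where the channel diverges downstream (``alpha- > 0``).
    Segment ``i`` (sections ``i-1 -> i``) is evaluated on its *upstream*
    section ``i-1``, whose downstream slope ``alpha-_{i-1} = (D_i -
    D_{i-1}) / L`` is the segment's own divergence; this makes the surrogate
    resistance an exact function of that section's extracted features.
    """
    if Q <= 0:
        raise ValueError("Q must be > 0")
    A, D = channel.A, channel.D
    L = channel.spacing
    nu = fluid.kinematic_viscosity_nu
    Du, Au = D[:-1], A[:-1]  # upstream section i-1 for segment i = 1..n
    Re = Q * Du / (Au * nu)
    alpha_minus = np.diff(D) / L  # (D_i - D_{i-1}) / L at section i-1
    fr = 64.0 * L / (Du * Re) + k_sep * np.maximum(0.0, alpha_minus * Du / L) ** 2
    return ResistanceProfile(fr)


def make_ground_truth(
    channel: DiscretizedChannel,
    fluid: FluidProperties,
    conditions: FlowConditions,
    k_sep: float = K_SEP_DEFAULT,
) -> SectionGroundTruth:
    """Solve the surrogate flow self-consistently and emit a reference table.

    Finds the flow rate at which the closed-form Bernoulli flow rate with
    ``fr = synthetic_fr(Q)`` equals ``Q`` (bracketed scalar root-find; the
    residual is monotone because added resistance only reduces the flow),
    then emits the corresponding per-section pressures.
    """
    Q_bern = solve_flow_rate(channel, np.zeros(channel.n), fluid, conditions)
    target = 2.0 * conditions.delta_P / fluid.density_rho

    def residual(Q: float) -> float:
        fr = synthetic_fr(channel, fluid, Q, k_sep=k_sep)
        from .flow import _denominator

        return Q * Q * _denominator(channel, fr.fr) - target

    lo, hi = 1e-3, Q_bern * (1.0 + 1e-9)
    if residual(lo) > 0 or residual(hi) < 0:
        raise DegenerateChannelError("no bracket for the surrogate flow rate")
    Q = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    fr = synthetic_fr(channel, fluid, Q, k_sep=k_sep)
    sol = pressure_distribution(channel, fr, fluid, conditions, Q)
    return SectionGroundTruth(
        positions=channel.Y.copy(),
        areas=channel.A.copy(),
        mean_pressures=sol.pressures_P,
        Q_ref=float(Q),
        provenance="synthetic_oracle",
    )


def targets_from_ground_truth(
    gt: SectionGroundTruth, fluid: FluidProperties
) -> ResistanceProfile:
    """Resistance targets from a reference table (Bernoulli-balance inverse)."""
    return compute_target_fr(gt.areas, gt.mean_pressures, gt.Q_ref, fluid)


def build_training_set(
    channels: Sequence[AirwayChannel | DiscretizedChannel],
    fluid: FluidProperties,
    conditions: FlowConditions,
    n_sections: int = 128,
    k_sep: float = K_SEP_DEFAULT,
) -> pd.DataFrame:
    """Assemble (features, target) records for every segment of every shape.

    For each shape: surrogate ground truth at the reference flow rate,
    targets by the Bernoulli-balance inverse, features at the reference flow
    rate.  Record ``i`` pairs the feature row of section ``i`` (the upstream
    section of segment ``i + 1``) with target ``fr_{i+1}``, giving exactly
    ``n`` records per shape.
    """
    if len(channels) == 0:
        raise ValueError("need at least one channel")
    frames = []
    for shape_id, ch in enumerate(channels):
        dchan = (
            ch
            if isinstance(ch, DiscretizedChannel)
            else discretize_channel(ch, n_sections)
        )
        gt = make_ground_truth(dchan, fluid, conditions, k_sep=k_sep)
        fr = targets_from_ground_truth(gt, fluid)
        X = _feature_array(dchan, fluid, conditions, gt.Q_ref)
        df = pd.DataFrame(X, columns=list(FEATURE_COLUMNS))
        df["fr_target"] = fr.fr
        df["shape_id"] = shape_id
        df["section_index"] = np.arange(dchan.n)
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)
    if not np.all(np.isfinite(records[list(FEATURE_COLUMNS) + ["fr_target"]].to_numpy())):
        raise ValueError("training records contain non-finite values")
    return records
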