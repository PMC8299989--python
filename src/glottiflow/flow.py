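"""Modified Bernoulli flow solver with per-segment viscous resistance.

The quasi-steady pressure balance from the contraction entry (prescribed
subglottal pressure ``Ps``, area ``As``) through ``n`` glottal segments to
the expansion (supraglottal pressure ``Pc``, area ``Ac``) is::

    Ps + rho/2 (Q/As)^2 = Pn + rho/2 (Q/An)^2 + rho/2 Q^2 sum_i fr_i / A_i^2

with sudden-expansion pressure recovery ``Pn - Pc = -rho/2 (Q/An)^2 *
2 (An/Ac) (1 - An/Ac)``.  Each dimensionless coefficient ``fr_i`` carries the
viscous loss of segment ``i`` (spanning sections ``i-1 -> i`` and normalized
by the downstream area ``A_i``); negative values represent pressure recovery
beyond the inviscid prediction.  Solving for ``Q`` gives the closed form::

    Q = sqrt( 2 (Ps - Pc) / rho /
              [ -1/As^2 + (1 - 2 (An/Ac)(1 - An/Ac))/An^2 + sum fr_i/A_i^2 ] )

The same algebra inverted section-by-section recovers ``fr`` from any
reference (e.g. Navier-Stokes) per-section mean pressures and flow rate —
this is how training targets are produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .geometry import (
    DiscretizedChannel,
    FluidProperties,
    FlowConditions,
    _feature_array,
)

if TYPE_CHECKING:  # pragma: no cover
    from .dnn import TrainedModel

__all__ = [
    "ResistanceProfile",
    "FlowSolution",
    "ErrorReport",
    "NoRealSolutionError",
    "ConvergenceError",
    "solve_flow_rate",
    "pressure_distribution",
    "compute_target_fr",
    "solve_self_consistent",
    "relative_errors",
    "summarize_errors",
]


class NoRealSolutionError(ValueError):
    """The flow-rate expression has a non-positive denominator."""


class ConvergenceError(RuntimeError):
    """The self-consistent resistance/flow iteration failed to converge."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class ResistanceProfile:
    """Per-segment dimensionless loss coefficients ``fr_1 .. fr_n``."""

    fr: np.ndarray

    def __post_init__(self) -> None:
        self.fr = np.asarray(self.fr, dtype=float)
        if not np.all(np.isfinite(self.fr)):
            raise ValueError("resistance coefficients must be finite")

    def __len__(self) -> int:
        return self.fr.size


def _as_fr(fr) -> np.ndarray:
    if isinstance(fr, ResistanceProfile):
        return fr.fr
    return np.asarray(fr, dtype=float)


@dataclass
class FlowSolution:
    """Flow rate, per-section pressures and the recovered outlet pressure."""

    Q: float
    pressures_P: np.ndarray
    recovered_Pc: float
    fr: np.ndarray | None = None
    iterations: int = 0


@dataclass
class ErrorReport:
    """Percent relative errors of flow rate and pressure distribution."""

    E_Q: float
    E_P: float


def _denominator(channel: DiscretizedChannel, fr: np.ndarray) -> float:
    As, An, Ac = channel.inlet_area_As, channel.exit_area_An, channel.expansion_area_Ac
    r = An / Ac
    return (
        -1.0 / As**2
        + (1.0 - 2.0 * r * (1.0 - r)) / An**2
        + float(np.sum(fr / channel.A[1:] ** 2))
    )


def solve_flow_rate(
    channel: DiscretizedChannel,
    fr,
    fluid: FluidProperties,
    conditions: FlowConditions,
) -> float:
    """Closed-form flow rate of the modified Bernoulli system, cm^3/s."""
    fr = _as_fr(fr)
    if fr.size != channel.n:
        raise ValueError(f"expected {channel.n} segment coefficients, got {fr.size}")
    denom = _denominator(channel, fr)
    if denom <= 0.0:
        raise NoRealSolutionError(
            "non-positive denominator: resistance profile admits no real flow rate"
        )
    return float(np.sqrt(2.0 * conditions.delta_P / fluid.density_rho / denom))


def pressure_distribution(
    channel: DiscretizedChannel,
    fr,
    fluid: FluidProperties,
    conditions: FlowConditions,
    Q: float,
) -> FlowSolution:
    """Per-section pressures for a given flow rate and resistance profile.

    ``P_i = Ps + rho/2 (Q/As)^2 - rho/2 (Q/A_i)^2 - rho/2 Q^2 *
    sum_{j<=i} fr_j/A_j^2``; the recovered outlet pressure applies the
    sudden-expansion term to ``P_n`` and closes back on the prescribed
    ``Pc`` when ``Q`` solves the flow-rate equation.
    """
    if Q < 0:
        raise ValueError("Q must be >= 0")
    fr = _as_fr(fr)
    rho = fluid.density_rho
    Ps = conditions.inlet_pressure_Ps
    A = channel.A
    As, An, Ac = channel.inlet_area_As, channel.exit_area_An, channel.expansion_area_Ac
    loss = np.concatenate(([0.0], np.cumsum(fr / A[1:] ** 2)))
    P = Ps + 0.5 * rho * (Q / As) ** 2 - 0.5 * rho * (Q / A) ** 2 - 0.5 * rho * Q**2 * loss
    r = An / Ac
    recovered_Pc = float(P[-1] + 0.5 * rho * (Q / An) ** 2 * 2.0 * r * (1.0 - r))
    return FlowSolution(Q=float(Q), pressures_P=P, recovered_Pc=recovered_Pc, fr=fr)


def compute_target_fr(
    areas,
    mean_pressures,
    Q_ref: float,
    fluid: FluidProperties,
) -> ResistanceProfile:
    """Invert the segment pressure balance for the resistance coefficients.

    Given per-section areas and mean pressures (e.g. section-averaged
    Navier-Stokes data) and the reference flow rate, returns::

        fr_i = [ (P_{i-1} - P_i) + rho/2 Q^2 (1/A_{i-1}^2 - 1/A_i^2) ]
               / ( rho/2 (Q/A_i)^2 )

    which is the exact algebraic inverse of the per-segment Bernoulli
    balance.
    """
    if Q_ref <= 0:
        raise ValueError("Q_ref must be > 0")
    A = np.asarray(areas, dtype=float)
    P = np.asarray(mean_pressures, dtype=float)
    if A.shape != P.shape or A.ndim != 1 or A.size < 2:
        raise ValueError("areas and mean_pressures must be 1-D arrays of equal length >= 2")
    rho = fluid.density_rho
    num = (P[:-1] - P[1:]) + 0.5 * rho * Q_ref**2 * (1.0 / A[:-1] ** 2 - 1.0 / A[1:] ** 2)
    return ResistanceProfile(num / (0.5 * rho * (Q_ref / A[1:]) ** 2))


def solve_self_consistent(
    channel: DiscretizedChannel,
    fluid: FluidProperties,
    conditions: FlowConditions,
    model: "TrainedModel",
    tol: float = 1e-6,
    max_iter: int = 50,
    relaxation: float = 0.5,
) -> FlowSolution:
    """Fixed-point iteration coupling resistance prediction and flow rate.

    The features feeding the resistance model depend on ``Q`` (pressure-drop
    coefficient and Reynolds number) while ``Q`` depends on the predicted
    resistance, so the two are iterated: start from ``fr = 0``, predict,
    under-relax the resistance update, and resolve until the relative change
    of ``Q`` drops below ``tol``.
    """
    fr = np.zeros(channel.n)
    base = _denominator(channel, fr)
    if base <= 0.0:
        raise NoRealSolutionError("channel admits no real inviscid flow rate")
    Q = solve_flow_rate(channel, fr, fluid, conditions)
    trace = [Q]
    inv_A2 = 1.0 / channel.A[1:] ** 2
    for iteration in range(1, max_iter + 1):
        X = _feature_array(channel, fluid, conditions, Q)
        fr_new = model.predict(X)
        # physical safeguard: individual coefficients may be negative (local
        # pressure recovery) but the TOTAL viscous loss of a dissipative
        # channel cannot be negative — such out-of-distribution predictions
        # make the fixed point run away (Q above the inviscid value).
        # Rescale the negative entries so the total is exactly zero,
        # preserving the positive (dissipative) part of the profile.
        S = float(np.sum(fr_new * inv_A2))
        if S < 0.0:
            pos = fr_new > 0.0
            pos_sum = float(np.sum(fr_new[pos] * inv_A2[pos]))
            neg_sum = S - pos_sum
            factor = pos_sum / -neg_sum if neg_sum < 0.0 else 0.0
            fr_new = np.where(pos, fr_new, fr_new * factor)
        fr = relaxation * fr_new + (1.0 - relaxation) * fr
        Q_new = solve_flow_rate(channel, fr, fluid, conditions)
        trace.append(Q_new)
        if abs(Q_new - Q) / max(Q, 1e-300) < tol:
            sol = pressure_distribution(channel, fr, fluid, conditions, Q_new)
            sol.iterations = iteration
            return sol
        Q = Q_new
    raise ConvergenceError(
        f"self-consistent loop did not converge in {max_iter} iterations", trace
    )


def relative_errors(
    reference: FlowSolution,
    predicted: FlowSolution,
    conditions: FlowConditions,
) -> ErrorReport:
    """Percent errors of flow rate and of the glottal pressure distribution.

    ``E_Q = |Q - Qhat| / Q * 100``;
    ``E_P = (1/n) sum_{i=1..n} |P_i - Phat_i| / Ps * 100``.
    """
    if reference.Q == 0:
        raise ValueError("reference flow rate is zero; relative error undefined")
    if reference.pressures_P.shape != predicted.pressures_P.shape:
        raise ValueError("solutions must share one section grid")
    E_Q = abs(reference.Q - predicted.Q) / reference.Q * 100.0
    dP = np.abs(reference.pressures_P[1:] - predicted.pressures_P[1:])
    E_P = float(np.mean(dP) / conditions.inlet_pressure_Ps * 100.0)
    return ErrorReport(E_Q=float(E_Q), E_P=E_P)


def summarize_errors(reports: Sequence[ErrorReport]) -> dict:
    """Max and mean of E_Q and E_P over a set of shapes."""
    eq = np.array([r.E_Q for r in reports])
    ep = np.array([r.E_P for r in reports])
    return {
        "E_Q_max": float(eq.max()),
        "E_Q_mean": float(eq.mean()),
        "E_Q_min": float(eq.min()),
        "E_P_max": float(ep.max()),
        "E_P_mean": float(ep.mean()),
        "E_P_min": float(ep.min()),
    }
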