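"""Spatially homogeneous limit: basic offspring number, equilibria, inversion.

Integrating the reaction-diffusion system over an isolated region (no-flux
boundary) and dividing by its area removes the diffusion term and leaves the
well-mixed ODE system

    dM/dt = gamma A - mu1 M
    dE/dt = r M - e E
    dA/dt = e (1 - A/k) E - (mu2 + gamma) A.

Its dynamics are governed by the basic offspring number

    Q0 = r gamma / (mu1 (gamma + mu2)):

for Q0 <= 1 the only admissible equilibrium is extinction (0, 0, 0); for
Q0 > 1 a unique coexistence equilibrium appears with every component scaled
by the carrying capacity k and the bifurcation factor (1 - 1/Q0).
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np

from .grid import Grid
from .params import EquilibriumState, ParameterSet, SpraySchedule

__all__ = [
    "basic_offspring_number",
    "equilibrium_state",
    "invert_carrying_capacity",
    "pulsed_to_continuous_rate",
    "total_equilibrium",
    "ode_rhs",
]


def basic_offspring_number(p: ParameterSet) -> float:
    """Q0 = r*gamma / (mu1*gamma + mu1*mu2); population persists iff Q0 > 1."""
    mu1 = p.mu1
    if mu1 <= 0:
        raise ValueError("basic offspring number undefined for mu1 = 0")
    if p.gamma + p.mu2 <= 0:
        raise ValueError("basic offspring number undefined for gamma + mu2 = 0")
    return p.r * p.gamma / (mu1 * (p.gamma + p.mu2))


def equilibrium_state(p: ParameterSet) -> EquilibriumState:
    """Equilibrium of the well-mixed system: extinction or coexistence.

    For Q0 > 1 the coexistence equilibrium is

        A* = k (1 - 1/Q0)
        M* = k gamma / mu1 * (1 - 1/Q0)
        E* = k gamma r / (mu1 e) * (1 - 1/Q0).
    """
    q0 = basic_offspring_number(p)
    if q0 <= 1.0:
        return EquilibriumState(Q0=q0, M_star=0.0, E_star=0.0, A_star=0.0)
    if p.e <= 0:
        raise ValueError("coexistence equilibrium undefined for hatching rate e = 0")
    factor = p.k * (1.0 - 1.0 / q0)
    mu1 = p.mu1
    return EquilibriumState(
        Q0=q0,
        M_star=factor * p.gamma / mu1,
        E_star=factor * p.gamma * p.r / (mu1 * p.e),
        A_star=factor,
    )


def invert_carrying_capacity(
    observed: float,
    phase: Literal["mobile", "egg", "aquatic"],
    p: ParameterSet,
) -> float:
    """Carrying capacity k that makes the chosen equilibrium phase equal ``observed``.

    Field surveys measure at most one phase (adult catches, ovitrap eggs, or
    larval densities); given the rates, the matching equilibrium expression
    is solved for k.  The k field of ``p`` is ignored.
    """
    if observed <= 0:
        raise ValueError(f"observed equilibrium density must be positive, got {observed}")
    q0 = basic_offspring_number(p)
    if q0 <= 1.0:
        raise ValueError(
            f"no positive equilibrium to invert: Q0 = {q0:.4g} <= 1"
        )
    factor = 1.0 - 1.0 / q0
    mu1 = p.mu1
    if phase == "mobile":
        return observed * mu1 / (p.gamma * factor)
    if phase == "egg":
        if p.e <= 0:
            raise ValueError("egg equilibrium undefined for hatching rate e = 0")
        return observed * mu1 * p.e / (p.gamma * p.r * factor)
    if phase == "aquatic":
        return observed / factor
    raise ValueError(f"unknown phase {phase!r}; expected mobile, egg or aquatic")


def pulsed_to_continuous_rate(schedule: SpraySchedule) -> float:
    """Continuous mortality increment with the same time-averaged dose.

    The pulse rate is divided by the number of window-lengths per period
    (e.g. a weekly 30-minute pulse at 48/day becomes 48/336 per day),
    emulating the same amount of insecticide applied continuously.  Used for
    the equilibrium reference lines against which pulsed runs are compared.
    """
    return schedule.rate * schedule.window / schedule.period


def total_equilibrium(
    coeffs,
    grid: Grid,
    *,
    phase: Literal["mobile", "egg", "aquatic"] = "mobile",
) -> float:
    """Total equilibrium population over a heterogeneous raster, in individuals.

    The well-mixed equilibrium is applied cell by cell (each cell sees its
    local coefficients) and the densities are summed times the cell area.
    For homogeneous coefficients this reduces to density * domain area.

    ``coeffs`` is a :class:`~aedesdyn.fvm.CoefficientFields`; the insecticide
    increment stored in it is included in the local mu1 (pass a version with
    zero increment for the no-insecticide reference).
    """
    shape = grid.shape
    mu1 = np.broadcast_to(
        np.asarray(coeffs.mu1_base + coeffs.mu1_insecticide, dtype=float), shape
    )
    mu2 = np.broadcast_to(np.asarray(coeffs.mu2, dtype=float), shape)
    gamma = np.broadcast_to(np.asarray(coeffs.gamma, dtype=float), shape)
    r = np.broadcast_to(np.asarray(coeffs.r, dtype=float), shape)
    e = np.broadcast_to(np.asarray(coeffs.e, dtype=float), shape)
    k = np.broadcast_to(np.asarray(coeffs.k, dtype=float), shape)

    if np.any(mu1 <= 0):
        raise ValueError("mu1 must be positive everywhere for the local equilibrium")
    q0 = r * gamma / (mu1 * (gamma + mu2))
    factor = np.where(q0 > 1.0, k * (1.0 - 1.0 / np.maximum(q0, 1.0)), 0.0)
    if phase == "mobile":
        dens = factor * gamma / mu1
    elif phase == "egg":
        dens = factor * gamma * r / (mu1 * e)
    elif phase == "aquatic":
        dens = factor
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return float(dens.sum() * grid.cell_area)


def ode_rhs(t: float, y: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Right-hand side of the well-mixed ODE system for y = (M, E, A)."""
    M, E, A = y
    return np.array(
        [
            p.gamma * A - p.mu1 * M,
            p.r * M - p.e * E,
            p.e * (1.0 - A / p.k) * E - (p.mu2 + p.gamma) * A,
        ]
    )
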