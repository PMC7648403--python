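"""Core domain types: rate parameters, spray schedules, and validation.

Units are fixed globally: lengths in meters, time in days, rates in 1/day,
population densities in individuals/m^2.  Egg mortality is taken to be zero
(desiccation-resistant eggs survive far longer than the time scales modelled
here) and therefore has no parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ParameterSet",
    "SpraySchedule",
    "EquilibriumState",
    "AnnulusData",
    "validate_parameters",
    "maturation_rate",
    "oviposition_rate",
    "rate_from_characteristic_time",
    "characteristic_time",
    "TABLE_WEIGHTS",
]

#: Default per-ring fit weights emphasising the outer (radial-propagation) rings.
TABLE_WEIGHTS = (1.0, 1.0, 5.0, 10.0, 10.0)


@dataclass(frozen=True)
class ParameterSet:
    """Rate and capacity coefficients of the three-compartment model.

    Attributes
    ----------
    D : float
        Diffusion coefficient of mobile females, m^2/day.
    gamma : float
        Aquatic-to-mobile maturation rate, 1/day (females only).
    mu1_base : float
        Base mortality rate of the mobile phase, 1/day.
    mu1_insecticide : float
        Mortality increment applied during an insecticide spray window, 1/day.
    mu2 : float
        Aquatic-phase mortality rate, 1/day.
    r : float
        Oviposition rate, eggs/day per female.
    e : float
        Egg hatching rate, 1/day.
    k : float
        Carrying capacity of the aquatic phase, individuals/m^2.
    """

    D: float
    gamma: float
    mu1_base: float
    mu2: float
    r: float
    e: float
    k: float
    mu1_insecticide: float = 0.0

    @property
    def mu1(self) -> float:
        """Effective mobile mortality: base plus insecticide increment."""
        return self.mu1_base + self.mu1_insecticide

    def with_insecticide(self, rate: float) -> "ParameterSet":
        return replace(self, mu1_insecticide=rate)

    def validate(self, for_simulation: bool = True) -> "ParameterSet":
        return validate_parameters(self, for_simulation=for_simulation)


def validate_parameters(p: ParameterSet, for_simulation: bool = True) -> ParameterSet:
    """Check nonnegativity of all rates and, for simulation use, D > 0 and k > 0.

    Returns ``p`` unchanged if valid; raises :class:`ValueError` naming the
    offending field otherwise.
    """
    for name in ("D", "gamma", "mu1_base", "mu1_insecticide", "mu2", "r", "e", "k"):
        value = getattr(p, name)
        if not math.isfinite(value):
            raise ValueError(f"parameter {name!r} must be finite, got {value}")
        if value < 0:
            raise ValueError(f"parameter {name!r} must be nonnegative, got {value}")
    if for_simulation:
        if p.D <= 0:
            raise ValueError(f"parameter 'D' must be strictly positive for simulation, got {p.D}")
        if p.k <= 0:
            raise ValueError(f"parameter 'k' must be strictly positive for simulation, got {p.k}")
    return p


@dataclass(frozen=True)
class SpraySchedule:
    """Periodic pulsed insecticide application.

    The increment ``rate`` is added to the mobile mortality on spray-mask
    cells during every window ``[start + n*period, start + n*period + window)``.
    The default window is 30 minutes, the time an insecticide suspension
    stays in the air after spraying.
    """

    period: float
    rate: float
    window: float = 0.5 / 24.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"spray period must be positive, got {self.period}")
        if not (0 < self.window <= self.period):
            raise ValueError(
                f"spray window must satisfy 0 < window <= period, got "
                f"window={self.window}, period={self.period}"
            )
        if self.rate < 0:
            raise ValueError(f"spray rate must be nonnegative, got {self.rate}")
        if self.start_time < 0:
            raise ValueError(f"start_time must be nonnegative, got {self.start_time}")

    @property
    def characteristic_time(self) -> float:
        """1/rate, days — the exponential-decay time scale of the pulse."""
        if self.rate == 0:
            return math.inf
        return 1.0 / self.rate

    def active(self, t: float, dt_half: float = 0.0) -> bool:
        """True if time ``t`` (+ half-step offset) lies inside a spray window."""
        tt = t + dt_half
        if tt < self.start_time:
            return False
        phase = (tt - self.start_time) % self.period
        return phase < self.window - 1e-12 or math.isclose(phase, 0.0, abs_tol=1e-12)


@dataclass(frozen=True)
class EquilibriumState:
    """Basic offspring number and coexistence equilibrium densities."""

    Q0: float
    M_star: float
    E_star: float
    A_star: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.M_star, self.E_star, self.A_star)


@dataclass
class AnnulusData:
    """Concentric-ring trap layout: ring radii, counts, and fit weights.

    ``edges`` are the ordered ring boundaries (in meters, starting at the
    release point); ring ``i`` spans ``[edges[i], edges[i+1])``.
    """

    edges: Sequence[float] = (0.0, 100.0, 200.0, 400.0, 600.0, 800.0)
    counts: Sequence[float] | None = None
    weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        self.edges = tuple(float(x) for x in self.edges)
        if len(self.edges) < 2:
            raise ValueError("need at least two ring edges")
        if self.edges[0] < 0:
            raise ValueError("ring edges must be nonnegative")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError(f"ring edges must be strictly increasing, got {self.edges}")
        n = self.n_rings
        if self.counts is None:
            self.counts = tuple(0.0 for _ in range(n))
        else:
            self.counts = tuple(float(c) for c in self.counts)
        if self.weights is None:
            w = TABLE_WEIGHTS if n == len(TABLE_WEIGHTS) else tuple(1.0 for _ in range(n))
            self.weights = w
        else:
            self.weights = tuple(float(w) for w in self.weights)
        if len(self.counts) != n:
            raise ValueError(f"expected {n} ring counts, got {len(self.counts)}")
        if len(self.weights) != n:
            raise ValueError(f"expected {n} ring weights, got {len(self.weights)}")

    @property
    def n_rings(self) -> int:
        return len(self.edges) - 1

    @property
    def inner(self) -> np.ndarray:
        return np.asarray(self.edges[:-1])

    @property
    def outer(self) -> np.ndarray:
        return np.asarray(self.edges[1:])


# ---------------------------------------------------------------------------
# Parameter-estimation recipes
# ---------------------------------------------------------------------------

def maturation_rate(maturation_days: float, female_fraction: float = 0.5) -> float:
    """Maturation rate gamma from the larva-to-adult development time.

    Only emerging females enter the mobile compartment, so the inverse
    development time is scaled by the female sex fraction (default 50/50).
    Eight days of development gives gamma = 0.0625 females/day.
    """
    if maturation_days <= 0:
        raise ValueError("maturation time must be positive")
    if not 0 < female_fraction <= 1:
        raise ValueError("female fraction must lie in (0, 1]")
    return female_fraction / maturation_days


def oviposition_rate(
    eggs_per_day: float, laying_days: float, lifetime_days: float
) -> float:
    """Lifetime-averaged oviposition rate r, eggs/day per female.

    Laboratory assays report a per-day clutch output over a short laying
    period; the model needs the average over the whole adult lifetime, so
    the lifetime egg total is divided by the lifespan.  75.01 eggs/day over
    5 laying days and an 11-day lifetime gives r ~ 34.1, rounded to 34 in
    the bundled defaults.
    """
    if min(eggs_per_day, laying_days, lifetime_days) <= 0:
        raise ValueError("all arguments must be positive")
    return eggs_per_day * laying_days / lifetime_days


def rate_from_characteristic_time(t_char_days: float) -> float:
    """Mortality rate whose exponential decay has the given time scale.

    Used to convert the airborne residence time of a sprayed insecticide
    (30 minutes) into a mortality increment: 1/(0.5/24) = 48/day.
    """
    if t_char_days <= 0:
        raise ValueError("characteristic time must be positive")
    return 1.0 / t_char_days


def characteristic_time(rate: float) -> float:
    """Inverse of a decay rate, in days; infinite for rate zero."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    return math.inf if rate == 0 else 1.0 / rate
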