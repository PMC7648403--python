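"""Genetic-algorithm estimation of dispersal parameters from ring counts.

Fits (D, mu, alpha) of the damped heat kernel to observed ovitrap counts on
concentric annuli by minimizing the weighted squared error

    sum_i ((R_i - E_i) * w_i)^2,

where R are the model ring counts, E the observed ones, and the weights
(default (1, 1, 5, 10, 10)) emphasise the outer rings carrying the radial
propagation signal.

The algorithm: tournament selection of size 4, arithmetic crossover (child =
component-wise mean of two parents), and a bounds-respecting truncated-normal
mutation whose scale decays over the generations (a simple stand-in for the
"adaptive feasible" mutation of commercial GA toolboxes).  One elite
individual is carried over unchanged each generation, which makes the best
objective value non-increasing.  All randomness flows from a single seed.

Note on identifiability: with observations at a single elapsed time t, the
objective depends on mu and alpha only through the product alpha*exp(-mu*t)
(an overall scale on the D-dependent ring profile), so the error surface has
an exactly flat valley trading mu against alpha.  D and the product are well
determined; where the algorithm settles along the valley depends on the seed,
which is what the spread of repeated fits measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kernel import ReleaseSpec, annulus_expected_counts
from .params import AnnulusData

__all__ = [
    "FitBounds",
    "FitResult",
    "GAParams",
    "weighted_error",
    "ga_optimize",
    "repeat_fit",
    "RepeatSummary",
]

PARAM_NAMES = ("D", "mu", "alpha")


@dataclass(frozen=True)
class FitBounds:
    """Box constraints of the search space.

    Defaults: D below 30000 m^2/day (several times any field estimate), mu
    below 1/day (adults survive days, not hours), alpha below 0.1 (thousands
    released, tens detected).  Lower bounds are zero.  Bounds may collapse to
    a point, in which case the search space is that single candidate.
    """

    D_max: float = 30000.0
    mu_max: float = 1.0
    alpha_max: float = 0.1
    D_min: float = 0.0
    mu_min: float = 0.0
    alpha_min: float = 0.0

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.D_min, self.D_max, "D"),
            (self.mu_min, self.mu_max, "mu"),
            (self.alpha_min, self.alpha_max, "alpha"),
        ):
            if lo < 0 or hi < lo:
                raise ValueError(f"bounds for {name} must satisfy 0 <= lower <= upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.D_min, self.mu_min, self.alpha_min])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.D_max, self.mu_max, self.alpha_max])

    def contains(self, theta: np.ndarray) -> bool:
        return bool(np.all(theta >= self.lower) and np.all(theta <= self.upper))


@dataclass(frozen=True)
class GAParams:
    """Population controls: 50 individuals over at most 200 generations,
    early stop after 30 generations without improvement of the best error."""

    population: int = 50
    generations: int = 200
    tournament_size: int = 4
    crossover_fraction: float = 0.8
    mutation_scale: float = 0.2
    mutation_decay: float = 0.97
    elite: int = 1
    stagnation_limit: int = 30

    def __post_init__(self) -> None:
        if self.population < 2 or self.generations < 1:
            raise ValueError("population >= 2 and generations >= 1 required")
        if not 0 <= self.crossover_fraction <= 1:
            raise ValueError("crossover_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FitResult:
    D: float
    mu: float
    alpha: float
    error: float
    generations_run: int
    seed: int

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.mu, self.alpha])


def weighted_error(predicted, observed: AnnulusData) -> float:
    """Weighted squared deviation between model and observed ring counts."""
    predicted = np.asarray(predicted, dtype=float)
    counts = np.asarray(observed.counts, dtype=float)
    if predicted.shape != counts.shape:
        raise ValueError(
            f"predicted has {predicted.shape[0] if predicted.ndim else 0} entries, "
            f"observed has {counts.shape[0]} rings"
        )
    w = np.asarray(observed.weights, dtype=float)
    return float(np.sum(((predicted - counts) * w) ** 2))


def _objective(theta: np.ndarray, observed: AnnulusData, release: ReleaseSpec) -> float:
    D, mu, alpha = theta
    if D <= 0:
        # zero diffusion puts all mass at the origin point: no trap mass
        pred = np.zeros(observed.n_rings)
    else:
        pred = annulus_expected_counts(release, D, mu, alpha, observed)
    return weighted_error(pred, observed)


def _truncated_normal(rng: np.random.Generator, center, scale, lo, hi):
    """Normal proposal re-drawn (then clipped) into [lo, hi]."""
    out = rng.normal(center, scale)
    for _ in range(10):
        bad = (out < lo) | (out > hi)
        if not np.any(bad):
            return out
        out = np.where(bad, rng.normal(center, scale), out)
    return np.clip(out, lo, hi)


def ga_optimize(
    observed: AnnulusData,
    release: ReleaseSpec,
    bounds: FitBounds | None = None,
    ga_params: GAParams | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit (D, mu, alpha) to observed ring counts by a genetic algorithm.

    Deterministic for a given seed.  The returned candidate is always inside
    the bounds and its error never exceeds the best error of the initial
    population (elitism).
    """
    if any(c < 0 for c in observed.counts):
        raise ValueError("observed counts must be nonnegative")
    bounds = bounds or FitBounds()
    ga = ga_params or GAParams()
    lo, hi = bounds.lower, bounds.upper
    span = hi - lo
    rng = np.random.default_rng(seed)

    if np.all(span == 0):
        theta = lo.copy()
        return FitResult(
            D=theta[0],
            mu=theta[1],
            alpha=theta[2],
            error=_objective(theta, observed, release),
            generations_run=0,
            seed=seed,
        )

    pop = lo + rng.random((ga.population, 3)) * span
    errors = np.array([_objective(t, observed, release) for t in pop])

    best_idx = int(np.argmin(errors))
    best = pop[best_idx].copy()
    best_err = float(errors[best_idx])
    stagnant = 0
    gens_run = 0

    for gen in range(ga.generations):
        gens_run = gen + 1
        scale = ga.mutation_scale * (ga.mutation_decay**gen) * span

        def tournament() -> np.ndarray:
            idx = rng.integers(0, ga.population, size=ga.tournament_size)
            return pop[idx[np.argmin(errors[idx])]]

        children = np.empty_like(pop)
        children[: ga.elite] = best
        for i in range(ga.elite, ga.population):
            if rng.random() < ga.crossover_fraction:
                children[i] = 0.5 * (tournament() + tournament())
            else:
                children[i] = _truncated_normal(rng, tournament(), scale, lo, hi)
        pop = children
        errors = np.array([_objective(t, observed, release) for t in pop])

        gen_best = int(np.argmin(errors))
        if errors[gen_best] < best_err:
            best_err = float(errors[gen_best])
            best = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= ga.stagnation_limit:
            break

    return FitResult(
        D=float(best[0]),
        mu=float(best[1]),
        alpha=float(best[2]),
        error=best_err,
        generations_run=gens_run,
        seed=seed,
    )


@dataclass(frozen=True)
class RepeatSummary:
    """Per-parameter mean, standard deviation, and SD as a percentage of the
    mean across repeated fits with distinct seeds."""

    mean: dict[str, float]
    sd: dict[str, float]
    sd_percent: dict[str, float]
    results: tuple[FitResult, ...]

    def table(self):
        """Summary as a pandas DataFrame (parameter, mean, sd, sd_percent)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": list(PARAM_NAMES),
                "mean": [self.mean[n] for n in PARAM_NAMES],
                "sd": [self.sd[n] for n in PARAM_NAMES],
                "sd_percent": [self.sd_percent[n] for n in PARAM_NAMES],
            }
        )


def repeat_fit(
    observed: AnnulusData,
    release: ReleaseSpec,
    bounds: FitBounds | None = None,
    ga_params: GAParams | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> RepeatSummary:
    """Run the GA ``n_repeats`` times with distinct derived seeds.

    Reports the mean, standard deviation (ddof = 1) and relative SD of each
    parameter, the format in which repeated stochastic fits are usually
    tabulated.
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats for a standard deviation")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    results = tuple(
        ga_optimize(observed, release, bounds, ga_params, seed=int(s))
        for s in child_seeds
    )
    values = np.array([r.as_array() for r in results])
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(mean != 0, 100.0 * sd / np.abs(mean), np.nan)
    return RepeatSummary(
        mean=dict(zip(PARAM_NAMES, mean)),
        sd=dict(zip(PARAM_NAMES, sd)),
        sd_percent=dict(zip(PARAM_NAMES, pct)),
        results=results,
    )
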