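"""Finite-volume Crank-Nicolson integrator for the reaction-diffusion system.

The three-compartment model

    dM/dt = div(D grad M) + gamma A - mu1 M
    dE/dt = r M - e E
    dA/dt = e (1 - A/k) E - (mu2 + gamma) A

is discretized on a uniform cell-centered grid with a conservative two-point
flux (face diffusivity = harmonic mean of the adjacent cells, appropriate for
the piecewise-constant street/house coefficient fields) and zero-flux outer
boundaries.  Time stepping is Crank-Nicolson; the diffusion term leads to one
sparse linear solve per sweep while the local source terms are closed by a
fixed-point (Picard) iteration, which converges in a few sweeps at the mild
nonlinearity of the aquatic logistic term.

Insecticide pulses enter as a mortality increment added on spray-mask cells
during scheduled windows; window edges must coincide with step boundaries so
that every step is entirely inside or outside a pulse.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import factorized

from .grid import FieldSet, Grid
from .kernel import ReleaseSpec
from .params import AnnulusData, ParameterSet, SpraySchedule

__all__ = [
    "SolverConfig",
    "CoefficientFields",
    "SimulationResult",
    "build_diffusion_operator",
    "step",
    "simulate",
    "dispersal_simulate",
    "annulus_sums",
]

log = logging.getLogger(__name__)

#: Largest admissible time step: 30 minutes.
DT_MAX = 1.0 / 48.0


@dataclass(frozen=True)
class SolverConfig:
    """Time-stepping controls.

    ``dt`` may not exceed 30 minutes (1/48 day); when a spray schedule is
    used it must also divide the spray window so pulses align with steps.
    """

    dt: float = DT_MAX
    t_end: float = 1.0
    nonlinear_tol: float = 1e-10
    max_inner_iters: int = 50
    snapshot_times: tuple[float, ...] = ()
    boundary_mass_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.dt > DT_MAX * (1 + 1e-12):
            raise ValueError(f"dt must not exceed 1/48 day (30 min), got {self.dt}")
        if self.t_end <= 0:
            raise ValueError(f"t_end must be positive, got {self.t_end}")
        if self.nonlinear_tol <= 0 or self.max_inner_iters < 1:
            raise ValueError("nonlinear_tol must be > 0 and max_inner_iters >= 1")

    @property
    def n_steps(self) -> int:
        n = int(round(self.t_end / self.dt))
        if not math.isclose(n * self.dt, self.t_end, rel_tol=1e-9):
            raise ValueError(
                f"t_end = {self.t_end} is not an integer number of steps of dt = {self.dt}"
            )
        return n


def _as_field(value, shape) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(shape, float(arr))
    if arr.shape != shape:
        raise ValueError(f"coefficient has shape {arr.shape}, expected {shape}")
    return arr


@dataclass
class CoefficientFields:
    """Per-cell model coefficients on a grid.

    ``D``, ``mu1_base``, ``mu1_insecticide`` and ``mu2`` may vary per cell
    (streets vs. house blocks); ``gamma``, ``r``, ``e`` and ``k`` may be
    scalars or fields.  ``mu1_insecticide`` is the increment applied during
    spray windows (zero off the spray mask).
    """

    grid: Grid
    D: np.ndarray
    mu1_base: np.ndarray
    mu2: np.ndarray
    gamma: np.ndarray | float
    r: np.ndarray | float
    e: np.ndarray | float
    k: np.ndarray | float
    mu1_insecticide: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        shape = self.grid.shape
        self.D = _as_field(self.D, shape)
        self.mu1_base = _as_field(self.mu1_base, shape)
        self.mu2 = _as_field(self.mu2, shape)
        self.mu1_insecticide = _as_field(self.mu1_insecticide, shape)
        for name in ("gamma", "r", "e", "k"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, float(v) if v.ndim == 0 else _as_field(v, shape))
        if np.any(self.D <= 0):
            raise ValueError("diffusion coefficient must be positive everywhere")
        for name in ("mu1_base", "mu2", "mu1_insecticide"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"coefficient {name} must be nonnegative")
        if np.any(np.asarray(self.k) <= 0):
            raise ValueError("carrying capacity k must be positive everywhere")

    @classmethod
    def homogeneous(cls, grid: Grid, p: ParameterSet) -> "CoefficientFields":
        return cls(
            grid=grid,
            D=p.D,
            mu1_base=p.mu1_base,
            mu2=p.mu2,
            gamma=p.gamma,
            r=p.r,
            e=p.e,
            k=p.k,
            mu1_insecticide=p.mu1_insecticide,
        )

    def without_insecticide(self) -> "CoefficientFields":
        return CoefficientFields(
            grid=self.grid,
            D=self.D,
            mu1_base=self.mu1_base,
            mu2=self.mu2,
            gamma=self.gamma,
            r=self.r,
            e=self.e,
            k=self.k,
            mu1_insecticide=0.0,
        )


def build_diffusion_operator(
    grid: Grid, D, mean: str = "harmonic"
) -> sp.csr_matrix:
    """Sparse operator L with (L u) ~ div(D grad u) per cell, no-flux boundary.

    Face diffusivities are the harmonic (default) or arithmetic mean of the
    two adjacent cell values; the harmonic mean is conservative and exact for
    piecewise-constant coefficients.  Rows and columns sum to zero, so the
    operator conserves total mass exactly.
    """
    ny, nx = grid.shape
    D = _as_field(D, grid.shape)
    inv_h2 = 1.0 / grid.dx**2

    def face(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if mean == "harmonic":
            return 2.0 * a * b / (a + b)
        if mean == "arithmetic":
            return 0.5 * (a + b)
        raise ValueError(f"unknown face mean {mean!r}")

    idx = np.arange(nx * ny).reshape(ny, nx)
    rows, cols, vals = [], [], []

    def add_faces(i_a, i_b, t):
        t = t.ravel() * inv_h2
        a = i_a.ravel()
        b = i_b.ravel()
        rows.extend([a, a, b, b])
        cols.extend([a, b, b, a])
        vals.extend([-t, t, -t, t])

    # vertical faces (east-west neighbours)
    add_faces(idx[:, :-1], idx[:, 1:], face(D[:, :-1], D[:, 1:]))
    # horizontal faces (north-south neighbours)
    add_faces(idx[:-1, :], idx[1:, :], face(D[:-1, :], D[1:, :]))

    n = nx * ny
    L = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return L.tocsr()


@dataclass
class SimulationResult:
    """Per-step totals, optional snapshots, and solver diagnostics."""

    times: np.ndarray
    total_M: np.ndarray
    total_E: np.ndarray
    total_A: np.ndarray
    final: FieldSet
    snapshots: dict[float, FieldSet] = field(default_factory=dict)
    max_inner_iters_used: int = 0
    max_constraint_violation: float = 0.0

    def totals_frame(self):
        """Totals as a pandas DataFrame (t, total_M, total_E, total_A)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t_days": self.times,
                "total_M": self.total_M,
                "total_E": self.total_E,
                "total_A": self.total_A,
            }
        )


class _CNStepper:
    """Crank-Nicolson stepper with cached factorizations per mortality state."""

    def __init__(
        self,
        coeffs: CoefficientFields,
        dt: float,
        nonlinear_tol: float = 1e-10,
        max_inner_iters: int = 50,
        mean: str = "harmonic",
    ):
        self.grid = coeffs.grid
        self.coeffs = coeffs
        self.dt = dt
        self.tol = nonlinear_tol
        self.max_iters = max_inner_iters
        self.L = build_diffusion_operator(self.grid, coeffs.D, mean=mean)
        self._solvers: dict[bool, Callable[[np.ndarray], np.ndarray]] = {}
        self.max_inner_used = 0
        self.max_violation = 0.0

    def _mu1(self, spray_on: bool) -> np.ndarray:
        mu1 = self.coeffs.mu1_base
        if spray_on:
            mu1 = mu1 + self.coeffs.mu1_insecticide
        return mu1

    def _solver(self, spray_on: bool):
        if spray_on not in self._solvers:
            n = self.grid.n_cells
            mu1 = self._mu1(spray_on).ravel()
            A = sp.eye(n, format="csc") - (self.dt / 2.0) * (
                self.L.tocsc() - sp.diags(mu1, format="csc")
            )
            self._solvers[spray_on] = factorized(A.tocsc())
        return self._solvers[spray_on]

    def step(self, fields: FieldSet, spray_on: bool = False) -> FieldSet:
        c = self.coeffs
        dt = self.dt
        mu1 = self._mu1(spray_on)
        solve = self._solver(spray_on)

        M0 = fields.M
        E0 = fields.E
        A0 = fields.A
        lap0 = self.L.dot(M0.ravel()).reshape(self.grid.shape)

        # explicit (old-time) halves of the Crank-Nicolson right sides
        f1_old = lap0 + c.gamma * A0 - mu1 * M0
        f3_old = c.r * M0 - c.e * E0
        f2_old = c.e * (1.0 - A0 / c.k) * E0 - (c.mu2 + c.gamma) * A0

        rhs_M_base = M0 + (dt / 2.0) * f1_old
        rhs_E_base = E0 + (dt / 2.0) * f3_old
        rhs_A_base = A0 + (dt / 2.0) * f2_old
        denom_E = 1.0 + (dt / 2.0) * c.e

        M1, E1, A1 = M0, E0, A0
        converged = False
        for it in range(1, self.max_iters + 1):
            rhs = (rhs_M_base + (dt / 2.0) * c.gamma * A1).ravel()
            M_new = solve(rhs).reshape(self.grid.shape)
            E_new = (rhs_E_base + (dt / 2.0) * c.r * M_new) / denom_E
            denom_A = 1.0 + (dt / 2.0) * (c.e * E_new / c.k + c.mu2 + c.gamma)
            A_new = (rhs_A_base + (dt / 2.0) * c.e * E_new) / denom_A

            scale = max(
                float(np.abs(M_new).max()),
                float(np.abs(E_new).max()),
                float(np.abs(A_new).max()),
                1e-300,
            )
            delta = max(
                float(np.abs(M_new - M1).max()),
                float(np.abs(E_new - E1).max()),
                float(np.abs(A_new - A1).max()),
            )
            M1, E1, A1 = M_new, E_new, A_new
            if delta <= self.tol * scale:
                converged = True
                break
        self.max_inner_used = max(self.max_inner_used, it)
        if not converged:
            raise RuntimeError(
                f"Crank-Nicolson inner iteration failed to reach {self.tol:g} "
                f"in {self.max_iters} sweeps (last change {delta:.3e})"
            )

        # final guard: the continuous system is box-invariant, so any
        # excursion should be at roundoff/tolerance level; clip and log.
        kk = np.asarray(c.k)
        violation = max(
            float(-min(M1.min(), 0.0)),
            float(-min(E1.min(), 0.0)),
            float(-min(A1.min(), 0.0)),
            float(max((A1 - kk).max(), 0.0)),
        )
        if violation > 0.0:
            self.max_violation = max(self.max_violation, violation)
            if violation > 100.0 * self.tol:
                log.warning("box-constraint guard clipped a violation of %.3e", violation)
            M1 = np.maximum(M1, 0.0)
            E1 = np.maximum(E1, 0.0)
            A1 = np.clip(A1, 0.0, kk)
        return FieldSet(self.grid, M1, E1, A1)


def step(
    fields: FieldSet,
    coeffs: CoefficientFields,
    dt: float,
    *,
    spray_on: bool = False,
    nonlinear_tol: float = 1e-10,
    max_inner_iters: int = 50,
    mean: str = "harmonic",
) -> FieldSet:
    """One Crank-Nicolson update of all three fields.

    Convenience wrapper building a throw-away stepper; for long runs use
    :func:`simulate`, which caches the sparse factorization.
    """
    stepper = _CNStepper(coeffs, dt, nonlinear_tol, max_inner_iters, mean=mean)
    return stepper.step(fields, spray_on=spray_on)


def _check_alignment(schedule: SpraySchedule, dt: float) -> None:
    for name, value in (
        ("window", schedule.window),
        ("period", schedule.period),
        ("start_time", schedule.start_time),
    ):
        ratio = value / dt
        if abs(ratio - round(ratio)) > 1e-9 * max(1.0, abs(ratio)):
            raise ValueError(
                f"spray {name} = {value} is not an integer multiple of dt = {dt}; "
                "pulse edges must coincide with step boundaries"
            )


def simulate(
    initial: FieldSet,
    coeffs: CoefficientFields,
    cfg: SolverConfig,
    schedule: SpraySchedule | None = None,
    mean: str = "harmonic",
) -> SimulationResult:
    """Integrate the full system, applying scheduled insecticide pulses.

    During each spray window the mortality increment ``coeffs.mu1_insecticide``
    (already masked to spray cells) is switched on.  Totals (population counts,
    density integrated over the domain) are recorded at every step; snapshot
    fields are stored at the requested times.
    """
    if schedule is not None and schedule.rate > 0:
        _check_alignment(schedule, cfg.dt)
    stepper = _CNStepper(
        coeffs, cfg.dt, cfg.nonlinear_tol, cfg.max_inner_iters, mean=mean
    )
    n_steps = cfg.n_steps
    times = np.empty(n_steps + 1)
    tot = np.empty((n_steps + 1, 3))
    fields = initial.copy()
    times[0] = 0.0
    tot[0] = fields.totals()
    snapshots: dict[float, FieldSet] = {}
    snap_steps = {}
    for ts in cfg.snapshot_times:
        snap_steps[int(round(ts / cfg.dt))] = float(ts)
    if 0 in snap_steps:
        snapshots[snap_steps[0]] = fields.copy()

    for n in range(1, n_steps + 1):
        t_mid = (n - 0.5) * cfg.dt
        spray_on = bool(
            schedule is not None and schedule.rate > 0 and schedule.active(t_mid)
        )
        fields = stepper.step(fields, spray_on=spray_on)
        times[n] = n * cfg.dt
        tot[n] = fields.totals()
        if n in snap_steps:
            snapshots[snap_steps[n]] = fields.copy()

    log.info(
        "simulate: %d steps, max inner iterations %d, max box violation %.2e",
        n_steps,
        stepper.max_inner_used,
        stepper.max_violation,
    )
    return SimulationResult(
        times=times,
        total_M=tot[:, 0],
        total_E=tot[:, 1],
        total_A=tot[:, 2],
        final=fields,
        snapshots=snapshots,
        max_inner_iters_used=stepper.max_inner_used,
        max_constraint_violation=stepper.max_violation,
    )


def dispersal_simulate(
    release: ReleaseSpec,
    D: float,
    mu: float,
    grid: Grid,
    cfg: SolverConfig,
    initial_M: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the simplified dispersal equation dM/dt = D lap M - mu M.

    The point release is discretized as M0/(dx*dy) in the cell nearest the
    domain center, preserving total mass exactly; a smooth ``initial_M``
    field may be supplied instead (e.g. for convergence studies against the
    analytic kernel).  The equation is linear, so each Crank-Nicolson step
    is a single pre-factorized sparse solve.

    The grid must be large enough that the analytic free-space solution
    assigns less than ``cfg.boundary_mass_tol`` of the surviving mass beyond
    the largest disc inscribed in the domain; otherwise wall reflection would
    contaminate the annulus counts.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    Lx, Ly = grid.extent
    r_inscribed = min(Lx, Ly) / 2.0
    outside = math.exp(-r_inscribed**2 / (4.0 * D * cfg.t_end))
    if outside > cfg.boundary_mass_tol:
        raise ValueError(
            f"domain too small: {outside:.2e} of the released mass would lie beyond "
            f"the inscribed radius {r_inscribed:.0f} m at t = {cfg.t_end} d "
            f"(tolerance {cfg.boundary_mass_tol:g})"
        )

    n = grid.n_cells
    Lop = build_diffusion_operator(grid, D)
    mu_vec = mu * sp.eye(n, format="csc")
    A_impl = sp.eye(n, format="csc") - (cfg.dt / 2.0) * (Lop.tocsc() - mu_vec)
    B_expl = sp.eye(n, format="csc") + (cfg.dt / 2.0) * (Lop.tocsc() - mu_vec)
    solve = factorized(A_impl)

    if initial_M is None:
        M = grid.zeros()
        cx, cy = grid.center()
        row, col = grid.nearest_cell(cx, cy)
        M[row, col] = release.M0 / grid.cell_area
    else:
        M = np.asarray(initial_M, dtype=float)
        if M.shape != grid.shape:
            raise ValueError(f"initial_M shape {M.shape} != grid shape {grid.shape}")

    n_steps = cfg.n_steps
    times = np.empty(n_steps + 1)
    totals = np.empty(n_steps + 1)
    times[0] = 0.0
    totals[0] = M.sum() * grid.cell_area
    snapshots: dict[float, FieldSet] = {}
    snap_steps = {int(round(ts / cfg.dt)): float(ts) for ts in cfg.snapshot_times}

    zero = grid.zeros()
    v = M.ravel()
    for nstep in range(1, n_steps + 1):
        v = solve(B_expl.dot(v))
        times[nstep] = nstep * cfg.dt
        totals[nstep] = v.sum() * grid.cell_area
        if nstep in snap_steps:
            Mf = v.reshape(grid.shape).copy()
            snapshots[snap_steps[nstep]] = FieldSet(grid, Mf, zero.copy(), zero.copy())

    Mfinal = v.reshape(grid.shape)
    final = FieldSet(grid, np.maximum(Mfinal, 0.0), zero.copy(), zero.copy())
    zeros = np.zeros_like(totals)
    return SimulationResult(
        times=times,
        total_M=totals,
        total_E=zeros,
        total_A=zeros,
        final=final,
        snapshots=snapshots,
    )


def annulus_sums(
    field_M: np.ndarray,
    grid: Grid,
    annuli: AnnulusData,
    alpha: float = 1.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Ring-integrated counts: alpha * sum of field * cell area per annulus.

    Each cell belongs to the ring containing its center (distance measured
    from ``center``, default the domain center).
    """
    field_M = np.asarray(field_M, dtype=float)
    if field_M.shape != grid.shape:
        raise ValueError(f"field shape {field_M.shape} != grid shape {grid.shape}")
    if center is None:
        center = grid.center()
    X, Y = grid.cell_centers()
    rr = np.hypot(X - center[0], Y - center[1])
    out = np.empty(annuli.n_rings)
    for i, (ri, ro) in enumerate(zip(annuli.inner, annuli.outer)):
        mask = (rr >= ri) & (rr < ro)
        out[i] = field_M[mask].sum() * grid.cell_area
    return alpha * out
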