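# Methods

## Model and assumptions

`aedesdyn` models the urban population of *Aedes aegypti* females with three
coupled compartments: mobile females M (the only dispersing stage, modelled
as diffusion because adult flight at the neighbourhood scale is an erratic,
essentially unbiased walk), eggs E (immobile, zero mortality — eggs resist
desiccation for hundreds of days, far beyond the simulated horizons), and a
merged aquatic stage A (larvae + pupae) subject to a logistic
carrying-capacity limitation from larval competition.  Egg carrying capacity
is omitted because of skip oviposition: one clutch is distributed across
many sites, so no single site saturates with eggs.  Males, wind advection,
temperature and rainfall dependence, and epidemiological (SIR) coupling are
all out of scope; parameters are constant in time and piecewise constant in
space.

Integrated over any region with no population flux across its boundary, the
PDE system reduces to the well-mixed ODE system, whose threshold quantity is
the basic offspring number Q0 = r·γ/(μ1·(γ+μ2)).  The coexistence
equilibrium for Q0 > 1 scales every compartment by k(1 − 1/Q0); all three
expressions invert for k given a measured density of any one stage, which is
how an otherwise unmeasurable parameter is anchored to field surveys.

## Parameters

| symbol | meaning | unit | default | origin |
|---|---|---|---|---|
| D | female diffusion coefficient | m²/day | 18969 | fitted to ring counts (GA); cross-checked at 16997 by the containment recipe |
| γ | maturation rate (females) | 1/day | 0.0625 | 8-day larva→adult development, 50% female |
| μ1ᵇ | mobile base mortality | 1/day | 0.1177 | fitted to ring counts (≈ the literature's ~10%/day adult loss) |
| μ1ⁱ | insecticide increment | 1/day | 48 (weekly) | inverse of the 30-min airborne residence time; scaled with period for equal dose |
| μ2 | aquatic mortality | 1/day | 0.025 | larval laboratory estimate |
| r | oviposition rate | eggs/day | 34 | 75.01 eggs/day × 5 laying days / 11-day lifespan |
| e | hatching rate | 1/day | 0.24 | ideal-humidity laboratory mean |
| k | aquatic carrying capacity | 1/m² | 0.059 | anchored to an adult survey (~0.025 females/m²) |

The four standard spray schedules (daily 6.86, twice-weekly 24, weekly 48,
biweekly 96, all per day for 30 minutes) deposit the same total dose over
any 14-day horizon; 6.86 is the conventional rounding of 48/7 and an
`exact_dose` switch restores the exact value.

## Dispersal kernel and the two D-estimation conventions

A point release with constant mortality has the free-space solution
M = M0/(4πDt)·exp(−(x²+y²)/(4Dt) − μt); disc and annulus masses use the
closed-form polar antiderivative (quadrature is kept only as a test oracle).
The containment recipe inverts "a fraction c of the release lies within
radius R at time t" for D.  The default convention treats σ = √(2Dt) as a
one-dimensional normal width and uses the two-sided quantile z (z = 1.6449
for 90%; a `rounded_z` flag uses the conventional rounded 1.64, which
yields exactly 16997 m²/day for R = 800 m, t = 7 d).  Strictly, the radial
mass of the two-dimensional kernel is 1 − exp(−R²/(2σ²)), and a `radial2d`
convention exposes that alternative (it gives D ≈ 9927 for the same inputs);
the one-dimensional convention is the default because it is the established
recipe this toolkit replicates.  The elapsed time defaults to 7 days even
though the field experiment read traps on days 3 and 6; t is an explicit
argument everywhere.

## Finite-volume scheme

Uniform square cells, cell-centered unknowns, conservative two-point fluxes.
Face diffusivity is the harmonic mean of the adjacent cells — exact for the
piecewise-constant street/house fields and conservative across the jumps
(an arithmetic-mean switch exists for comparison).  The operator is
symmetric with zero row and column sums, so pure diffusion conserves total
mass to solver roundoff (≲1e-13 relative).  Outer boundaries are zero-flux,
consistent with the closed-region equilibrium argument; for dispersal
replication the domain is sized so the boundary is immaterial (the run is
rejected unless the analytic kernel leaves < `boundary_mass_tol`, default
1e-3, of the surviving mass beyond the largest inscribed disc).

Time stepping is Crank–Nicolson with dt ≤ 30 min.  The linear dispersal
equation needs one pre-factorized sparse solve (SuperLU) per step.  For the
full model the source terms are closed by damped-free Picard sweeps: solve
the implicit M system (with μ1 folded into the matrix; one factorization per
spray on/off state), then update E and A pointwise, iterating to a relative
tolerance of 1e-10; at field magnitudes this converges in ≤ 3 sweeps (≤ 5 is
regression-tested).  Insecticide pulses switch the increment on spray-mask
cells; window and period must be integer multiples of dt so every step lies
wholly inside or outside a pulse (enforced, since a 30-minute window equals
one default step).

The continuous system keeps M, E ≥ 0 and 0 ≤ A ≤ k, but the trapezoidal
rule is not unconditionally monotone: the A-update cannot overshoot k only
when dt·e·E/(2k) < 1, and rough (non-smooth) M data can ring below zero
when dt·2D/dx² ≫ 1.  At the bundled magnitudes (e = 0.24, E ≲ 4.4,
k = 0.059, dt = 1/48) the first condition holds with a factor-3 margin, and
simulated fields are smooth on the scale of dx, so excursions stay at
tolerance level.  A final guard clips to the box after convergence, records
the largest pre-clip excursion in the result diagnostics, and logs if it
ever exceeds 100× the nonlinear tolerance.  A Dirac release is discretized
as M0/dx² in one cell (mass-exact); its early-time ringing decays and is
irrelevant by day 7 when σ ≈ 515 m ≫ dx.  With smooth initial data the
scheme shows clean second-order L1 convergence to the analytic kernel
(observed orders ≈ 2.0 over dx = 100 → 25 m).

## Genetic-algorithm fit

(D, μ, α) are fitted to the five ring counts by minimizing
Σ((Rᵢ−Eᵢ)wᵢ)² with weights (1, 1, 5, 10, 10) emphasising the outer rings.
Search space: [0, 30000] × [0, 1] × [0, 0.1].  Population 50, up to 200
generations with early stop after 30 stagnant ones (population and
generation counts are this package's choice; the search space is tiny and
the objective closed-form).  Selection is best-of-4 tournament; crossover is
the component-wise parent mean; mutation is a truncated-normal perturbation
whose scale decays geometrically over generations — a transparent stand-in
for toolbox-style "adaptive feasible" mutation, kept bounds-respecting by
construction.  One elite individual guarantees a non-increasing best
objective.  All randomness flows from one seed; the repeat protocol derives
per-repeat seeds from it and reports mean, SD and SD% per parameter
(default 10 repeats; the source experiment reports both 10- and 100-fold
figures, so the count is a parameter).

**Identifiability.**  With observations at a single elapsed time, μ and α
enter the objective only through α·e^(−μt) — an overall scale on the
D-dependent ring profile.  The error surface therefore has an exactly flat
valley trading μ against α; D and the product are sharply determined
(repeat SDs ~1%), while the individual μ and α values freeze wherever the
optimizer lands on the valley (repeat SDs ~15–25%, matching the spread the
source fit reports).  Recovering μ independently would require counts at two
or more times, or an external estimate of either parameter.

## Synthetic urban scenario

The real street map behind the original study is unpublished, so scenarios
are generated: a periodic lattice of square house blocks (default 50 m)
separated by streets (default 10 m), optionally with 2×2 blocks merged into
central "big blocks", rasterized at dx = 10 m.  The default lattice's street
fraction (0.3056) approximates the 0.3116 implied by the published
street/house/average diffusion triple.  Streets carry the full D, μ1, μ2;
house interiors get half of each (movement corridors and outdoor hazards
both concentrate on streets); γ, r, e, k are uniform.  The spray mask is the
street mask dilated by one cell ring, mimicking aerosol drift into block
edges.  Homogenization replaces each field by its area mean, preserving
domain-average diffusion and mortality.

What the generator does **not** emulate: real block-size and street-width
distributions, dead ends and open spaces, the actual street fraction of any
particular city, and spatial variation of breeding habitat (k).  Passing
tests on this geometry demonstrate the mechanisms — block interiors acting
as refuges and recovery sources, dose-equivalent frequency trade-offs — not
absolute population numbers for any real city; absolute totals scale with
domain area and street fraction.

## Equilibrium over-bound and the frequency comparison

For heterogeneous domains the package evaluates the well-mixed equilibrium
cell by cell and sums — an *upper bound* on the true steady total, because
diffusion moves mosquitoes from favourable block interiors into deadlier
streets.  How loose the bound is depends on the mixing length √(D/μ1)
(≈ 280 m at street values) relative to the block size: on the default
50-m-block scenario mixing is nearly complete, the steady total matches the
equilibrium of the *area-averaged* parameters instead, and the local-sum
bound is ~10% high.  The frequency comparison therefore checks (i) all
pulsed totals stay below the no-insecticide over-bound, (ii) oscillation
amplitude grows with the application period, and (iii) the time-averaged
total approaches the continuous-equivalent steady state (computed by an
actual constant-rate run) monotonically as applications become more
frequent, with daily pulsing within 2% of the continuous limit.  The
continuous-equivalent rate divides the pulse rate by the number of
window-lengths per period (48/336 per day for the weekly schedule).

## Problem sizes and numerical defaults

Dispersal replication runs on a 4 km square at dx = 10 m (400×400 cells),
dt = 1/48 day, 7 days — large enough that < 5.4e-4 of the mass reaches the
inscribed-disc boundary.  The ODE-tracking check integrates a uniform 3×3
domain at dt = 5e-4 day, where the trapezoidal truncation error (~dt²) sits
near 2e-7, comfortably under the 1e-6 assertion; at the operational
dt = 1/48 the same trajectory is accurate to ~3e-4.  The frequency
comparison uses the default 5×5-block scenario (300 m, 30×30 cells) for
250 days, statistics over the final 14 days — long enough that the daily
strategy's window average is stationary to ~1e-10.  Refinement studies use
dx = 100/50/25 m with dt halved alongside.

## Known limitations

- Constant coefficients in time: no seasonality, temperature or rainfall
  response, so only relative comparisons between control strategies are
  meaningful across seasons.
- The trapezoidal scheme requires the documented step conditions for strict
  box preservation with extreme parameters or rough data; the guard clips
  and reports rather than failing.
- The pulsed model treats spraying as an instantaneous mortality increment
  on a fixed mask; no insecticide transport, decay chemistry, or resistance.
- Single-time ring counts cannot separate μ from α (see the GA section);
  fitted μ values inherit the optimizer's spread along the flat valley.
- The well-mixed inversion of k assumes the surveyed region is isolated and
  at equilibrium; surveys during growth or control transients bias k low.
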