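# Methods

## Model representation

A model is a list of reactions, each a rate expression over declared state
and parameter symbols plus a stoichiometry map; the right-hand side of
dx/dt = f(x, k, t) is the stoichiometry-weighted sum of rates.  Rate
expressions are parsed with sympy; the `mm(vmax, km, s)` primitive expands to
vmax·s/(km + s), and a negative value bound to a Michaelis constant is
rejected at build time.  Jacobians ∂f/∂x (n×n) and ∂f/∂k (n×m) are derived
symbolically and lambdified; if symbolic differentiation fails (e.g. a
non-smooth rate), the model falls back to central differences with step
max(1e-7, 1e-7·|value|) and is flagged `jacobian_mode = "numeric"`.

Kinetic parameters and initial conditions are treated uniformly through the
augmented vector p = [k_1..k_m, x_1(t0)..x_n(t0)] (declaration order).  This
ordering fixes the column order of every sensitivity array; initial-condition
columns are labelled `<state>_0`.

## Integration

`scipy.integrate.solve_ivp` with LSODA by default (stiffness-switching;
biochemical case studies span widely separated time scales), rtol 1e-8,
atol 1e-10, both exposed per model config.  The analytic state Jacobian is
passed to the integrator.  Variational systems (PSA: n + n(m+n) equations;
GFM: n² equations per perturbation time) use the same method and tolerances.

## Classical PSA (direct method)

S(t, τ) solves dS/dt = (∂f/∂x)S + [∂f/∂p, 0] from S(τ, τ) = [0^{n×m} I^{n×n}],
integrated together with the states from τ.  Entries at t < τ are exactly
zero (causality), and the initial blocks are written exactly (not to
integrator tolerance) at grid points coinciding with τ.

The independent oracle re-simulates with each augmented parameter stepped by
±δ·p_j from τ onward (initial-condition entries: the state is jumped at τ)
and forms central differences.  Difference quotients divide integrator noise
by the step (~1e-6 here), so the oracle defaults to tighter tolerances
(rtol ≤ 1e-10, atol ≤ 1e-12) than the forward model; with the model's own
tolerances the quotient noise would be of the same order as the 1e-3
agreement bound the cross-checks use.

Normalization: S̄ = (p_j / x_i(t)) S.  Entries with |x_i(t)| below
1e-12·max_t|x_i| are marked NaN ("undefined") rather than allowed to diverge
— states that start at exactly zero are common in stimulus–response models.
Columns with p_j = 0 are exactly zero wherever defined; undefined wins over
the zero-parameter rule where both apply (0/0 has no meaningful value).

Consolidated metrics over a time course, per parameter, NaN samples skipped:

- `inf`: max_t |S̄| (infinite norm);
- `fim`: sqrt(Σ_t S̄²) — the square root of the diagonal of S̄ᵀS̄, i.e. the
  per-parameter Fisher-information content under unit output noise.  The
  published formulations of this metric vary; the diagonal form is used here
  and stated as such;
- `int`: trapezoidal ∫|S̄| dt.  The absolute value is deliberate: a signed
  integral would let positive and negative excursions cancel and hide a
  parameter that matters twice with opposite sign;
- `at_time`: |S̄(t*)| with linear interpolation, since an externally chosen
  t* (typically a switching time) rarely lands on a grid point.

Rankings sort descending with ties broken by declaration order (stable sort),
so output is deterministic.  An all-undefined column scores 0 and is flagged
with a warning rather than dropped, keeping the ranking a permutation of all
parameters.

## Green's function matrix and impulse sensitivities

For each perturbation time τ the n² variational equations
dS^x/dt = (∂f/∂x)(x(t)) S^x are integrated from S^x(τ, τ) = I.  The Jacobian
is evaluated on a cubic Hermite interpolant of the stored nominal trajectory
(knot slopes from the rhs, so no state re-integration); forward per-τ
integration was chosen over an adjoint formulation because the target models
are desk-scale (n ≤ ~50) and the O(n²·|τ-grid|) cost is negligible there.
Two-time arrays are stored dense with NaN above the t = τ diagonal; a
warning fires above 10⁷ entries.

Impulse sensitivities: iS(t, τ) = S^x(t, τ)·(∂f/∂p)(x(τ)), so
iS(τ, τ) = ∂f/∂p exactly.  Initial-condition columns are defined only at
τ = t0, where they equal the corresponding GFM columns — an impulse on an
initial condition at a later τ is simply a state perturbation, already
described by the GFM.  Normalization mirrors the PSA rule, scaling by
p_j / x_i(t) with the state taken at the *observation* time (chosen by
symmetry with the PSA normalization).  Default observation time for
τ-profiles and rankings is the end of the simulation window.

The finite-pulse oracle raises p_j by (δp_rel·p_j)/Δτ on [τ, τ+Δτ], restores
it, and divides the trajectory change by δp_rel·p_j.  Its discrepancy from
the impulse limit is first order in Δτ; the convergence-order check uses a
model whose impulse response varies with τ, because for decoupled linear
decay the pulse-width error vanishes identically and only the δp floor
remains.

Superposition check: S(t, τ) − ∫_τ^t iS(t, σ) dσ is evaluated by trapezoidal
quadrature over a σ-grid (default 201 points; the quadrature interval is
closed at σ = t where iS = ∂f/∂p), at a small set of observation times, and
reported as a max residual relative to max|S|.  The residual is quadrature-
dominated and shrinks as the σ-grid refines.

## Switching time

Operationalized as the time of maximum first derivative of the chosen state:
central differences on the trajectory grid, argmax (ties to the earliest
time), refined by the vertex of a quadratic through the three bracketing
samples and clamped to that bracket.  A trajectory whose derivative never
exceeds 1e-9·max(1, max|x|) raises a no-switch error.  Maximum slope was
chosen over alternatives (half-maximum crossing, threshold time) because it
is parameter-free and well defined for any sigmoid.

## Fixture models and what they do (and do not) show

- `linear_decay`, `linear_2state` (closed_form): decoupled linear systems
  with exact formulas for the solution, the PSA field ((t−τ)·x_i(t) for the
  diagonal rate, e^{a(t−τ)} for the state block), the GFM (matrix
  exponential) and the impulse field (e^{a(t−τ)}·x_i(τ)).  These anchor every
  computation to closed forms at 1e-5.
- `random_mm(seed, n_states)` (synthetic): seeded sparse conversion networks
  mixing mass action, Michaelis–Menten and enzyme-modulated MM rates.
  Because reactions only interconvert species, total mass is conserved and
  trajectories on [0, 10] stay bounded; rate constants are drawn in
  [0.1, 10] (Michaelis constants and concentrations likewise), and halved up
  to ten times if the integrator fails.  Same seed, same model (sha256
  config hash).
- `simple_switch_network` (published_structure): six states, four reactions,
  one mass-action step and three MM steps; a direct and an indirect route
  activate x6 from a finite pool, producing a sigmoidal switch at ≈ 7 time
  units under a unit stimulus.  The rate constants are *stand-ins* selected
  so that the qualitative phenotype holds: the direct-route knock-out delays
  the switch (+2.3 time units), the indirect-route knock-out roughly halves
  the peak slope, consolidated PSA metrics rank the stimulus conversion and
  the direct route above the indirect one, and impulse profiles hand
  dominance from kf1 to the indirect route near the switch.  They are not
  measured values, and quantitative outputs on this fixture (e.g. the 6.98
  switching time) characterize the stand-in parameterization only.
- `apoptosis_skeleton` (supplement_required): the Fas-induced cell-death
  reaction schema of Jurkat T cells — receptor module, direct (type-I)
  caspase-8 → caspase-3 cleavage, Bid/Bax mitochondrial module, apoptosome,
  and mitochondria-dependent (type-II) caspase-3 activation, with FasL as the
  stimulus initial condition.  All 21 rate constants ship as null: the loader
  demands a complete table and lists every gap, so nothing in the package
  pretends to know the published constants.  Tests exercise the loader with
  clearly-labelled synthetic tables for structural checks only.

What passing tests show: the numerics (direct method, GFM, impulse algebra,
quadrature, rankings) are correct against independent oracles, and the
switch-network story is internally consistent.  What they do not show:
agreement with any measured biological data, or behaviour of the apoptosis
model under its published constants.

## Numerical choices and edge cases

- Grids must be strictly increasing; τ must lie inside the grid/trajectory
  span; mismatched grids raise rather than interpolate silently.
- FD fallback steps, normalization floor, memory guard: see above.
- Zero-height pulses return an exactly-zero field; zero-valued kinetic
  parameters yield zero relative sensitivities (no perturbation to scale by).
- Heat-map CSVs write repr-precision floats so a round trip
  (`pandas.read_csv(..., float_precision="round_trip")`) is bit-exact; the
  upper triangle t < τ is written as NA.
- CLI runs are deterministic: manifests record sha256 checksums and reruns
  reproduce them bit-for-bit.

## Problem sizes

Default analysis sizes — 301-point trajectories, 61-point τ-grids for
profiles, 201-point quadrature for the superposition residual, random
networks of 4–10 states — keep every documented analysis in the seconds
range on a single core while leaving the quadrature and discretization
errors one to two orders below the acceptance bounds used in the tests.
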