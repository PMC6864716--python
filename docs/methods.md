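# Methods

## Model and assumptions

All three experiments are modelled as one-dimensional Fickian diffusion of
a dilute drug in a gel slab of length `L`, with a constant, concentration-
independent diffusion coefficient `D` (m²/s) and concentrations in mg/L.
The slab axis convention is fixed once: `x = 0` is the face in contact with
the bath/sink, `x = L` the sealed end. (For a gel in a cuvette the choice
of which physical end is "top" is immaterial to the mathematics; the
package documents and uses this one convention throughout.)

Assumptions inherited from the experimental setup:

- the bath is large enough that its concentration `n0` is constant during
  inward loading (Dirichlet boundary), and the sink is refreshed often
  enough to stay at zero during outward release;
- the gel does not shrink or swell, and `D` is spatially uniform;
- measured "positions" are treated as point samples of `c(x, t)`, not
  optical-path averages over a finite segment;
- adsorption to the gel skeleton, when present, is at instantaneous
  equilibrium (see the generator section below) — no kinetic sorption
  model is attempted.

## Forward solutions

Inward and outward scenarios use the half-cosine Fourier series (501 terms
by default, indices n = 0…500); terms whose exponential damping factor is
below `tail_cutoff = 1e-15` are dropped, which changes nothing numerically
but speeds up late-time evaluation. Two numerical guards:

- `t = 0` returns the analytic initial condition instead of the truncated
  series, which would otherwise exhibit Gibbs oscillations of order
  `1/n_terms` at interior points;
- outputs are clamped to the physical range (`[0, n0]` or `[0, C0]`);
  clamping is logged at debug level and only ever trims sub-`1e-12`
  truncation negatives.

The mean inward load `(1/L)∫c dx`, the quantity the soak-time design
inverts, is computed by term-wise integration of the series. Below a
dimensionless time `Dt/L² = 1e-5` the truncated coefficient sum floors at
about `2/(π²·n_terms)` instead of vanishing, so the implementation switches
to the semi-infinite-medium mean `(2/L)·√(Dt/π)·n0`, which is exact there
to `O(exp(−L²/4Dt))`; the two branches agree to 13 significant digits at
the switch point.

A semi-infinite-medium closed form `n0·erfc(x/(2√(Dt)))` is provided as an
independent test oracle for short times (`Dt/L² < 0.1`; a warning is issued
beyond that) and is never used in production paths.

## Numerical solver

The sealed-gel (internal) scenario and all cross-checks use Crank–Nicolson
finite differences on a uniform grid: second-order in space and time,
unconditionally stable, with zero-flux boundaries implemented by mirror
ghost nodes (second-order) and Dirichlet nodes pinned exactly. Defaults:
200 cells and a time step capped so the diffusion number `D·Δt/Δx² ≤ 2` —
stability does not require this, but it keeps temporal error commensurate
with spatial error. The solver substeps between requested output times so
each is hit exactly, and aborts with a diagnostic on non-finite values.
With sealed ends the trapezoidal mass integral is conserved to round-off,
and the tests verify ~2nd-order convergence against the series solution.

Initial profiles supplied as measured knots are interpolated with a
monotone shape-preserving cubic (PCHIP) and extended as constants to
`x = 0` and `x = L`, which enforces the zero end-slopes required for
compatibility with sealed boundaries. An initial profile that contradicts
a Dirichlet boundary value is accepted (the boundary wins from the first
step) but logged as a compatibility warning, since the inward-loading
initial condition is exactly such a discontinuity.

## Estimation

The estimator minimises the unweighted sum of squared residuals (the data
give no basis for weighting) over the free parameters:

- `D` only: bounded scalar minimisation on `log₁₀D ∈ [−13, −7]`, a range
  generously bracketing small-molecule diffusion in liquids and gels. The
  objective is unimodal in practice; the search is deterministic.
- `D` plus `n0` or `C0`: Nelder–Mead refinement initialised from the
  D-only fit and the known/maximal concentration — the standard diagnostic
  for an interface effect depressing the effective boundary concentration.

`R²` is the coefficient of determination about the mean of the measured
values. Residuals are reported as measured − fitted, so data lying above
the fitted surface give positive residuals. Internal-scenario fits
recompute the Crank–Nicolson solution per candidate `D` on a fixed grid
(fixing the grid keeps the objective smooth in `D`).

Identifiability guards reject datasets with a single distinct time or a
single distinct position (subset fits, which legitimately restrict to two
positions, only require that time and position are not both singletons).

### Apparent D and adsorption coupling

The optical measurement cannot distinguish drug dissolved in the pore
liquid from drug adsorbed on the skeleton, so what the fit returns is an
*apparent* coefficient. When data are generated with the Langmuir coupling
(below), the fit must be run against the apparent gel-side equilibrium
concentration — `c_app(n0)`, or equivalently with `n0` freed — because
that is what an experimenter calibrating against a saturated gel would
observe. Done this way, the two classic signatures reproduce: the
low-concentration position subset (D, E) yields a larger apparent `D` than
the high-concentration subset (A, B), and the pure-diffusion fit leaves
positive residuals at the far, low-concentration positions. Fitting the
coupled signal against the bath `n0` instead inverts both signatures,
because the apparent signal saturates above `n0` and the near-face data
then sit above any admissible model curve.

## Loading-protocol design

Soak time `t1` solves `mean(t1) = c0` by Brent root-finding on the strictly
increasing series mean (relative tolerance 1e-9, bracket found by
doubling); infeasible targets `c0 ≥ n0` raise immediately. The dimensionless
product `t1·D/L²` depends only on `c0/n0` (≈ 0.197 at half-filling), which
the tests verify across geometries against a Crank–Nicolson time-scan
oracle.

Homogenization time `t2` is found by marching the soak-end profile (passed
analytically, not re-simulated, to avoid compounding discretization error)
under sealed boundaries and taking the first step at which the spread
max−min drops below `eps`; the spread is non-increasing, so this is
well-defined, and the march is re-run with a finer step until the step is
below 0.5% of `t2`. `eps` is interpreted in absolute concentration units
(mg/L). The single-cosine-mode closed form
`t2 = (L²/π²D)·ln(2A/eps)` serves as the test oracle.

## Synthetic-data generator

The generator emulates the cuvette experiments: five sampling positions at
3.5, 7.0, 10.5, 14.0, 17.5 mm (labels A–E from the open face; the
experimental protocol's position list has five entries, which the package
follows), daily readings for seven days, additive homoscedastic Gaussian
noise (seeded `numpy` Generator, clamped at zero), and optionally the
equilibrium Langmuir term

    c_app = c_free + φ · q_max · K · c_free / (1 + K · c_free)

with defaults-by-example `q_max = 2 mg/L`, `K = 1 L/mg`, `φ = 1` in the
tests. Ground-truth parameters are stored in the dataset metadata (and the
CSV sidecar) so recovery can be asserted downstream.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: heteroscedastic or non-Gaussian measurement
error, finite optical-path averaging, kinetic (non-equilibrium) sorption,
gel shrinkage, interface resistance (beyond what freeing `n0` captures),
and any concentration dependence of `D` itself.

## Problem sizes and tolerances

The reference recoveries use the 5-position × 7-day grid (35 observations).
Internal-scenario reference data are generated on a 400-cell grid with
diffusion number ≤ 0.5 and refit on the 200-cell default, so the reported
recovery error reflects genuine discretization mismatch rather than a
shared-grid identity; observed error is ~2e-5 relative, against a 2%
discretization tolerance. Series↔solver cross-checks are asserted at
`1e-3·n0` over `Dt/L² ∈ {0.01, 0.1, 1}`; sealed-end mass conservation at
1e-6 relative; equilibrium limits at the analytic decay envelope of the
slowest mode, `(2/π)e^{−π²τ/4}`.

## Known limitations

- One-dimensional, constant-D, linear diffusion only; no 2D/3D geometry,
  concentration-dependent D, or time-varying bath concentration.
- The TG loading-fraction arithmetic exposes two conventions
  (`difference` and `blank_corrected`) because typical published loading
  percentages are not exactly reproduced by either; reports print both.
- Percentage residuals are computed from the table's own measured and
  residual columns; third-party tables rounded from unrounded intermediates
  may differ in the last digit.
- No uncertainty quantification beyond `R²` (no bootstrap/Bayesian CIs).
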