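# slabdiff

One-dimensional Fickian diffusion analysis for drug transport in gel
monoliths (silica alcogels and similar carriers): forward solutions of the
diffusion equation for the three cuvette experiment geometries, least-squares
estimation of apparent diffusion coefficients from time- and
position-resolved concentration data, adsorption-coupling diagnostics, and a
two-step drug-loading protocol designer.

## Who this is for

Formulation and drug-delivery researchers who measure in-gel drug
concentrations optically (Beer–Lambert, blank-corrected) at a handful of
positions over days, and want to (a) turn those readings into an apparent
diffusion coefficient `D`, (b) check whether adsorption to the gel skeleton
is biasing it, and (c) design soak/equilibration schedules that hit a target
drug load at a prescribed uniformity.

## The model

The gel occupies `0 ≤ x ≤ L`, with `x = 0` the open face touching the bath
and `x = L` sealed. Concentration `c(x, t)` (mg/L) obeys Fick's second law

    ∂c/∂t = D ∂²c/∂x²

with three scenario-specific boundary/initial conditions:

| scenario  | left boundary (x = 0) | right (x = L) | initial condition |
|-----------|----------------------|---------------|-------------------|
| inward    | `c = n0` (bath)      | `∂c/∂x = 0`   | `c = 0`           |
| outward   | `c = 0` (sink)       | `∂c/∂x = 0`   | `c = C0`          |
| internal  | `∂c/∂x = 0`          | `∂c/∂x = 0`   | `c = F(x)`        |

The inward solution is the half-cosine Fourier series

    c(x,t) = n0 [ 1 − Σₙ 2/((n+½)π) · exp(−((n+½)π/L)² D t) · sin((n+½)πx/L) ]

(n = 0…500 by default); the outward series is its exact complement. The
internal scenario, whose initial profile is arbitrary, is solved by
Crank–Nicolson finite differences with mirror-ghost Neumann nodes. The
estimator minimises Σ(measured − model)² over `D` (deterministically:
bounded search on log₁₀D, Nelder–Mead refinement when `n0`/`C0` is freed)
and reports `R² = 1 − SS_res/SS_tot`.

The synthetic-data generator reproduces the cuvette sampling layout (five
optical windows A–E at 3.5–17.5 mm, daily reads) and can add seeded Gaussian
noise and an equilibrium Langmuir adsorption term
`c_app = c + φ·q_max·K·c/(1+K·c)`, which biases the apparent signal upward
at low concentration — the mechanism that makes subset fits at low and high
concentration disagree.

## Worked example

Simulate a noisy inward-loading experiment (true `D = 2.93e-10 m²/s`,
bath `n0 = 9.50 mg/L`, `L = 34 mm`, noise sd 0.1 mg/L) and refit it:

```sh
cat > inward.json <<'EOF'
{
  "schema_version": 1,
  "geometry": {"length_mm": 34.0},
  "scenario": {"kind": "inward", "D_m2_s": 2.93e-10, "n0_mg_L": 9.50},
  "synthetic": {"noise_sd_mg_L": 0.1, "seed": 7}
}
EOF
slabdiff simulate-dataset --config inward.json --out inward.csv
slabdiff fit --config inward.json --data inward.csv --out fit.json
```

which prints

```
D = 2.876e-10 m^2/s, R^2 = 0.9985
```

i.e. the estimator recovers the generating coefficient to ~2% under that
noise level, with the fit quality typical of a diffusion-dominated run.
With `"noise_sd_mg_L": 0.0` the recovery is exact to the optimizer
tolerance and `R² = 1`.

Designing a loading protocol — soak a 34 mm gel in a 9.50 mg/L bath until
the mean load reaches 4.75 mg/L, then equilibrate sealed until the
concentration spread falls below 0.05 mg/L:

```sh
slabdiff design --config design.json --out design_report.json
# t1 = 7.762e+05 s (8.98 d), t2 = 1.93e+06 s (22.33 d), spread = 0.05 mg/L
```

The same functionality is available as a library
(`slabdiff.fit_diffusion_coefficient`, `slabdiff.design_protocol`, …); see
`docs/methods.md` for the numerical details and modelling assumptions.

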