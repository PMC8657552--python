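# Methods

## Model and procedure

### LS-SVR core

Least-squares support vector regression replaces the ε-insensitive loss of
standard SVR with a squared loss, so the training problem collapses to one
symmetric positive-definite linear system.  With the RBF Gram matrix
`Ω[i,j] = exp(−‖xᵢ−xⱼ‖²/2σ²)` and `A = Ω + γ⁻¹I`,

```
b = 1ᵀA⁻¹y / (1ᵀA⁻¹1),    α = A⁻¹(y − b·1),    ŷ(x) = Σᵢ αᵢK(x, xᵢ) + b.
```

`A` is positive definite for every γ > 0, so the solve uses a Cholesky
factorization.  Every training point carries a dual coefficient (no
sparsity); the fitted object checks its own KKT residuals
(`(Ω + γ⁻¹I)α + b·1 − y` and `1ᵀα`) to 1e-8 in max-norm.  Larger γ means a
weaker ridge penalty: as γ → ∞ the fit interpolates distinct training
points, which the tests exploit as an oracle (γ = 1e8 drives in-sample MSE
below 1e-6).

No standardization happens inside `fit`; scaling is the pipeline's job.
This keeps the closed form exactly testable against the (m+1)-dimensional
saddle system `[[0, 1ᵀ], [1, A]]·[b; α] = [0; y]` and against
scikit-learn's `KernelRidge` (fit on `y − b` with ridge penalty 1/γ).

### Hyperparameter tuning

`(σ, γ)` are tuned by a random direct search: from `B₀ = (σ₀, γ₀)` propose
`(σ + λσ, γ + λγ)` with uniform random steps, evaluate the in-sample mean
squared error `G`, accept iff `G` does not increase (ties accepted, which
keeps the walk moving on plateaus), stop when `G ≤ ε` or after `N`
proposals.  Two step modes exist:

* `signed` (default): steps uniform on (−1, 1), candidates with a
  non-positive coordinate rejected.  A strictly positive-step walk can
  only ever increase both coordinates from `B₀`, making the search
  one-sided, so the signed variant is the shipped default;
* `literal-positive`: steps uniform on (0, 1).

Defaults: `B₀ = (1, 1)` (sensible on normalized predictors), `ε = 1e-6`,
`N = 500`.  The accepted-`G` sequence is monotone non-increasing in either
mode and the full trace is recorded for audit.  The tuner is benchmarked
against a 20×20 logarithmic grid spanning one decade either side of `B₀`
— the coarse-grid baseline a practitioner would run with the same prior
information — and must land within factor 1.5 of the grid optimum at a
fixed seed.  Note the objective is *training* error: the procedure
optimizes sample fitting, not held-out error, and the evaluation stage
likewise reports in-sample metrics; a holdout split is deliberately out of
the default path.

### SBM-DEA eco-efficiency

The REE predictor is the non-oriented slacks-based measure with
undesirable outputs.  For DMU *o* with inputs `x_o`, desirable outputs
`y_o^g` and undesirable outputs `y_o^b`:

```
ρ_o = min  (1 − (1/m) Σ sᵢ⁻/x_io) / (1 + 1/(s₁+s₂)(Σ s_r^g/y_ro^g + Σ s_r^b/y_ro^b))
s.t.  x_o = Xλ + s⁻,   y_o^g = Y^gλ − s^g,   y_o^b = Y^bλ + s^b,   λ, s ≥ 0.
```

The fractional program is linearized by the Charnes–Cooper transformation
(multiply all variables by t, pin the denominator to 1) and solved with
HiGHS, one LP per DMU.  Constant returns to scale is the default;
variable returns adds `Σλ = t`.  The reference set pools all region-years
(pooled frontier) by default — a per-year frontier is a switch — and
column roles (`input:`, `good:`, `bad:`) are fully configuration-driven
since no canonical input set exists.  Slacks below 1e-9 are treated as
zero for the ρ = 1 / frontier test.  ρ is units-invariant because every
slack is normalized by the DMU's own observed value; the test suite checks
this to 1e-9 and checks the LP against an independent nonlinear solve of
the fractional program (multi-start SLSQP) to 1e-6.

### Evaluation metrics

`MPE = (1/T) Σ (yₜ − ŷₜ)/yₜ` (signed, so over- and under-predictions can
cancel; an absolute variant is a flag), `MSE = (1/T) Σ (yₜ − ŷₜ)²`, and
`SDE = √MSE`.  The SDE definition is pinned by worked examples: residual
series with MSE 0.005300 / 0.004053 / 0.003812 must give SDE 0.072800 /
0.063664 / 0.061742 to four significant figures.

Metrics are computed on the *normalized* outcome scale.  Predictors are
min-max scaled to [0, 1] (fit globally across the panel; z-score is a
switch); the outcome is divided by the maximum of the modelled series
rather than min-max scaled, because min-max would map the smallest
observation to zero and MPE divides by the observed values.  The five
settings are each tuned and fitted independently per region (and for the
national aggregate: outcomes summed, predictors averaged across regions),
with per-task seeds derived deterministically from the run seed.

### Elasticities

For the four-indicator basic model, elasticity of predictor *j* is the
mean relative change of predictions when column *j* is multiplied by
1 + δ (δ = 0.01) one at a time, all other columns fixed.  Perturbation
and prediction happen on the raw predictor/outcome scale: the raw
perturbed rows are re-normalized with the stored scaling state, predicted,
and inverse-transformed before the relative change is taken, so the
reported fractions do not depend on the normalization choice.  The
reduction over the panel rows is the arithmetic mean of per-row relative
changes (mean-of-absolute or last-row-only are alternatives a caller can
compute from the same machinery).  `E_j(0) = 0` identically and
`E_j` is continuous in δ.

## Synthetic data

The generator emulates a ~30-region × 15-year (2002–2016) provincial
panel:

* **Climate** (temperature, humidity, precipitation, sunshine): regional
  mean × (1 + v·AR(1)) with relative amplitude `climate_volatility`
  (default 0.08, AR coefficient 0.3) — visibly noisy series;
* **Controls** (GDPPC, UL, PD, MP, LAD, NHCI) and **REE**: smooth
  regional trends (exponential or linear growth) with ≤1% jitter;
* **Outcomes** (VTH, OWT, NOI): a chosen response surface applied to the
  predictors plus Gaussian noise, floored at a small positive constant.
  The three outcomes share the surface up to fixed positive scale factors
  (1 / 0.6 / 0.25), so they share one set of true elasticities.

Response families: constant, linear, log-linear (the default: controls
carry most of the signal, climate a moderate share, so outcome series are
smoother than climate series, matching the qualitative volatility contrast
the analysis assumes), and smooth-nonlinear (linear + quadratic terms).
The generator returns the analytic elasticity of the noiseless response at
the panel mean (`0.01·x̄ⱼ f′ⱼ(x̄)/f(x̄)`; the mean matches the averaging
used downstream); unused predictors are exactly 0.  The outcomes' smooth
trend component is carried *through* the response by the smoothly growing
controls rather than added outside it — an additive exogenous trend would
break the exactness of the ground-truth elasticities that every recovery
test relies on.

The DEA generator produces three inputs, one desirable and two undesirable
outputs per region-year, with one DMU planted strictly undominated
(verified by brute-force pairwise dominance in the tests).

What the generator does **not** emulate: spatial autocorrelation between
regions, realistic marginal distributions of any specific province,
measurement error in predictors, or structural breaks.  Passing recovery
tests therefore demonstrate internal consistency of the pipeline — that
known sensitivities are recovered under the model's own assumptions — not
fidelity to any real yearbook data.

## Numerical choices

* LS-SVR solve: Cholesky on `A`; singular `A` (duplicate rows with very
  large γ) raises with advice rather than silently regularizing.
* Direct-search candidates that fail to fit are rejected with a warning;
  the walk continues.
* SBM LP: HiGHS defaults; score clipped to ≤1 against round-off; slack
  tolerance 1e-9.
* MPE raises on any zero observation, naming the index; the generator's
  positive floor (1e-3) guarantees this cannot trigger on synthetic data.
* Zero-range (or zero-sd) columns normalize to 0 with a warning.
* Determinism: every stochastic component consumes a
  `numpy.random.Generator` seeded from the task seed; per-(outcome,
  setting, region) seeds derive from the run seed via CRC32-hashed
  `SeedSequence` entropy, so runs are reproducible byte for byte and
  independent of execution order.

## Problem sizes

Default study conditions are 30 regions × 15 years.  The full pipeline
(five settings × three outcomes × 30 regions, plus national and
per-region elasticity models, each with a 500-iteration search) runs in
about half a minute on one core; the test suite uses smaller panels
(3–10 regions, 6–15 years) for unit-level checks and the full 30 × 15
bundle for the end-to-end determinism check.

## Known limitations

* The tuner is a local random walk; it is not guaranteed to find the
  global optimum of `G`, only never to regress and to beat a coarse grid
  in practice at the shipped budgets.
* In-sample evaluation rewards interpolation; model comparison between
  settings is meaningful relative to this objective, not as a
  generalization claim.
* One-at-a-time elasticities ignore interactions between predictors; the
  joint-perturbation diagnostic (`perturb` applied to several columns) is
  available but not tabulated.
* With 15 annual observations per region and up to 11 predictors, the
  per-region fits are heavily smoothed; elasticity signs for weakly
  contributing predictors are noisy at this sample size (the recovery
  guarantees in the tests are stated for pooled fits with m ≥ 100).
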