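# Methods

This note documents the models implemented in `nitroplan`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not establish.

## Scope and units

The package models a country of `D` districts (default 64), three cropping
seasons r ∈ {1 spring, 2 summer, 3 winter}, and three land uses per season:
rice (j = 1), non-rice crops (j = 2) and idle cropland (j = 0, the residual
category).  Areas are in acres, nitrogen rates in kg/acre, yields in
kg/acre, money in Taka.  Household urea rates are treated as the nitrogen
input of the yield model; because an elasticity is invariant to a
multiplicative unit change, the estimated ρ applies to nitrogen directly,
and the kg-N-per-kg-urea factor (default 0.46, configurable) only matters
where absolute rates meet prices.

## Step 1: toy nutrient transport

Flow routing is single-direction D8: each pixel drains to its lowest
8-neighbor, with ties broken toward the first neighbor in the fixed E, SE,
S, SW, W, NW, N, NE scan order — chosen for determinism, and implemented as
an argmin over neighbor elevations (no slope-length normalisation, so the
brute-force oracle is a one-line neighbor comparison).  Interior pixels
with no strictly lower neighbor are errors, not something to fill: the
raster generator forbids pits by construction, which keeps the stage free
of a pit-filling algorithm.

A pixel's delivery ratio is the product of (1 − retention) over the
strictly-downstream pixels on its path, stopping at (and excluding) the
first stream pixel; stream pixels deliver fully.  The source pixel's own
retention is *not* applied — removal happens in the cells the load passes
through — which makes the single-intermediate-cell example exact
(retention 0.8 ⇒ ratio 0.2).  This is a deliberate simplification of the
full effective-retention recursion used by production NDR tools: the
downstream consumer is only the district ratio θ, and every property the
optimizer relies on (linearity in load, monotonicity in retention,
θ ∈ [0, 1]) holds for the simple product.  The stream mask is supplied
explicitly rather than derived from a flow-accumulation threshold, which
would add an under-specified parameter.  Subsurface transport is omitted;
the conventional vegetated-buffer constants (200 m retention length, 80%
efficiency) are accepted in configuration but unused.

θ is computed by two-run differencing (with-fertilizer minus natural-only)
per district and season.  Because export is linear in load, the difference
quotient is exactly the fertilizer-attributable ratio and is invariant to
the magnitude of the natural load — both are tested.  Seasonality enters
through season-specific cropland activation masks on the fertilizer load
raster (θ is invariant to uniform load scaling, so *pattern*, not level,
is what makes θ seasonal).  Retention parameters are held constant across
seasons.

## Step 2: land-use share system

The logistic share system is linearised to log-odds against idle and
estimated as one six-equation SUR system (a single system, matching the
single system-weighted R² such models report, rather than three season-wise
pairs).  Implementation choices:

* **Cross-equation restriction.**  The inertia coefficient α_r is shared by
  the two crop equations of a season, imposed by mapping both equations'
  inertia columns to one global parameter in the stacked FGLS system.
* **Iterated FGLS.**  The 6×6 error covariance is estimated from joint-OLS
  residuals with a residual-degrees-of-freedom correction (divisor n − 4,
  four regressors per equation) and iterated to convergence (tolerance
  1e-8 on the covariance, max 100 iterations).  A near-singular covariance
  (few districts, or a noiseless fit) falls back to the pseudo-inverse; an
  exactly noiseless system short-circuits to the (already exact) OLS
  solution.  With identical regressors and no restriction the estimator
  collapses to equation-by-equation OLS — the classical equivalence — which
  is tested against `numpy.linalg.lstsq`.
* **System R².**  McElroy's weighted R², the statistic printed as "system
  weighted R-squared" by the major statistical packages.
* **Zero shares.**  Rows with a zero share are floored at ε = 1e-4 (with
  renormalisation) before the log transform, and the count of floored
  triples is logged.  Dropping such rows would bias seasonal equations
  where idle land is rare.
* **Significance zeroing.**  Price marginal effects use a two-sided 10%
  t-test; only the price coefficients β are ever zeroed — the inertia and
  covariate coefficients, and the yield elasticities of Step 3, are used as
  estimated.

The analytic marginal effects ∂s_rj/∂x_rk = s_rj(1{j=k} − s_rk)β̂_rk are
verified against central finite differences of the logistic system (step
1e-6, relative tolerance 1e-6 with an absolute floor of 1e-9 — the
roundoff floor of a central difference at this step size).

## Step 3: yield model and optimization

**Elasticities.**  asinh(yield) is regressed on asinh(urea), asinh(labor)
and the hybrid/HYV variety shares with district fixed effects absorbed by
within-demeaning, separately per season × crop.  The inverse hyperbolic
sine behaves like the logarithm away from zero but is defined at zero
inputs, so zero-urea and zero-labor households need no ad-hoc treatment.
Regressors that are collinear after demeaning (e.g. a variety share pinned
by the others when no local varieties exist) are dropped with a logged
warning and reported as missing.  Districts contributing fewer than two
households are dropped (logged).

**Calibration.**  δ̂_irj = y_b / N_b^ρ̂ reproduces every baseline yield to
machine precision (tested at 1e-12).  The nitrogen-cost change is
Δc(N) = pᴺN/y(N) − c_b with c_b = pᴺN_b/y_b; it is zero at baseline and
strictly increasing in N for ρ < 1, so the optimizer's trade-off between
revenue and export is well-posed (concave output value, increasing cost).

**The programs.**  Decision variables are scaled to u = N/N_b and
ℓ = L/L̄_i, and the objective and constraints are normalised by their
baseline values, which makes the problems scale-invariant (tested: scaling
all prices by a common factor leaves the optimum unchanged).  Bounds:
N ∈ [0.05·N_b, 2·(district max N_b)] — the Cobb-Douglas form misbehaves as
N → 0, and rates far above the local maximum are agronomically meaningless;
|x| ≤ 25% of the baseline price, respecting the validity range of the
linearised share response.  Solved with multistart SLSQP (baseline start
plus four seeded 10%-jittered starts; analytic gradients; ftol 1e-12).
The baseline point is always retained as a candidate incumbent, so the
reported objective never exceeds the baseline export whenever the baseline
is feasible.  The seasonal-spatial solve can be warm-started from the
seasonal solution (the pipeline does this), which enforces the feasible-set
nesting numerically as well as theoretically.  A solution is accepted only
if an *independent* audit — per-row scalar re-evaluation of every
constraint, sharing no code with the solver — passes at 1e-6 relative
slack, with the objective recomputed to 1e-8 relative agreement.  The
audit, not the solver, is the source of truth.

**Scenarios.**  Seasonal: revenue floor per district; seasonal-spatial: one
national revenue floor; both with the national rice floor and the
seasonal/annual land caps.  The rice food-security constraint is kept in
every scenario as a standing requirement.  Integrated: areas are replaced
by L_irj(x) = L̄_i(s_b + Σ_k ∂s_rj/∂x_rk · x_irk) with the implied shares
kept in [0, 1] by explicit constraints (not post-hoc truncation), and
revenue is priced at p + x + Δc(N) as the model defines — note this keeps
the Δc(N) adjustment even at x = 0, so the degenerate case (all price
effects zero) reduces to a nitrogen-only program under the *cost-adjusted*
revenue price; the test suite verifies that equivalence against an
independently coded reduced program.  When every marginal effect is zero
the price instruments are dropped from the problem entirely: instruments
that cannot move any area could only act on the revenue constraint, which
is not their purpose.

**Verification oracle.**  On tiny instances the solver is checked against
`grid_oracle`: an exhaustive enumeration over the nitrogen rates in which,
at every nitrogen grid point, the areas are solved *exactly* as a linear
program (areas enter the objective and every constraint linearly once N is
fixed).  A pure product grid over (N, L) jointly cannot reach verification
accuracy within any reasonable enumeration budget in 8+ dimensions; the
N-grid-with-exact-inner-LP construction is still an independent oracle (it
shares no code path with the SLSQP solver) and is refined by a beam of the
best few grid points with slowly shrinking windows, so refinement never
worsens the oracle objective.  On 2-district × 2-season instances the
solver agrees with the oracle to within 1%.

## Synthetic data: what it emulates, and what it does not

The generator is the package's definition of the study conditions: 64
districts × 3 seasons, shares drawn from the logistic system at the
documented coefficient values (inertia 2.68–5.15, price effects −0.066 to
0.419, covariate effects as published for such systems), household yields
from the arcsinh-linear yield equation at elasticities 0.045–0.120, about
8 households per district × season × crop cell (≈ 512 per regression), a
5% zero-input fraction, and delivery ratios θ ∈ [0.05, 0.35], bracketing
the seasonal range such transport models report.  The share-equation error
s.d. is 0.60 on the log-odds scale, chosen so the fitted system-weighted R²
falls in the high-0.7s/low-0.8s — the fit quality a national application of
this model class reports.  Two details matter for exactness:

* Noise enters the share model on the linear-predictor (log-odds) scale,
  so the SUR estimator is correctly specified and the noiseless limit is
  exact.
* Household yields are generated on the arcsinh scale — asinh(y) is
  *exactly* linear in the asinh inputs — which is the estimating equation
  itself.  At the magnitudes generated (yields ~1600 kg/acre, urea
  ~100–250 kg/acre) this coincides with the Cobb-Douglas form
  y = δ·Urea^ρ·Labor^b·exp(effects) to O(1/x²), and the raw-scale identity
  is tested at that tolerance.  Generating on the raw log scale instead
  would leave an O(1/x²) specification gap that breaks exact noiseless
  recovery through the asinh regression.

Baseline revenue totals v_b, v_b_i and rice production Y1_b are *computed*
from the generated panel, never drawn, so the baseline allocation is
feasible — and revenue- and land-binding — by construction.  The annual
cropping intensity CI_i is set to the baseline harvested share, so the
annual land constraint binds at baseline.

Not emulated: spatial autocorrelation across districts, real rainfall or
land-cover geography, price endogeneity, household survey weights, and
multi-year dynamics.  Passing tests therefore demonstrate that the
estimators and programs recover a *correctly specified* world at realistic
magnitudes and sample sizes — not that the model is robust to the
misspecifications real data carry.  The lagged ("inertia") shares are drawn
from a Dirichlet favouring cultivated uses; the pre-period's own generating
process is not part of the model.

## Problem sizes and tolerances

Unit and property tests run the estimation stages at the 64-district design
size and the nonlinear programs at 8 districts; the acceptance script uses
16 districts for the three scenario solves and 60 replicates for the
recovery simulations.  These sizes were chosen so the whole validation
cycle runs in minutes while keeping every estimator at its design sample
size where sampling properties are the claim being tested.  Key tolerances:
log-odds round trip 1e-12; noiseless estimator recovery 1e-6; calibration
identity 1e-12 (relative); ±3-SE coverage ≥ 99% over replicates; solver vs
closed form 1e-4; solver vs grid oracle 1%; audit slack 1e-6 relative,
objective recomputation 1e-8 relative.

## Known limitations

* SLSQP provides local optima; multistart plus the baseline incumbent and
  the independent audit guard feasibility and monotone improvement, but no
  global optimality certificate is produced, and on large panels the
  dense-QP cost grows roughly cubically in the district count.
* The revenue definition of the integrated scenario adds Δc(N) to the
  price with a positive sign, as the model defines; economically one could
  argue the nitrogen-cost change should *reduce* the net price.  The
  positive sign is conservative (it penalises nitrogen cuts in the revenue
  constraint) and is kept as defined; the ambiguity is confined to the
  integrated scenario.
* SUR standard errors are classical (no bootstrap); with 64 districts and
  six equations they are mildly optimistic, which the ≥ 99% coverage
  criterion absorbs.
* The toy transport stage is not a substitute for a calibrated watershed
  model: its purpose is to supply district θ with the right structural
  properties, and external θ tables (e.g. from a full NDR run) can be
  supplied to the pipeline instead.
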