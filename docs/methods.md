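# Methods

This note records the model, the numerical choices, and the judgement calls
behind `lbb`, at the level of detail a maintainer or reviewer needs.

## Population and gear model

A cohort grows deterministically along the von Bertalanffy curve and dies at
rate `Z(L) = M + F·S(L)`. Everything is expressed in K-scaled ratios (M/K,
F/K, Z/K): absolute time, K and t0 never enter the fitting pipeline (the
growth curve in age is provided for completeness only). Survival from length
`L1` to `L2` is `((L_inf−L2)/(L_inf−L1))^(Z/K)`; with length-dependent
fishing this becomes the difference equation over bin midpoints given in the
README. Choices:

* **Midpoints, not edges.** The recursion is evaluated at bin midpoints,
  matching the fixed-interval length-frequency format (a midpoint-rule
  discretisation).
* **Seed bin.** The recursion is seeded with N = 1 at the first grid bin
  when simulating and at the first non-empty data bin when fitting; catch
  proportions are invariant to the seed.
* **Gear filter.** The observable composition is `N_L·S_L` renormalised —
  the gear, not the population, generates the data. Bins at or beyond
  `L_inf` get expected number 0.
* **Selectivity.** A single Gaussian (`L_c`, σ), the appropriate shape for
  gillnets. A trawl-type ogive is deliberately not offered: it is untested
  here and the fitted surveys are gillnet surveys.

## Length-frequency construction

Class intervals follow the published step rule on the maximum observed
length (0.3 cm up to 12 cm, 0.5 up to 20, 1.0 up to 35, 2.0 above). Bins
are left-closed/right-open, anchored at `floor(min/Δ)·Δ`, with the top edge
closed so the largest fish is kept; anchoring is otherwise arbitrary and
this convention makes binning deterministic. Months are pooled within a
year. `L_mean` is computed over bins at or above `L_c`; the 95th percentile
uses the weighted empirical CDF with linear interpolation inside a bin
(counts spread uniformly), which is stable on coarse bins. A catch with no
bins at or above `L_c` yields a flagged degenerate indicator set, never a
silent NaN.

## Priors and inference

The five free parameters carry log-normal priors. Default relative (log)
spreads: `L_inf` 0.10, `M/K` 0.15, `F/K` 0.60, `L_c` 0.10, σ 0.60. The M/K
prior median defaults to 1.5, the life-history invariant that supplies the
method's absolute mortality scale. When a width control `alpha` is supplied
with the priors, the σ prior median is taken as `L_c/alpha`; this is an
interpretation (the Gaussian curve itself has no alpha parameter) and is
used only to centre the prior. Without alpha, σ's prior median defaults to
`0.15·L_c`.

`suggest_priors` provides data-driven starting points: `L_inf = L_max/0.95`,
`L_c` at the first modal bin, Z/K from the Beverton–Holt estimator
`(L_inf−L_mean)/(L_mean−L_c)` floored at M/K, `F/K = max(Z/K−M/K, 0.1)`.
**Known limitation:** both heuristics assume knife-edge selection. Under a
gillnet dome, `L_max` underestimates `L_inf` (large fish escape the gear)
and the Beverton–Holt form overestimates Z/K, so externally supplied priors
are first-class and preferred whenever a literature `L_inf` or a per-stock
pre-analysis exists.

The likelihood is multinomial over length classes. Bins below the first
non-empty bin are dropped; interior and trailing zero-count bins inside the
data range are retained — they are informative about the decay. Fitting
requires at least 5 non-empty classes.

Sampling is adaptive random-walk Metropolis in log-parameter space: a
Haario-style proposal (empirical covariance of the burn-in history, scaled
by 2.38/√d with an acceptance-rate-tuned factor targeting ≈ 0.28), adapted
only during burn-in and frozen afterwards so the retained chain is a valid
Markov chain. Defaults: 3 independent chains × 30 000 iterations, 50%
burn-in, thinning 10, all overridable. Per-chain RNGs derive from
`(seed, chain)` so identical inputs give bit-identical posterior summaries.
Convergence is summarised by split-R̂ and effective sample size (arviz); any
R̂ > 1.05 flags the result (`converged = False`, a RuntimeWarning) — it is
returned, never silently accepted or discarded.

### Identifiability

Gillnet dome data identify `L_c` and σ sharply but `L_inf` and `F/K` only
weakly. Two structural degeneracies cause this: (i) as `L_inf → ∞` the
composition degenerates to the bare selectivity curve, which already fits
any dome; (ii) the within-window imprint of F/K on the log-composition is
first-order linear in L, and a linear term is absorbed exactly by a small
shift of the Gaussian peak `L_c`. F/K is therefore informed only by the
curvature of the cumulative fishing imprint near the window edges, where
counts are sparse. Consequently the posterior for `L_inf` and F/M leans on
the prior, and honest use of the method requires an informative `L_inf`
prior (literature or pre-analysis). Recovery experiments follow the
simulation-based-calibration convention: priors centred on the generating
values with the default spreads (`scenario_priors`). Under that protocol,
with n = 3000, `L_inf` and `L_c` recover within a few percent, F/M within
roughly ±25% (its posterior remains wide, typically [0.5, 3] at truth 1.5),
and an unfished stock is recognised (posterior F/M < 0.1).

## Reference points

* `L_opt = L_inf·3/(3+M/K)` and
  `L_c_opt = L_inf(2+3F/M)/((1+F/M)(3+M/K))`; `L_c_opt ≤ L_opt` always,
  with equality in the heavy-fishing limit.
* `E = F/Z = (F/M)/(1+F/M)`; 0.5 is the classical optimal-harvest
  reference.
* **Relative biomass.** `B/B0` is the standing exploited-phase biomass
  (lengths above `L_c`, weight ∝ L^b, b = 3 isometric by default and
  configurable) under current F divided by the same quantity at F = 0.
  The integrand carries the age-per-length Jacobian `1/(L_inf−L)` — fish
  accumulate at lengths where growth slows — and the fishery is treated as
  knife-edge above `L_c`: the Gaussian curve describes what the survey gear
  *sees*, not which fish the fishery can kill. Both sums use the exact
  closed-form survivorship on 200 equal steps of relative length in
  (0, 0.9999], integrated by trapezoid with the exact lower limit `L_c`
  prepended; the result is stable well past 3 significant figures under
  grid doubling and matches independent quadrature. Dropping the Jacobian
  would inflate the MSY proxy from ≈ 0.37 to ≈ 0.52 and contradict
  published B/B0-vs-B/BMSY pairs.
* **BMSY proxy.** `B_MSY/B0` is the relative biomass of the reference state
  F = M with `L_c = L_c_opt(F/M = 1)`; at M/K = 1.5 it evaluates to ≈ 0.367.
  `B/B_MSY = (B/B0)/(B_MSY/B0)`.
* **Yield per recruit.** The classical three-term Beverton–Holt relative
  form with `U = 1−L_c/L_inf`, `E = F/Z`, `m = K/Z`:
  `Y/R′ = E·U^(M/K)·(1 − 3U/(1+m) + 3U²/(1+2m) − U³/(1+3m))`. This is the
  exact closed form of the catch-biomass integral over the survivorship
  curve (knife-edge at `L_c`, W ∝ L³); the numerical integral is kept in
  the test suite as the authoritative oracle and the closed form agrees
  with it to ~1e-10.

## Status classification and advice

B/B_MSY maps to five categories with left-closed boundaries (1.0 is
healthy, 0.8 slightly overfished, and so on) — boundary closure matters
because values rounded to 2 dp can land exactly on a threshold. Flags use
strict inequalities (F/M > 1 overfishing, B/B0 < 0.5 depleted, the two
length ratios < 1) except large-fish presence, where "approaching or
exceeding 0.9" is implemented as ≥ 0.9 (0.88 counts as below). Advice:
reduce catch while `B/B0 < B_MSY/B0`; raise size at first capture while
`L_c < L_c_opt`; both strict.

## Synthetic data

The generator draws multinomial counts from the gear-filtered expected
composition — by construction the data-generating process the fitter
assumes, which is exactly what a recovery experiment needs and exactly what
it limits: passing tests demonstrate correct inference under the model, not
robustness to real-world violations (size-dependent availability,
recruitment pulses, spatial structure, measurement error). Individual
records, when requested, place fish uniformly within their sampled bin.

The multi-mesh mode emulates a nine-panel survey net (default meshes
1.0–14.0 cm): per-mesh Gaussian curves with peak length proportional to
mesh size (factor defaulting to `L_c`/largest mesh), combined by envelope
(max) — two nets fished simultaneously make per-length capture probability
envelope-like — with sum as a configurable alternative. No per-mesh catch
data exist to calibrate this mode; it is a testing device.

The 16-scenario bank mirrors the bundled survey prior table (`L_inf`
10–52 cm, F/M ≈ 0.1–3, n = 169–631 per scenario). Scenario σ uses the
alpha width control where it gives a usable width, floored at 1.5 class
intervals so simulated compositions stay multi-bin — the raw `L_c/alpha`
value would collapse some scenarios into one or two bins, which no real
gillnet catch shows.

Recovery experiments at reduced scale (20 replicates, n = 1000, shortened
chains) are used for the credible-interval coverage check (≥ 80% coverage
for `L_inf` at nominal 95%, a loose bound acknowledging approximation
error); problem sizes were chosen so the full suite and the acceptance
script each run in well under a minute.

## Known limitations

* F/M carries wide posterior uncertainty on gillnet data; point estimates
  inherit prior information (see Identifiability). Trawl-type (ogive)
  data would identify it far better but are out of scope.
* M/K is effectively fixed by its prior, as in all length-based methods of
  this family; a badly wrong M/K median biases every mortality-derived
  quantity.
* The weight exponent b = 3 (isometric) is an assumption; allometric
  exponents can be passed but no length–weight data ship with the package.
* One length-frequency per species-year: no seasonal growth, no
  multi-year dynamics, no hierarchical sharing across species.
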