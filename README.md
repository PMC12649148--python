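# lbb — length-based Bayesian biomass stock assessment

`lbb` estimates the exploitation status of a fish stock from nothing but a
length-frequency sample of the catch. It targets data-poor fisheries —
typically small-scale inland or coastal fisheries where catch-at-age series
and absolute abundance surveys do not exist, but where measuring the body
lengths of a few hundred fish per species and year is feasible. The bundled
example is the 2019/2024 multi-mesh gillnet survey of eight commercial
species in Xingkai Lake, and the synthetic-data generator reproduces that
kind of survey so the whole pipeline is testable against known truth.

## The model

Growth follows the von Bertalanffy curve `L_t = L_inf (1 − e^(−K(t−t0)))`.
Working in length instead of age, mortality enters only through ratios to the
growth coefficient K: the fraction of a cohort surviving from length class
`L_{i−1}` to `L_i` under natural mortality M and length-dependent fishing
mortality `F·S(L)` is

```
N_i = N_{i−1} · ((L_inf − L_i)/(L_inf − L_{i−1}))^(M/K + F/K·S_i)
```

with a Gaussian gillnet selectivity curve `S(L) = exp(−(L−L_c)²/2σ²)` peaking
at the length of maximum selectivity `L_c`. The catch the gear shows us is
`N_i·S_i`, renormalised over length classes; observed bin counts are
multinomial with those probabilities. Five parameters — `L_inf`, `M/K`,
`F/K`, `L_c`, `σ` — carry log-normal priors and are sampled by MCMC
(adaptive random-walk Metropolis, 3 chains × 30 000 iterations by default,
split-R̂/ESS diagnostics via arviz).

From the posterior medians the package derives the standard reference
points: `L_opt = L_inf·3/(3+M/K)` (length of peak cohort biomass),
`L_c_opt = L_inf(2+3F/M)/((1+F/M)(3+M/K))` (yield-maximising length at first
capture), exploitation rate `E = F/Z`, Beverton–Holt relative yield per
recruit `Y/R′`, and relative biomass `B/B0` (standing exploited-phase
biomass with weight ∝ L³, fished vs unfished). `B/B_MSY` uses the proxy
`B_MSY/B0` = relative biomass at `F = M` with `L_c = L_c_opt` (≈ 0.37 at
M/K = 1.5). Status is classified on B/B_MSY: healthy (≥ 1.0), slightly
overfished [0.8, 1.0), overfished [0.5, 0.8), grossly overfished
[0.2, 0.5), collapsed (< 0.2).

## Worked example

Simulate a moderately fished stock (`L_inf` = 30 cm, M/K = 1.5, F/M = 1.5,
`L_c` = 12 cm, σ = 2 cm, n = 3000 fish) and assess it:

```python
from lbb import LBB, default_recovery_scenario, scenario_priors, simulate_catch

cfg = default_recovery_scenario(n_individuals=3000, seed=7)
lf = simulate_catch(cfg)                      # binned at 0.5 cm, 31 classes
est = LBB(priors=scenario_priors(cfg.true_state), seed=11).fit(lf)

est.posterior_.to_frame()    # medians and 95% credible intervals
est.reference_points_        # L_opt, L_c_opt, E, Y/R', B/B0, B/BMSY
est.assessment_.status_label
```

Output (posterior median and 95% CI; generating values in brackets):

```
l_inf     30.096  [25.138, 36.690]   (30.0)
m_over_k   1.492  [ 1.114,  1.996]   (1.5)
f_over_m   1.502  [ 0.546,  3.131]   (1.5)
l_c       12.027  [11.733, 12.475]   (12.0)
sigma      1.994  [ 1.934,  2.075]   (2.0)

L_opt 20.10   L_c_opt 17.42   E 0.601   Y/R' 0.046
B/B0 0.210    BMSY/B0 0.367   B/BMSY 0.572
status: overfished   advice: reduce_catch, increase_size_at_first_capture
```

Read: fishing mortality is 1.5× natural mortality (E = 0.60 against the
F = M optimum of 0.5), the stock stands at 21% of its unexploited biomass —
57% of the MSY level — and fish are first caught at 12 cm although yield
would peak with first capture at 17.4 cm, so the assessment flags
overfishing, depletion and undersized capture.

The same pipeline runs from the shell:

```
lbb simulate --config sim.yaml --out lf.csv --seed 7
lbb assess --lf lf.csv --priors priors.csv --seed 42 --outdir results/
```

producing a prior/input summary, an estimates-and-status table, per-fit
convergence diagnostics, an observed-vs-fitted plot per stock, and a
provenance record; a rerun with the same seed is byte-identical.

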