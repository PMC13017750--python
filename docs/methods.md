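# Methods

## The independence null

For a combination of two regimens evaluated in separate randomized trials —
arm A vs a shared-backbone comparator in trial 1, arm B vs control in
trial 2 — independent drug action predicts the combination's survival as

    S_pred(t) = S_A(t) · S_B(t) / S_0(t)

the survival of the comparator regimen multiplied by the second drug's
relative survival benefit over its own control. This is probabilistic
independence on the survival scale: if the two mechanisms rescue disjoint
subpopulations (or act through non-interacting mechanisms), their benefits
multiply. The model assumes the two trial populations are exchangeable and
that the relative benefit transports across trials; both are untestable from
aggregate data and are the analysis's main scientific caveats.

For exponential arms the formula collapses to an exponential with hazard
λ_A + λ_B − λ_0, which must be positive for the null to define a proper
survival function; the simulator rejects scenarios violating this.

## Preprocessing of digitized curves

Digitized coordinates are time-sorted; duplicate times collapse to their
minimum survival; a (0, 1) origin is anchored (prepended if absent, forced
if present, since S(0) = 1 by definition); values in (1, 1 + 1e-6] clamp
to 1 and anything further outside [0, 1] is rejected rather than rescaled.
Monotone repair is a running minimum, which is idempotent and preserves
every already-valid curve. All curves entering one analysis are linearly
interpolated onto a common uniform grid (default 0.5 months) truncated at
the shortest follow-up among them — never extrapolated. Coordinates are
treated as sampled values of the published step function but combined by
linear interpolation; at 20+ coordinates per curve the difference is below
digitization noise.

The ratio S_B/S_0 is unstable as S_0 → 0, so the analysis grid is hard
truncated at the first point where the control survival falls below
`epsilon` (default 0.01). Raw products above 1 or locally increasing
(possible under digitization noise) are repaired by capping at 1 followed by
a running minimum; the number of adjusted grid points (`clamp_count`) and
the retained extent (`truncation_time`) are part of the prediction object
and of every results JSON.

## IPD reconstruction

Events are placed exactly at the grid points where the curve drops;
censorings are spread deterministically at equal spacing within each
risk-table interval, so the inversion is seed-free and byte-reproducible.
Within an interval the event count at each drop solves the product-limit
recursion d_k = round(n_k (1 − S_k/Ŝ_{k−1})) (round half away from zero)
against the *implied* running estimate Ŝ, which makes rounding
self-correcting; the interval's censoring count is iterated (≤ 50 steps,
with a stall detector) until the implied at-risk count at the next published
time matches the published value. When no nonnegative censoring count can
attain the published value — rounding makes off-by-one cases routine — the
default is to accept the nearest achievable count and record the mismatch in
the dataset's diagnostics (`on_infeasible="error"` turns this into a hard
error). After the last published risk time the tail is walked without
interior censoring and survivors are censored at the end of follow-up; a
supplied total event count is then matched exactly by promoting
end-of-follow-up censorings to events at the final time (or demoting the
latest events), recorded as `tail_event_adjustment`.

The predicted cohort has no published risk table. It borrows the comparator
doublet arm's risk-table times with counts rescaled by S_pred(T)/S_A(T)
(rounded, forced non-increasing) and the comparator's sample size at t = 0 —
the least-assumption choice, flagged in the output metadata so downstream
readers see it.

## Two-cohort comparison

The reconstructed observed and predicted cohorts are compared with the
standard two-group log-rank test and a two-group Cox model. Efron tie
handling is the default because reconstruction places events on a shared
grid, making ties heavy; Breslow is available. The CI and p-value are Wald
on the log-HR scale with z = 1.959964 fixed, so
exp(log HR ± 1.959964·se) reproduces the bounds exactly. A monotone partial
likelihood (one group's events entirely preceding the other's) is reported
as non-estimable rather than as a spuriously huge HR. Classification:
`greater_than_additive` iff the CI lies entirely below 1,
`less_than_additive` iff entirely above, else `consistent_with_additive`.

## The simulator

`SimulationScenario` defaults define the study conditions: monthly hazards
λ_0 = 0.08 (control), λ_A = 0.05, λ_B = 0.04 (doublets), combination hazard
ψ·(λ_A + λ_B − λ_0) with ψ = 1 the additive null; 700 patients/arm;
administrative censoring at 24 months (matched to the control's 8.7-month
median survival — longer follow-up would push the control curve into a
regime the ratio cannot use); exponential loss to follow-up at 0.005/month
(light, trial-like attrition); 6-monthly risk tables; 25 digitized
coordinates per curve, sampled from the arm's exact empirical KM step
function at evenly spaced times plus all risk-table times, with optional
truncated-normal vertical jitter (off by default — digitization error is
typically below KM sampling noise at these arm sizes and grid densities).
Each arm draws from its own stream spawned off the master seed, so arms are
individually reproducible.

What the simulator does not emulate: cross-trial population heterogeneity,
covariate-dependent hazards, non-proportional effects, or digitization bias
(systematic misreading of plateaus). Passing tests therefore demonstrate
algorithmic fidelity — that the chain recovers what the model defines — not
that the independence model transports across real trial populations.

## Operating characteristics: a structural caveat

The predicted curve's cumulative hazard is Λ_A + Λ_B − Λ_0, a *small
difference of three large cumulative hazards* (0.01/month net from
components of 0.04–0.08/month). Each component carries KM (Greenwood)
noise Var(Λ̂(t)) ≈ (e^{λt} − 1)/n, so the prediction's log-hazard noise is
amplified roughly eight-fold relative to the sampling noise of a same-size
cohort: SD ≈ 0.45 at n = 700/arm and ≈ 0.17 at n = 5000/arm at 24 months.
The Cox comparison of the two reconstructed cohorts, however, sees only
within-cohort sampling noise (SE(log HR) ≈ 0.08 at n = 700) and is blind to
the curve-level noise baked into the predicted cohort.

Consequences, measured by this package's own simulation study
(`run_simulation_study`, reported by the acceptance script):

* at the additive null (ψ = 1, n = 700/arm, 200 replicates) the rate of
  non-additive classification is ≈ 0.6, an order of magnitude above the
  nominal 5%, with replicate-level SD(HR) ≈ 0.5–0.9;
* at n = 5000/arm the recovered HR carries a common per-dataset
  multiplicative offset of roughly ±20% across ψ values, so point recovery
  of ψ to ±0.05 at a single seed is not achievable.

This is a property of the methodology — reconstructed-IPD comparisons of a
cross-trial model prediction overstate their own precision — not of this
implementation; borderline synergy calls produced by this workflow (CIs
barely excluding 1) should be read with that inflation in mind. The package
reports the observed rates rather than hiding them.

## Numerical conventions

* Grid step 0.5 months; epsilon floor 0.01 on the control curve; both
  configurable.
* Event-count rounding: half away from zero.
* Censoring placement: equal spacing strictly inside each risk interval.
* Ties: Efron default; both methods validated against brute-force
  partial-likelihood maximization to 1e-6 on small fixtures.
* The KM estimator and log-rank test are delegated to lifelines, the Cox
  partial-likelihood maximization to statsmodels PHReg; both are
  cross-checked in the test suite against independent hand-written oracles.
* Problem sizes in tests and the acceptance script (300-subject round
  trips, 5000/arm recovery runs, 200-replicate calibration at 700/arm) are
  chosen to exercise the asymptotic claims while keeping a full run in the
  tens of seconds.
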