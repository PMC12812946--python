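# Methods

## Model structure

A partitioned survival model (PSM) with three states — progression-free
(PFS), progressed disease (PD), death — and a unidirectional pathway
PFS → PD → death. Unlike a state-transition model, occupancy is not
propagated through transition rates: at every cycle boundary it is read
directly off two marginal survival curves, `pfs = min(S_PFS, S_OS)`,
`dead = 1 − S_OS`, `pd` the remainder. When fitted curves cross (a
finite-sample artifact), PFS is clamped to OS rather than renormalized,
which keeps `dead = 1 − S_OS` exact and the PD share non-negative.

Cycle length is 28 days (the regimen's treatment cycle); months are
365.25/12 days throughout. The lifetime horizon runs until 99% of the
cohort has died, capped at 40 years (the cap nearly never binds and is
flagged on the trace when it does). Costs and QALYs accrue on
half-cycle-averaged occupancy — the average of the two boundary values —
and are discounted at 5%/year with the continuous exponent
`(1+r)^(−t)` evaluated at cycle midpoints. Discounting at midpoints
rather than in annual steps matches the half-cycle convention; the
difference is well under 0.1%.

## Synthetic trial generator

The generator stands in for digitized trial curves. For each endpoint it
draws event times from a two-arm Weibull pair with a **common shape**,
calibrated in closed form so the published summaries hold exactly:

    k = ln(HR) / ln(m_ctl / m_trt),    λ_arm = m_arm / (ln 2)^(1/k)

With a shared shape the hazard ratio `(λ_ctl/λ_trt)^k` is constant in
time, so the pair satisfies both medians *and* the published HR
simultaneously — PFS: medians 15.0/7.3 months, HR 0.43 (k ≈ 1.172);
OS: medians 34/27 months, HR 0.67 (k ≈ 1.737). Observation is truncated
by administrative censoring at 21.4 months (PFS; midpoint of the two
published median follow-ups) and 34.2 months (OS; the extended
follow-up). Default arm size is 162 (phase-III scale, 1:1
randomization); precision-hungry checks use 5,000/arm.

What the generator does **not** emulate: patient-level coupling between
PFS and OS (endpoints are independent marginal datasets — all the PSM
consumes), covariates and subgroups, dropout (censoring is purely
administrative), non-proportional hazards, and digitization click noise.
Passing tests therefore demonstrate correctness of the pipeline under a
clean proportional-hazards Weibull world, not robustness to real-world
curve shapes such as plateaus or delayed separation.

Note one consequence of the OS calibration: true survival at the
34.2-month cut-off is ≈0.497, so in roughly a third of simulated trials
the treated-arm KM curve never quite reaches 0.5 and the sample median
is undefined. Headline recovery checks therefore average medians over a
few replicate simulations, skipping replicates without a defined median.

## Pseudo-IPD reconstruction

The digitized-curve inverter implements the standard interval algorithm:
within each numbers-at-risk interval it iterates on the censoring count
(censor times spread evenly, allocated to click subintervals), chooses
per-click event counts so the recomputed product-limit estimate tracks
the digitized survival values, and stops when the implied number at risk
matches the next table entry. Patients never observed to fail are
censored at the end of follow-up. The procedure is fully deterministic.

Two implementation choices matter. First, censor times are emitted
inside the click subinterval they were allocated to during the solve
(i.e. after that click's events), keeping the emitted records exactly
consistent with the solving walk; spreading them blindly across the
whole interval can misplace a censoring ahead of an event and shift the
recomputed curve by O(1/n). Second, an at-risk mismatch of ±1 after the
censoring-count search is accepted as integer rounding; anything larger
raises an error naming the interval (infeasible curve/table
combinations). With at-risk information at every click time the round
trip is exact; with a realistic coarse risk grid (every 3 months) and
trial-scale n the recomputed curve stays within 0.01 sup-norm. Without
any risk table the inverter falls back to assuming no censoring before
the end of follow-up — a documented degradation, not an error.

## Survival extrapolation

Royston–Parmar flexible parametric models on the proportional-hazards
scale: `ln H(t) = γᵀ b(ln t)` with a restricted cubic spline basis
`b = [1, x, ν₁(x), …]`, natural (linear) beyond the boundary knots —
which is what makes long-horizon extrapolation stable. Interior knots
(0–3) sit at equally spaced centiles of the uncensored log event times,
boundary knots at the min/max log event time. The right-censored log
likelihood

    ℓ(γ) = Σ_events [η + ln(dη/dx) − ln t] − Σ_all exp(η)

is maximized by multi-start BFGS (five starts: a Weibull-MLE-based
initialization plus seeded perturbations of scale 0.1; gradient
analytic; gtol 1e-8). Validity of the hazard is enforced twice: a soft
quadratic penalty (weight 1e4) on negative `dη/dx` during optimization,
and a post-fit check on a 1000-point grid out to 480 months that rejects
any decreasing cumulative hazard. With zero interior knots the model is
exactly Weibull (`k = γ₁`, `λ = exp(−γ₀/γ₁)`), which provides an
independent maximum-likelihood oracle; agreement is within 1e-4 on the
log likelihood in tests.

Model selection minimizes AIC (default) or BIC with `n = events` in the
BIC penalty (survival-model convention); ties break toward fewer
parameters, then lower BIC. Selection is data-driven per arm/endpoint
and the verdict is logged. The candidate set is the spline family
itself; since the 0-knot member *is* the Weibull comparator, separate
standard parametric wrappers were not duplicated.

## Economics

USD per 28-day cycle, healthcare-system perspective, direct medical
costs only. PFS state: the arm's regimen drugs (combination
4065.70 + 419.60 + 646.59; control 419.60 + 646.59) plus routine items
(laboratory 59.89, imaging 152.95, hospitalization 90.71, supportive
care 140.20, follow-up 11.64). PD state, both arms: everolimus 459.28
plus the same routine items (the table gives no state mapping for the
routine items; the symmetric default is configurable). Regimen drugs are
costed for the entire PFS occupancy (treat-to-progression) — the
standard PSM simplification, since time-on-treatment is not modelled
separately. Utilities 0.837 (PFS) and 0.443 (PD); QALYs are
occupancy-weighted, discounted person-time.

Grade ≥3 adverse events with their published unit costs and
disutilities enter as a one-off at model entry: cost Σ incidence·cost,
QALY loss Σ incidence·disutility·duration with duration one cycle
(configurable; a per-cycle cost mode is also exposed because "per
cycle" labelling of AE costs is ambiguous). **Per-arm AE incidences are
not part of the tabulated inputs; the shipped defaults are synthetic
placeholders** of plausible magnitude and must be overridden for
substantive use. Their influence is small: total AE burden is tens of
dollars against five-figure drug costs, and the tornado places AE
parameters last.

The CNY/USD rate (7.1329) is metadata only; all arithmetic is USD.

## Sensitivity and scenario analyses

DSA: every tabulated parameter varies ±20% around base (the discount
rate 0–8%); bars are ordered by |ICER_high − ICER_low| and entries whose
incremental QALYs change sign are flagged and sorted last. Cost
parameters enter ΔC linearly, so their bars are symmetric about the
base ICER — asserted to 1e-6 in tests.

PSA: gamma for costs, beta for utilities/disutilities, with sd =
range/(2·1.96) (ranges read as 95% intervals; the alternative
sd = range/4 convention is a one-line change). Hyper-parameters by
moment matching: gamma `shape=(m/s)², rate=m/s²`; beta by the standard
method of moments with the mean clamped into (0,1) and variance capped
at 99% of the Bernoulli bound. The discount rate keeps its tabulated
beta tag, scaled to [0, 0.08]. Utility draws above 1 are clamped at
evaluation. Survival-curve uncertainty is *not* resampled — the
distributions cover cost/utility/probability inputs only, and traces
stay at their point fits. 10,000 iterations by default; the economic
layer re-runs per draw over cached traces, so the full PSA takes
seconds. CEAC: fraction of draws with positive NMB per WTP value.

Scenarios: (1) price sweep on the novel agent only, per-tablet baseline
= cycle cost / 28 tablets (9 mg once daily, days 1–28) = $145.204;
since ΔE is price-invariant and ΔC affine in price, the ICER is affine
and strictly increasing in price, and the break-even price (ICER = WTP)
is found by bisection on [0, base] to 1e-6 relative tolerance.
(2) Horizon sweep over 5/10/15/20 years and lifetime; note that under
the Weibull calibration the 99%-dead stopping point (~8.4 years) is
shorter than the longer fixed horizons, so "lifetime" here means the
stopping rule, not the longest horizon. (3) Alternative utilities
(e.g. US population values 0.736/0.630) — costs are untouched by
construction. (4) Regional thresholds are plain config numbers
(3× provincial GDP per capita); the model reports NMB and a verdict per
region.

## Reproducibility and problem sizes

A single global seed expands into fixed per-stage child seeds (one per
endpoint, one for the PSA), so toggling stages never perturbs the
synthetic data; artifacts carry the seed and a config-content hash in a
header line. Calibration-recovery checks use 5,000 patients/arm with
medians and hazard ratios averaged over a handful of replicates;
property tests use 162–2,000/arm. The deterministic assembled model
(exact calibrated Weibull survival, no sampling) underlies the
base-case worked example; its ICER (≈$174k/QALY) sits above published
spline-based figures because the Weibull tail is lighter than flexible
spline fits to the real digitized curves — the directional verdict
against the $40,271/QALY threshold is unchanged.

## Known limitations

- Endpoint independence and proportional hazards are baked into the
  generator; violation patterns (cure fractions, crossing hazards)
  are untested.
- Treat-to-progression drug costing ignores dose interruptions and
  time-on-treatment shorter than PFS, overstating drug cost slightly.
- AE incidence defaults are placeholders (see above).
- No post-progression treatment heterogeneity: one representative PD
  regimen for all patients.
- The probabilistic analysis omits structural and survival-parameter
  uncertainty by design; a bootstrap-the-IPD extension would capture
  the latter.
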