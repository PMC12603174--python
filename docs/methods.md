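# Methods

## Model structure

The disease model has four health states: progression-free (PF),
progressed disease without brain metastases (PD w/o BM), progressed
disease with brain metastases (PD w/ BM), and death.  Movement is
one-directional: PF can progress with or without BM or die (TP1, TP2,
TP3); PD w/o BM can acquire BM or die (TP4, TP5); PD w/ BM can only die
(TP6).  No reverse transitions exist, and death is absorbing.

Transition hazards are *clock-reset* (semi-Markov): each pathway's hazard
depends on time since entry into the origin state, not on time since
model start.  In the cohort engine this is realised exactly by duration
expansion (tunnel states): occupancy is tracked per (state, cycles since
state entry).  PF is entered only at model start, so its duration equals
model time and needs no expansion.  Memory cost is quadratic in the cycle
count, which is negligible at 3-week cycles over 15–40 years.

## Survival families and fitting

Six families are supported, parameterised on an unconstrained scale (log
for positive parameters) in the convention used by the dominant
multistate-fitting tools, so published coefficient tables can be
transcribed directly:

| family | parameters | notes |
|---|---|---|
| exponential | log rate | constant hazard |
| Weibull | log shape, log scale | S(t) = exp(−(t/scale)^shape) |
| Gompertz | shape, log rate | H(t) = (rate/shape)(e^{shape·t}−1); shape may be negative (hazard plateau, S(∞) > 0) |
| log-logistic | log shape, log scale | S(t) = 1/(1+(t/scale)^shape) |
| log-normal | μ, log σ | on log-time |
| generalized gamma | μ, log σ, q | q→0 is log-normal, q=1 is Weibull |

Fitting maximises the right-censored log-likelihood
Σ_events log f(t) + Σ_censored log S(t) by BFGS from five deterministic
moment-based starting points; the covariance is the inverse observed
information (central-difference Hessian, symmetrised, eigenvalue-clipped
at zero).  Datasets with fewer events than parameters raise a
degenerate-fit error rather than returning an unstable optimum.  Ranking
uses AIC with BIC, then parameter count, then a fixed family order as tie
breaks.  Visual assessment is supported by a Kaplan–Meier overlay plot
(`plots.plot_survival_fits`) but never enters the selection logic.

## Discrete-time transition probabilities

Within a cycle of length c starting at state duration u, each
cause-specific hazard is treated as piecewise constant.  With
ΔH_k = H_k(u+c) − H_k(u) and ΔH = Σ_k ΔH_k, the total exit probability is
1 − e^{−ΔH}, apportioned to causes proportionally to ΔH_k.  This is exact
for exponential hazards and consistent as c → 0.

Two refinements align the discrete engine with continuous time (they were
required for the simulated-cohort consistency check below to hold at its
stated tolerance):

1. **Mid-cycle entry offset.**  A cohort reaching a PD state during a
   cycle has, at the next boundary, already spent half a cycle there on
   average.  PD duration grids are therefore evaluated at d + 0.5 cycles;
   PF, entered exactly at time zero, uses integer durations.
2. **Entry-step exit risk.**  New entrants face the first half-cycle of
   their new state's exit risk before the boundary (first-order composite
   transitions: PF→PD→death within one cycle).  Without this, deaths
   routed through short PD sojourns are systematically delayed by one
   cycle.

With both corrections the occupancy of a 20,000-patient simulated cohort
and the analytic trace agree to < 0.01 (the residual is Monte-Carlo
noise); without them the systematic gap is ≈ 0.024.

## Rewards

* **PF utility per cycle**: u = u_pre + (u_post − u_pre)·respProp(c) +
  Σ_k aePrev_k(c)·d_k, with u_pre = 0.74, u_post = 0.81 and disutilities
  d = −0.0005 (leukocyte deficiencies), −0.0124 (anemia), −0.0692
  (platelet deficiencies).  The coefficients are estimable from a
  longitudinal panel by linear GEE (identity link, exchangeable working
  correlation by default, patient-clustered sandwich errors).
* **PD utilities**: 0.76 without BM, 0.72 with BM.
* **Costs** (2023 NT$): chemotherapy in the four induction cycles in both
  arms and atezolizumab (NT$83,258/cycle) from cycle 1 until
  discontinuation in the intervention arm, both weighted by the
  on-treatment proportion; expected AE-management cost
  (Σ prevalence × unit cost); non-medication point values multiplied by
  the NHI conversion factor 0.9198; flat per-cycle PD-state costs
  (defaults equal across arms); a one-off terminal supportive-care cost
  charged to the fraction dying each cycle, discounted at that cycle.
* **Discounting**: 3%/year on costs and outcomes.  Half-cycle correction
  (default on, configurable) averages start- and end-of-cycle occupancy
  and discounts at the cycle midpoint.  The horizon is truncated to whole
  cycles (floor(horizon/c)); the residual fraction of a final cycle is
  dropped.

## Time-varying curves

Response proportion, AE prevalence per category and on-treatment
proportion can be supplied analytically or built from event-level IPD:
prevalence is the share of at-risk patients with an active (merged,
grade ≥ 3, category incidence > 2%) episode overlapping the cycle;
on-treatment is the Kaplan–Meier survivor of time to discontinuation with
administrative censoring.  Beyond observed follow-up, response and AE
curves hold their last value; the on-treatment curve drops to 0 after the
last observed risk interval (configurable) — the conservative choice for
an expensive maintenance drug.

## Uncertainty analysis

* **DSA**: one parameter at a time at its low/high bound, two full model
  runs per row; survival coefficients vary within ±1.96 SE (their 95%
  CI), the conversion factor between user-supplied regional min/max
  (default 0.88–0.96), everything else ±25%.  Tornado order is descending
  |INMB range|, with INMB evaluated at the run's own WTP so that varying
  the threshold itself registers.
* **PSA** (5,000 draws by default): beta for utilities and proportions
  (method of moments, SE = 10% of base), gamma for costs (SE = 25% of
  base), negated gamma for disutilities, multivariate normal on the
  unconstrained coefficient scale per transition using the fit
  covariance.  These distribution assignments are conventional CEA
  practice, flagged as assumptions in the run manifest.  Each parameter
  draws from its own substream (SHA-256 of the parameter name combined
  with the master seed), so adding or removing a parameter never shuffles
  the others.
* **CEAC**: P(λ·ΔE − ΔC > 0) along a WTP grid.  **EVPI** (per person):
  E[max_s NMB_s] − max_s E[NMB_s] ≥ 0.
* **Scenarios 1–9**: (1) second-best fit per transition; (2)/(3) the
  most/least favourable of each transition's three lowest-AIC/BIC
  candidates, operationalised as the largest/smallest model survival at
  the analysis horizon and applied per transition and per arm
  independently (slower progression counts as favourable alongside lower
  mortality); (4–7) horizons of 5, 10, 20, 40 years; (8)/(9) both PD
  utilities set to 0.7511 / 0.473.  Scenario application is pure — the
  base model instance is never mutated — and each scenario gets a full
  CEA + DSA/PSA summary.

## Synthetic cohort generator

The generator emulates the restricted trial IPD: 201/202 patients per
arm, ~2 years of administrative follow-up, multistate trajectories drawn
by total-hazard inversion (vectorised bisection of Σ_k H_k(t) = E against
unit-exponential draws) with the exit cause apportioned by cause-specific
hazard ratios at the event time — exact for the model class, with no
latent-failure-time assumption.  Hazard plateaus (negative-shape
Gompertz) simply censor at the administrative cut-off.  Response onset is
log-normal (median ≈ 6 weeks) in ~60%/64% of patients; AE episodes are
Poisson onsets while on treatment with log-normal durations (median ≈ 3
weeks) and categorical grades, so the grade ≥ 3 / incidence > 2% filter
has something to filter; treatment stops at progression, intolerance
(rate 0.3/yr) or — comparator only — the end of induction.  Utility
records add a patient-level random intercept (SD 0.05) and residual noise
(SD 0.08), clipped to the EQ-5D-3L range [−0.594, 1].

The default truth hazards are Weibull/exponential mixes anchored to
ES-SCLC clinical reality (median PFS ≈ 5 months, median OS ≈ 12 months,
intervention arm uniformly slower on pathways into death), chosen once so
that the resulting base case lands in the northeast quadrant of the
cost-effectiveness plane near the WTP threshold — the decision regime the
method is built for.  They are **not** a reconstruction of the
unpublished trial coefficients, and no numeric agreement with a
trial-fitted base case should be expected from them; the shipped set
exercises the machinery under realistic conditions, while the published
decision arithmetic (ICER/INMB identities) is reproduced exactly from its
printed inputs.

What the generator does not emulate: informative censoring, covariate
heterogeneity beyond the random intercept, measurement error in
progression dates, claims-data cost noise.  Passing recovery tests on
this data therefore demonstrates correctness of the estimators under the
stated model, not robustness to those real-data features.

## Numerical choices and test conditions

* Optimiser: BFGS, gradient tolerance 1e-8, five deterministic starts.
* Mass conservation is asserted every cycle at 1e-9; schedules whose rows
  exceed unity raise.
* Problem sizes used by the test suite: simulation/occupancy consistency
  at 20,000 patients over a 6-year window; survival-parameter recovery at
  n = 500 with ~20% administrative censoring; GEE recovery at 400
  patients; PSA stability at 5,000 draws across two master seeds;
  scenario/PSA smoke checks at reduced draw counts.
* Currency is reported as integer NT$ (round-half-even), effects to three
  decimals.

## Known limitations

* PF rewards and transitions assume the whole cohort enters PF at time
  zero (first-line setting); delayed entry would need PF tunnel states.
* AEs affect utilities and costs only; they are not explicit health
  states.
* The discrete entry-step correction is first order: composite paths
  traversing two states within one cycle are approximated, three-state
  composites ignored (error O(c²) at 3-week cycles).
* EVPI is per person; population EVPI and partial EVPI (EVPPI) are out of
  scope.
* Left truncation, covariate-adjusted survival regression, spline and
  cure-fraction models are not supported.
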