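# Methods

## Evidence synthesis

Each trial contributes a comparison-level effect: a hazard ratio (OS, PFS)
with its 95% CI, or severe-adverse-event counts per arm converted to a risk
ratio with log-scale SE √(1/e_a − 1/n_a + 1/e_b − 1/n_b).  CI bounds
back-transform to SEs as (ln high − ln low)/(2·z), z = 1.959964 at the 95%
level (the exact normal quantile, not 1.96).  Zero event cells are rejected
unless the caller explicitly enables a 0.5 continuity correction — evidence
is never altered silently.

The network solution is fixed-effects weighted least squares on the
comparison graph: incidence matrix X, weights w = 1/se², treatment effects
μ = L⁺X′Wy with L = X′WX the weighted Laplacian.  Contrast variances come
from L⁺ (var(μ_a − μ_b) = L⁺_aa + L⁺_bb − 2L⁺_ab).  On a star network this
reduces to inverse-variance pooling per edge followed by subtraction, which
the test suite uses as an independent closed-form oracle.  Heterogeneity:
Q = Σw(y − Xμ)², df = #estimates − #treatments + 1, I² = max(0, (Q − df)/Q),
with I² forced to 0 whenever Q ≤ df + 1e−12 (a saturated network fits
exactly; the epsilon absorbs float rounding in Q).

Fixed effects only: the evidence base is five trials on four edges, far too
sparse to estimate a between-trial variance, and the source evaluation used
a fixed-effects model.  Multi-arm variance decomposition is not implemented;
loading two correlated estimates from one trial raises a warning.

The packaged evidence table (`five_trials_high_pdl1.csv`) holds the
published high-PD-L1 subgroup estimates of KEYNOTE-024, KEYNOTE-042,
CheckMate-026, IMpower110 and MYSTIC.  Subgroup definitions differ slightly
across these trials (TPS ≥ 50%, TC/IC3, TC ≥ 25%), and the MYSTIC PFS
interval is published at a wider-than-95% level but ingested as 95%
(conservative).  Users reproducing a specific evidence base should replace
this file; its format is the module's documented CSV schema.

## Survival model

Weibull curves are parameterised S(t) = exp(−λt^γ) with time in months
(the axis unit of the source KM figures); the single day↔month constant is
365.25/12.  The 21-day model cycle is therefore Δ = 21/30.4375 months.

Hazard ratios adjust the scale only (λ′ = HR·λ, common shape), the unique
choice consistent with a constant proportional hazard on a Weibull —
equivalently S′(t) = S(t)^HR, asserted as a property test.  Per-cycle exit
probabilities p_k = 1 − S((k+1)Δ)/S(kΔ) are computed in log space so the
ratio stays exact deep in the tail.

**Fitting digitized KM coordinates.**  The fitter is linear least squares on
the complementary-log-log linearization ln(−ln S) = ln λ + γ ln t over
points with t > 0 and 0 < S < 1, weighted by (S·ln S)² — the delta-method
inverse variance of the transform under additive digitization noise on S.
Unweighted fitting lets the S → 0 tail dominate (at S = 0.01 a ±0.005
digitization error moves ln(−ln S) enormously) and biases λ̂ by tens of
percent; the weighted fit is still closed-form, deterministic, and exact on
noiseless data.  Points with S = 1 are excluded with a warning, t = 0
silently; fewer than three usable points is an error.  Maximum-likelihood
fitting via lifelines appears in the tests as an independent oracle only.

## Cohort model

Three exclusive states: progression-free (PFD, the initial state of the
whole cohort), progressed disease (PD), death.  Occupancy is the
partitioned-survival construction — PFD_k = S_PFS(kΔ), dead_k = 1 − S_OS(kΔ),
PD_k the difference — because the two published curve parameter pairs fully
determine this structure, whereas an explicit 3×3 transition matrix would
require a progressed-to-death hazard nowhere published.  The implied
per-cycle transition probabilities are exported with every trace for audit.

Curve crossing (S_PFS > S_OS, possible when each endpoint's HR is applied
independently) is clamped to PD = 0; a violation exceeding 0.05 aborts the
run as structurally inconsistent.  PSA runs relax the abort and clamp fully,
since independent lognormal HR draws occasionally cross by more than the
tolerance and a Monte-Carlo simulation should not die on a tail draw.

The trace stops at the first cycle where the death fraction reaches 99%
(configurable), capped at 2,000 cycles (~115 years) to bound degenerate
inputs.  Occupancy is evaluated at cycle start with no half-cycle
correction; the choice is isolated in one function, and the price-linearity
results are invariant to it.

## Economics

Per cycle k, discount factor d_k = (1 + rate)^(−k·Δ_years) with
Δ_years = 21/365.25 — discounting is continuous-in-cycles rather than
stepped annually.  Accrual rules:

* drug cost × price multiplier and inpatient/follow-up cost on PFD occupancy
  (treat-to-progression, no stopping rule);
* progression treatment and best supportive care on PD occupancy;
* terminal care once per death, applied to each cycle's death increment
  (telescoping to terminal_cost × final death fraction when undiscounted);
* SAE management once at cycle 0 as rate × unit cost.  The source table
  labels this cost "per cycle", but charging it every cycle would make AE
  management dominate lifetime costs and contradict the published totals'
  ordering; the one-off reading matches how grade ≥ 3 events cluster at
  treatment start.  The decision is isolated in one accumulator line;
* QALYs as (PFD·u_PFD + PD·u_PD)·Δ_years, discounted like costs.

Costs are unitless money (the source used 2020 USD at 6.5 CNY/USD); nothing
in the model converts currencies.

## Decision analysis

ICER = Δcost/ΔQALY per (strategy, comparator) pair.  A pair where one arm is
cheaper *and* more effective prints "Dominated" instead of a ratio; equal
QALYs with unequal costs print "Undefined".  The default layout orders
strategies by effectiveness and compares each against every less effective
one.  Ranking is by net monetary benefit at the configured threshold
(`rank_by="nmb"`); `rank_by="cost"` ranks by ascending mean cost instead,
which is the ordering printed in the source evaluation's rank column — at
the $32,517 threshold the two rules agree on the winner but can permute the
middle ranks.  An efficiency-frontier mode (strict + extended dominance,
sequential ICERs) is provided as a separately labelled output.

Price scenarios multiply every strategy's drug price by (1 − r)
simultaneously.  Traces do not depend on price, so they are computed once
and re-accumulated; QALY columns across price levels are bitwise identical
and lifetime cost is exactly affine in the multiplier.

## Uncertainty

**One-way DSA** varies each parameter that has a published (low, high) range
— care costs, the two utilities, the discount rate — plus each strategy's
OS/PFS hazard ratios over their NMA 95% CIs, re-running the full model at
both bounds and reporting the ICER swing, sorted by bar width.

**PSA** assigns beta distributions to utilities and SAE rates and lognormal
to care costs and hazard ratios; drug prices, the discount rate, and the
Weibull parameters stay fixed, following the published distribution column.
Printed ranges are read as 95% intervals (SE = range/3.92); SAE rates have
no published range and fall back to a 20% coefficient of variation.  Betas
are method-of-moments from (mean, SE); cost lognormals match mean and SE on
the natural scale; HR lognormals are centred on the point estimate with the
CI-implied log-SE, sampled independently per endpoint (the joint OS/PFS
uncertainty is not published).  All draws come from one seeded generator;
identical seeds give bitwise-identical results.

**CEAC**: at each willingness-to-pay λ, the probability each strategy
maximises NMB = λ·QALY − cost across draws, with exact ties splitting their
vote uniformly (relevant only for degenerate deterministic inputs).

## Synthetic data

The generator emulates the pipeline's three inputs with known truth:
digitized KM clouds (uniform time grid to the 1st survival percentile,
additive gaussian noise, L2 isotonic projection onto a non-increasing
sequence, clipped into (0,1]), star-network trial tables (SE ~ uniform,
effect ~ normal around truth), and full configurations (the packaged
published set, or randomized within a factor of 3 of its costs, utilities
in (0.2, 0.97), HRs in (0.4, 1.6)).  It does *not* simulate patient-level
recruitment, censoring, at-risk tables, or correlated multi-arm trials —
so passing tests demonstrate estimator correctness under the stated noise
model, not robustness to every artefact of real digitization.

## Problem sizes and numerical choices

Default test/verification scales: 200-point digitizations at noise sd 0.005
(parameter recovery within 5%, typically ~2%), 10,000 replicates for the
95%-coverage check of the network CIs (±1% band), 1,000 PSA draws for the
acceptability-curve checks, 100 random star networks for the
oracle-equivalence test at 1e−10.  Occupancy conservation is asserted at
1e−9 per cycle, the chained-transition ↔ direct-survival identity and
league-table antisymmetry at 1e−12.

## Known limitations

The published headline QALYs (0.96/1.15/1.34/1.49) and ICERs are not
reproducible from the published inputs alone: the per-trial hazard ratios
behind the evaluation's NMA, and its half-cycle and cost-binding
conventions, are not printed.  This implementation's base case yields longer
survival (atezolizumab ~2.2 QALYs) with costs near the published totals and
the same qualitative conclusions: nivolumab cost-effective at list prices
(CEAC ≈ 97% at the threshold), atezolizumab dominating pembrolizumab, ICERs
falling linearly with price cuts.  Binding best-supportive-care cost to the
progressed state (rather than post-discontinuation PFD) is an assumption the
source leaves open; it is flagged as sensitivity-relevant.
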