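# Methods

## Model structure

The analysis couples a decision tree (one-time screening) to a cohort Markov
model (lifetime disease progression), the standard architecture for
screening cost-utility analyses.

**Decision tree.** For a cohort of screening age *a*, the target condition
is significant fibrosis (stage ≥ F2) with population prevalence π(a). A
two-stage strategy screens a fraction u₁ with a blood score (sensitivity
Se₁, specificity Sp₁), refers positives, of whom u₂ attend transient
elastography (Se₂, Sp₂). The tree's leaves are: unscreened, step-1
negative, referred-but-not-attending, TE-negative, TE-positive with true
F2–F4 ("treated, true positive") and TE-positive without ("treated, false
positive"). The two tests are taken as conditionally independent given true
fibrosis status — published accuracies carry no joint information. Leaf
masses therefore compose multiplicatively, e.g. treated-true =
u₁·π·Se₁·u₂·Se₂. Expected screening spend per person offered screening is
u₁c₁ + u₁·P(step-1 +)·u₂·c₂.

**Starting states.** Each leaf's occupants are distributed over the Markov
states by Bayes' rule: the diseased branch spreads over F2:F3:F4 in a
configurable 60:25:15 split, the non-diseased branch over
no-MASLD : F0 : F1 using the age band's overall MASLD prevalence and a
50:50 F0:F1 split. Both splits are explicit assumptions (the primary
staging data behind them are unpublished) and are config knobs. Where the
published age bands conflict (significant-fibrosis prevalence above the
coarser MASLD prevalence at ages ≥ 60 in obesity and ≥ 80 in MetS), the
MASLD prevalence is floored at the significant-fibrosis prevalence so the
F0/F1 pool is never negative.

**Markov model.** Thirteen states, 1-year cycles from the screening age to
age 100 (configurable). Annual disease transitions are the published
pooled probabilities; transplant entry (DC→LT, HCC→LT) is closed above age
70 (implemented as "age ≤ 70 permits entry", following the tabulated age
label rather than the stricter prose "under 70"). Death competes first:
each state's annual death probability is the life-table probability times
the population multiplier and a disease hazard ratio (1.29 non-cirrhotic
MASLD, 1 for no-MASLD, 3.13 for F4/CC, DC and HCC); the transplant-year
and post-transplant states instead use a flat annual post-transplant
mortality parameter (placeholder 0.05, overridable — the source cohort
values are not printed). Disease exits apply to the surviving fraction, so
rows are stochastic by construction; parameter draws whose raw exits sum
above 1 raise an error rather than being renormalised. Death mass is split
across cardiovascular / liver / other death states by configurable
fractions; the split is attribution only and never changes totals, so its
placeholder defaults are harmless to every reported quantity.

**Treatment effect.** TE-confirmed true positives who adhere (adherence
default 1.0, swept 0.60–1.00) have F2→F3, F3→F4/CC and F4/CC→DC multiplied
by 1 − RRR, RRR = 0.204, for the remainder of the run. Symmetrically, the
annual lifestyle-programme cost (1,426.8 THB) accrues in every alive
pre-decompensation state, for life, in all intervention strata — including
TE false positives, who get cost without benefit. A finite programme
duration is configurable. This lifelong convention is the internally
coherent reading of a lifelong effect with a per-year cost and no stated
stop rule, but it is also the single largest source of deviation from the
published incremental costs, whose (unpublished) supplementary convention
evidently differs: the published MetS incremental costs are too small to
contain a lifelong programme cost and too large for a one-year one.

**Payoffs.** QALYs: state utilities × occupancy, discounted at 3 %/yr,
first cycle undiscounted (t = 0), no half-cycle correction — chosen for
bit-for-bit reproducibility, documented because the source is silent.
Costs: annual state management costs (cost-to-charge ratio, default 1.0,
range 0.6–1.2, applies to the hospital-database-derived states: no-MASLD
management, F0–F3, F4/CC) plus direct non-medical costs per clinic visit
(tertiary-hospital food + transport, 245.9 THB/visit; 2 visits/yr
pre-decompensation, 4 visits/yr in advanced states — assumed counts,
config knobs). Obesity-without-MASLD incurs no healthcare costs, medical
or non-medical. Screening-test spend is added at t = 0. Life expectancy is
undiscounted alive person-years.

## Parameter uncertainty

Every uncertain input carries a distribution: beta for probabilities
(moment-matched from the printed mean and SE), gamma for costs, and the
relative-risk-reduction convention for the treatment effect — RR = 1 − RRR
sampled lognormally with matched moments, returned as 1 − RR truncated to
[0, 1), which keeps the progression multiplier positive (a lognormal on
RRR itself would be unbounded above 1). Range-only parameters (screening
uptakes) are fixed at base case deterministically and uniform over their
printed range in PSA; their sampled mean is consequently the range
midpoint, not the base value. The FIB-4 and SAFE screening costs are sums
of component laboratory costs; their gamma SEs are taken in quadrature
over the components (39.25 and 46.84 THB). Mortality hazard ratios stay
fixed in PSA (the prescribed families cover accuracy, transitions, effect
and costs only); their printed 95 % CIs serve as one-way sweep bounds.
One-way bounds elsewhere are mean ± 1.96 SE truncated to the domain
(interpreting the "95 % confidence interval" as a normal approximation),
± 25 % for costs, and the stated ranges for adherence (0.60–1.00) and the
cost-to-charge ratio (0.6–1.2). Parameters are sampled independently — no
correlation structure is specified by the source evidence. Utilities are
sampled without state-ordering constraints; rare non-monotone draws
(e.g. DC utility above F4/CC) are kept.

PSA uses common random numbers across strategies (one sampled parameter
set per draw, all strategies evaluated on it), the standard practice for
incremental comparisons. Each draw is seeded by (seed, index) so any draw
is reproducible in isolation; infeasible draws are resampled with a
logged count and a > 5 % resample rate raises. The acceptability curve is
computed among the three screening strategies only (the probability each
achieves the highest NMB versus no screening), while the probability-
cost-effective-versus-no-screening statistic is reported separately — the
two answer different questions and both are standard outputs.

## Strategy comparison

ICERs always use full-precision model outputs. The frontier algorithm
sorts by QALYs, removes simple dominance (≥ cost and ≤ QALYs, one strict;
QALY ties resolve by lower cost, exact double ties are reported jointly),
then iteratively removes entries whose ladder ICER is not strictly below
that of the next more effective survivor (extended dominance). The
threshold analysis exploits that the ICER is affine and increasing in the
TE unit cost at fixed QALYs and bisects to |ICER − λ|/λ < 10⁻⁶, returning
boundary verdicts when the threshold is not bracketed. The F4/CC→HCC and
F4/CC→DC exits are treated as simultaneous competing risks within a cycle.

## Budget impact

Payer perspective, screening-test costs only, undiscounted, 5 years. The
eligible pool in year 1 is national population × condition prevalence
(MetS 18.0 %, obesity 33.4 %, both 15.2 %); years 2–5 each add the pool's
incident growth — population × prevalence × annual incidence (MetS 8.0 %,
obesity 0.9 %, both approximated as their average, 4.45 %) — so each
person is screened once. This at-risk-equals-prevalent-pool reading is the
one consistent with the published 5-year target pools (≈ 4.2 M MetS /
7.2 M obesity / 3.4 M both) arising from a single national population of
adults 50–79; the default count is a synthetic round 20,000,000,
configurable. The step-1 positivity rate reuses the age-50
significant-fibrosis prevalence (configurable reference age). No
population growth or mortality attrition is modelled within the window.

## Synthetic data and oracles

The default life table is a frozen Gompertz table, annual death
probability 1 − exp(−α·e^{βa}) with α = 4.9645 × 10⁻⁵, β = 0.09, giving
life expectancy 77.0 y at birth and 28.8 y at 50 — Thailand-like in level
and shape but *not* the national table, which is not bundled. It lacks
infant/young-adult mortality structure and secular trends; everything
downstream that depends on absolute survival (life expectancy, lifetime
costs, hence ICER levels) inherits this approximation, which is the main
reason published point values are reproduced only approximately. The toy
scenario switches off disease flows and sets constant mortality so
discounted QALYs have a closed geometric form (1/(1 − s/(1+d)) =
7.9230… at s = 0.9, d = 0.03), anchoring the engine analytically. The
microsimulation oracle re-runs any scenario as n sampled individuals using
the same age-indexed transition rows but none of the occupancy-vector
algebra, and agrees with the cohort engine within Monte Carlo error
(checked at n = 50,000 and across 20 random parameter draws); passing
these checks validates the engine's arithmetic, not the realism of the
inputs.

## Problem sizes and runtimes

Deterministic evaluation runs 51 annual cycles × 13 states per stratum
(≈ 10 ms for all four strategies); the PSA uses 1,000 draws; the
microsimulation checks use 20,000–50,000 individuals; the budget horizon
is 5 years. The acceptance script completes in well under a minute.

## Known limitations

- One-time screening only; no repeat or interval screening.
- No HCC from non-cirrhotic states (a documented limitation of the source
  model, kept).
- Published headline values are reproduced conditionally: the obesity
  cost-utility structure (all strategies under the 160,000 THB threshold,
  FIB-4 + TE lowest ICER), the ICER orderings, the tornado drivers
  (fibrosis-progression probabilities and the discount rate), the
  projected MASLD incidence (within ~5 %) and the budget band reproduce;
  the MetS ICER levels land roughly 2× above the published values under
  the synthetic life table and the lifelong-programme cost convention, so
  the MetS cost-effectiveness verdict and the TE price threshold do not
  reproduce. These deviations are reported as-is by the test suite and
  acceptance script rather than calibrated away.
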