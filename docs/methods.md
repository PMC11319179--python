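# Methods

## Model structure

The pipeline couples a one-shot screening decision tree to a discrete-time
Markov state-transition model and evaluates strategies by cost-utility
analysis.

**Decision tree.** A screened adult is either an undiagnosed type 2
diabetic (probability = prevalence) or not. The index test (POCT HbA1c,
venous HbA1c or FCG) classifies each person; screen-positives receive a
confirmatory OGTT treated as a perfect gold standard (sensitivity =
specificity = 1), so the tree has exactly four terminal arms. Misdiagnosed
individuals (screen-positive, OGTT-negative) incur the OGTT cost but no
treatment cost and enter the non-diabetic model; nobody is re-screened.
Screening happens once, at time zero, and its cost is therefore neither
discounted nor half-cycle corrected.

**State space.** Thirteen states: NON_DM; diabetes without complications;
CVD and stroke (macrovascular); diabetic kidney disease, foot ulcer,
retinopathy and peripheral neuropathy (microvascular); their severe
sequelae ESRD, amputation and blindness, each reachable only from its
parent complication; one lumped multi-complication state (single transition
probability and single annual cost, reflecting the scarcity of
multi-morbidity data); and absorbing DEATH. NON_DM can only persist or die
(no incident diabetes in the negative model), so the non-diabetic model is
the two-state sub-chain of the same space.

**Dynamics.** One-year cycles; transitions are age-banded annual
probabilities (any partition of [18, 80) is accepted; the synthetic default
is 5-year bands) and cohorts run until age 80. Occupancy accrues annual
costs and utility weights with half-cycle correction — the per-cycle
effective occupancy is the mean of the cycle's start and end occupancy,
i.e. the trapezoid rule over the trace — and discounting at integer cycle
boundaries with cycle 0 undiscounted, at rate 5%/year (sensitivity range
0–8%). The baseline population is partitioned into single-year age strata,
each run to 80 and averaged by weight; sex is carried in the population
structure but the bundled tables are sex-pooled.

**Hazard-ratio adjustment.** Missed (untreated) diabetics have transitions
into microvascular states multiplied by 1.391, into macrovascular states by
1.287, and into DEATH by 1.290; rural residence multiplies complication
incidence by CVD 1.15, stroke 1.25, blindness 2.09, foot ulcer 1.42, ESRD
1.15 (unlisted transitions ×1.0, overridable per config). Multipliers act
directly on annual probabilities — the convention under which the source
estimates were derived — rather than via a rate transform; each product is
capped at 1 and the row is re-closed through the stay probability. In the
degenerate case where adjusted outflows exceed 1, outflows are rescaled
proportionally, the stay probability is set to 0 and a warning is logged.
The lumped multi-complication state is classified microvascular so the
larger (more conservative) multiplier applies to transitions into it. The
death hazard ratio applies only to diabetic-state mortality, not to
background (NON_DM) mortality, since it estimates diabetes-attributable
excess risk.

## Evaluation routes

Three routes compute the same expectations and are cross-checked in tests:

1. **Forward cohort recursion** (`run_cohort`) — returns the full occupancy
   trace; used for reporting and trace export.
2. **Backward value iteration** (`expected_values_by_age`) — one sweep over
   ages yields the expected discounted lifetime cost/QALY for every (state,
   start age); with half-cycle correction the accrual at age *a* is
   ½(v + P_a v). This is exactly the forward total (verified to 1e-9) at a
   fraction of the cost, and powers OWSA/PSA where thousands of model
   evaluations are needed.
3. **Microsimulation** (`run_microsimulation`) — seeded individual walks
   with transitions taken mid-cycle (half weight in origin and destination
   for the transition year, the individual-level analogue of half-cycle
   correction); returns Monte Carlo standard errors and is bit-reproducible
   per seed. The published analysis's 10-million-person simulation is
   reproduced at n = 100,000, which already pins the mean to ≈0.1% — the
   package's validation runs use that size as a deliberate desk-scale
   choice with identical expectations.

Strategy outcomes are the arm-fraction-weighted mixture of the three arm
runs (diagnosed: base transitions; missed: base × missed-diagnosis HRs;
misdiagnosed and true negative: non-diabetic chain) plus the screening-stage
cost; the arm runs are strategy-independent and shared across strategies.

## Cost-utility analysis

ICUR = ΔC/ΔE for each (reference, comparator) pair; default pairs are each
HbA1c strategy versus FCG plus venous versus POCT, mirroring the layout of
published screening cost-utility tables (an efficiency frontier is not the
default). Dominance: ΔC < 0 and ΔE > 0 → dominant; ΔC > 0 and ΔE < 0 →
dominated, with the signed negative ICUR still reported. Cost-effective at
λ iff dominant, or ΔE > 0 and ICUR ≤ λ. When ΔE = 0 the ICUR is undefined
and the verdict follows the cost sign (a tie counts as cost-effective).
λ defaults to 3 × GDP per capita ($12,551), i.e. $37,653/QALY. Costs are
stored in USD; CNY inputs convert at 6.4 CNY/USD.

## Sensitivity analysis

**One-way.** Each parameter takes its reported range, or ±20% of base when
only a point estimate exists (probabilities clipped to [0, 1]; the discount
rate uses its declared 0–8% range). Endpoint ICURs come from full re-runs;
bars are sorted by width descending with parameter-id tie-breaks. An
endpoint that invalidates the bundle is skipped with a logged warning and
recorded as NaN; its bar width falls back to |valid endpoint − base ICUR|.
Probability perturbations re-close their row through the stay probability,
the same contract as HR application.

**Probabilistic.** Distributions per parameter: Beta(α = events,
β = non-events) for count-backed probabilities (the synthetic default uses
pseudo-counts at an effective sample size of 1,000; a zero count gets +0.5);
lognormal for costs with μ = ln(point estimate) (point estimate = median)
and σ = sqrt(ln(1 + 0.1²)) ≈ 0.09975 so the draw's SD is exactly 10% of its
mean — the phrasing "SD = 10% of the mean" also admits σ = 0.1, which
differs by <0.3% and is accepted via the `cv` argument; uniform (±20%) for
utilities and hazard ratios. Draws are independent across parameters (no
correlation structure is specified for this class of model). 1,000
iterations by default; draw *i* is seeded from (seed, *i*, attempt), so any
single draw is reproducible in isolation and rejected draws (invalid after
clipping; counts logged) do not perturb their neighbours. The CEAC counts
draws with net monetary benefit λ·ΔE − ΔC strictly positive (ties are not
cost-effective) over a default λ grid of 0 to 3×WTP in 101 points.

## Synthetic data

The generator emulates the *structure* of a real parameter file — not any
published supplementary values: age-banded transitions with background
mortality rising from 0.05% (18–25) to 4.6% (75–80) per year and
state-specific excess-mortality multipliers (1.5–6); complication onset
0.5–2%/year and sequela progression 2–5%/year, all jittered ±10% per seed;
annual state costs from $320 (uncomplicated, treated) to $9,500 (ESRD);
a strictly ordered utility ladder 1.0 > 0.84 > single complications ≥ 0.44
(multi-complication) > 0; FCG sensitivity centred on the 65.1% reported for
Chinese screening populations with both HbA1c tests drawn more sensitive;
undiagnosed prevalence ≈ 0.10–0.14 urban, 0.09–0.13 rural; and per-test
cost components in which the venous test carries the largest non-medical
burden, amplified (×2.5 travel, ×1.8 time) rurally. Urban and rural bundles
from one seed share base transitions, utilities and state costs, so
urban/rural contrasts isolate the rural hazard ratios, prevalence and
screening-cost differences.

What passing tests on synthetic data do and do not show: they verify the
*machinery* — conservation, discounting, half-cycle correction, HR
algebra, mixture weighting, distribution moments, CEAC counting — and the
qualitative orderings any credible parameterisation must produce (missed ≤
diagnosed QALYs, rural ≤ urban at equal base transitions, higher Se never
harms). They do not certify any published headline ICUR: those depend on
the actual parameter values, which can be loaded through the same schema
when available. Whether a specific strategy dominates is likewise a
property of the parameter values, not of the code.

## Numerical choices and edge cases

- Transition rows must sum to 1 within 1e-6 before validation and are
  stored exactly re-closed; rows already within ~1 ulp are left untouched
  so that validation is a fixed point and files round-trip bit-exactly.
- Structural zeros (e.g. NON_DM → ESRD) are rejected at validation, not
  silently zeroed.
- A start age at or above the horizon yields a zero-cycle outcome; a
  single-row trace is returned unchanged (with a warning) by the half-cycle
  corrector.
- `half_cycle=False` switches both engines to start-of-cycle accrual, used
  by the closed-form oracle tests.
- Full precision in all CSV outputs; rounding to 2 dp is presentation-only.

## Known limitations

- No incident diabetes in the non-diabetic arm, no later clinical detection
  of missed cases, no repeat screening — all mirrors of the modelled
  design, listed here because they bound what the comparison measures.
- OGTT is assumed error-free; imperfect confirmatory testing would need an
  extra tree layer.
- PSA draws are uncorrelated; correlated (e.g. Cholesky) sampling is out of
  scope.
- Compliance is implicitly 100%: every diagnosed person is treated, every
  screen-positive attends the OGTT.
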