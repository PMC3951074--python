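# Methods

## Decision problem and model structure

The package compares two radiotherapy strategies for a cohort of 6-year-old
children with medulloblastoma: conventional photon craniospinal irradiation
plus tumour-bed boost (XRT) versus proton craniospinal irradiation plus
boost (PT). Both arms deliver the same target dose, so tumour control and
survival are identical; the strategies differ only in mean cochlear dose and
therefore in the risk of permanent Grade 3–4 hearing loss, and in price.

The model is a deterministic three-state Markov cohort model (alive without
hearing loss, alive with aided hearing loss, dead) with an annual cycle and
a lifetime horizon (age 6 to 100). Each arm is evaluated separately for the
average-risk (70% of the cohort) and high-risk (30%) prognostic groups and
the results mixed.

### Mortality

* Years 1–5: a constant annual disease hazard `q` with `(1−q)⁵ = OS₅`
  (0.85 average-risk, 0.70 high-risk). The geometric shape is the simplest
  hazard consistent with a single 5-year survival constraint; the trial
  curves are treated as all-cause in this window, so no background
  mortality is added on top (adding it would double-count deaths).
* Year 6 onward: disease mortality plateaus; the annual probability of death
  is the background all-cause `q(age)` from an age-indexed life table, with
  attained age = 6 + years since treatment.
* Mortality is state-independent: hearing loss does not alter survival, and
  the two arms share the same mortality schedule.

### Hearing-loss onset

Severe ototoxicity appears from one year after treatment and its cumulative
incidence among survivors plateaus at the lifetime risk in year 3. Between
those bounds the accrual shape is not constrained by the inputs; we use
equal cumulative increments over cycles 1–3 (e.g. 13% / 26% / 39% for the
photon average-risk group) and convert them to conditional per-cycle
transition probabilities. Within a cycle, death is applied before
conversion; with this ordering the hearing-loss prevalence among survivors
at the plateau equals the tabulated lifetime risk exactly (asserted to
1e-9 in the tests), which is how those risks are defined.

### Rewards and discounting

Rewards accrue at cycle end: cycle 0 carries only the radiation-course cost,
cycles 1..94 contribute utilities and hearing-related costs, discounted at
3%/year by `(1+r)^−t`. No half-cycle correction is applied by default — the
convention shifts absolute QALYs by ~1–2% and incremental results much less;
`half_cycle_correction: true` enables mid-cycle valuation of averaged
adjacent state vectors for exploration.

Utilities: 1.0 without hearing loss (the analysis's QALY totals are
consistent with full utility for unimpaired survivors; population norms
below 1 can be configured via `u_no_hl_*`), and instrument-specific aided
hearing-loss utilities 0.807 (EQ-5D), 0.644 (HUI3), 0.792 (SF-6D). HUI3
contains explicit hearing and cognition attributes, which is why it is the
most sensitive instrument and produces the largest incremental QALY gain.

Costs (USD, payer perspective, no indirect costs, no inflation): radiation
course at t=0; at each onset cohort's conversion cycle a hearing test
($65.4), a fitting test ($121.5) and one hearing aid ($2,086.9); an annual
hearing test in each of the two years after onset; and a replacement aid
every 5 years for the rest of life. All post-onset items are pro-rated by
the fraction of the onset cohort still alive at the purchase cycle (exact,
because mortality is state-independent). Replacements carry the aid price
only — the fitting test is not repeated — which may slightly understate
photon-arm costs. One aid per purchase; bilateral aids would double that
line and can be modelled by doubling `c_hearing_aid`.

### Incremental analysis

ICER = ΔCost/ΔQALY from unrounded values (the published table's rounded
ΔQALY of 0.98 would naively give 21,833, not the printed 21,716 — rounded
quotients are never used here). When ΔQALY = 0 the ICER is flagged
undefined and net monetary benefit (`λ·ΔQALY − ΔCost`) carries the
comparison.

## Dose–response module

The relation between mean cochlear dose and Grade 3–4 hearing-loss
incidence is modelled as the average of logistic curves. The original
regression coefficients behind the per-arm risks are not recoverable from
the published inputs, so the base case feeds the tabulated risks directly
into the Markov model, and the dose–response module is a calibrated
scenario tool: `fit_logistic` interpolates (dose, incidence) anchors on the
logit scale (exact through two anchors, least squares beyond), and
`predict_risk` averages member curves on the probability scale (a
logit-scale mean is available, the two differ negligibly over the 29–50 Gy
range of interest). Concurrent cisplatin (~300 mg cumulative) is a constant
context of those anchors, not a covariate.

## Sensitivity analyses

**One-way (tornado):** each uncertain parameter is set to the low and high
end of its range with everything else at base, and the ICER recomputed.
Ranges are the tabulated intervals; the hearing-test and fitting-test costs,
which have no tabulated interval, use ±25% (the same half-width assumed for
the analysis's cost inputs); the discount rate spans 0–7%. Entries are
sorted by ICER spread. Under the defaults the three widest bars are, for
every instrument: discount rate, proton-arm hearing-loss risk
(average-risk), proton radiation cost.

**Probabilistic:** 10,000 iterations per utility instrument; every ranged
parameter is drawn independently from triangular(low, mode=base, high) by
inverse CDF from a single seeded generator. The discount rate is included
among the sampled parameters, drawn from triangular(0, 0.03, 0.07): all of
the model's uncertain variables fluctuate simultaneously. This matters —
with the discount rate held at 3% the acceptability probability at the
$46,729/QALY threshold is 100% for every instrument because no combination
of the remaining ranges pushes the ICER above the threshold; the
sub-100% acceptability the analysis is known for arises from high-discount
draws interacting with unfavourable proton-arm draws.
`include_discount=False` (CLI `--fixed-discount`) restores the restricted
variant. Draws are independent across parameters; combinations that invert
the proton/photon risk ordering are kept as drawn and flagged (with the
default ranges the supports cannot overlap, so the flag count is zero).

**CEACs:** at each willingness-to-pay value on a grid (0–150,000 by 1,000,
containing 46,729 exactly), the acceptance probability is the fraction of
draws with positive net monetary benefit. The "integrated" curve pools the
three instruments' draw sets with equal weight (3n draws); per-trial random
instrument selection would have the same expectation.

## Synthetic life table

Background mortality uses a synthetic stand-in for a modern Japanese
complete life table, generated from a Gompertz–Makeham hazard
`mu(a) = A + B·exp(c·a)` with A = 4·10⁻⁴, B = 5·10⁻⁶, c = 0.115 per year.
These values were calibrated once so that period life expectancy at birth
over ages 0–100 is ≈ 81.4 years with a realistic old-age q(a) profile
(q(65) ≈ 0.009, q(80) ≈ 0.049); they are approximate, not official, and the
table is both-sex composite (the cohort's sex split is not an input). The
generator has no infant-mortality hump and no cohort (generation) effects —
features of real tables that do not matter here because the model only
consumes q(a) from age 12 upward at a 3% discount. The bundled CSV is
committed (regeneration is deterministic and bit-identical) so downstream
results are stable. A dedicated test shows the incremental cost and QALY
results move by under 2% when the hazard level is perturbed by ±20%,
i.e. the conclusions do not hinge on the exact stand-in. (A ±20% change of
the exponent c is not a level perturbation — it shifts life expectancy by
roughly eight years — and is outside the family of plausible stand-ins.)

## Numerical conventions and degenerate inputs

* State-vector conservation is enforced to 1e-12 per cycle; Dead is
  absorbing by construction.
* The life table must cover ages 0..100 contiguously; lookups past its end
  raise, with an optional terminal clamp q(end)=1.
* Equal risks in both arms are a valid input (ICER reported as undefined);
  lifetime risk 0 and survival 1 reduce to closed-form limits used in tests.
* Validation failures name the offending configuration key; unknown keys
  are rejected rather than ignored.
* All Monte Carlo randomness flows through one `numpy` generator seeded
  explicitly; identical seeds give bitwise-identical sample tables.

## Problem sizes

The base case runs 4 cohort traces of 94 cycles (milliseconds). The shipped
probabilistic analysis uses 10,000 iterations per instrument (one model run
per iteration serves all three instruments, since utilities do not affect
state occupancy), about half a minute on one core; the acceptance script
uses the same size.

## Known limitations

* No relapse, progression or second-malignancy states; survival past year 5
  is purely background mortality, per the plateau assumption.
* Hearing loss is a binary Grade 3–4 endpoint; audiogram-grade severity
  progression is not modelled.
* Costs beyond radiotherapy and hearing care (endocrine, cognitive,
  vascular late effects) are excluded, as are indirect costs — the
  comparison is conservative toward proton therapy.
* Utilities come from adult hearing-aid users in western populations;
  child- and Japan-specific utilities were not available.
* Parameter draws are independent; no correlation structure (e.g. between
  the two arms' risks, which share a dose–response mechanism) is imposed.
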