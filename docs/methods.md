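# Methods

## The decision problem

A patient with cirrhosis presents with a symptomatic abdominal hernia.
Elective repair removes the symptom burden and the ongoing risk of
acute hernia events, but carries an upfront operative mortality that
grows with the severity of liver disease (summarised by the MELD-Na
score, 6–40). Nonoperative management avoids the operation but leaves
the patient exposed, every cycle, to incarceration and flood syndrome
(spontaneous rupture), either of which can force *emergent* surgery at
considerably higher mortality. The package quantifies this trade-off
in quality-adjusted life-years (QALYs) and locates the MELD-Na value at
which the two strategies break even.

## Markov cohort model

Three base states: **symptomatic hernia**, **resolved hernia**,
**death**. Cycles are 180 days; the horizon is 10 cycles (≈5 years).
Within a cycle a patient may traverse transition states before coming
to rest in a base state:

* symptomatic mass splits multinomially: incarceration
  (`p_incarceration`), flood syndrome (`p_flood`), or neither;
* incarcerated hernias are reduced successfully with
  `p_reduction_success` and stay symptomatic; failed reductions and all
  flood events proceed to emergent surgery;
* emergent surgery kills with `p_emergent(m)`; survivors suffer a
  complicated recovery with `p_ecomp(m)` and rest resolved;
* in the surgical strategy only, the entire symptomatic cohort
  undergoes elective surgery in cycle 1 (death `p_elective(m)`,
  complication `p_comp(m)`, survivors rest resolved);
* mass with no surgical event that cycle dies of liver disease with
  `p_nonop(m)`; resolved survivors recur to the symptomatic state with
  `p_recurrence` (a return of symptoms, not an acute event, so it
  carries no penalty).

Liver-disease mortality is applied **only** to mass without a surgical
event in that cycle: the operative-mortality channels are fitted to
all-cause postoperative death and therefore already embed
liver-related risk; stacking `p_nonop` on top would double-count it.
For the same reason a successfully reduced incarceration (no surgery)
does face `p_nonop`. Elective surgery happens exactly once — strategies
are fixed at the initial decision node, and recurrences in either arm
are managed nonoperatively thereafter.

Disease progression is modelled as a deterministic MELD-Na drift of
0.75 points per cycle, clamped to [6, 40]; all five probability
channels are re-evaluated each cycle at the drifted score. The drift
default honours the published per-cycle value; the package also
provides the converter from a cohort's mean annual change (1.59
points/year × 180/365.25 ≈ 0.78), and the two are deliberately kept
separate rather than reconciled.

### Utilities and half-cycle correction

Per-cycle base-state utilities: resolved hernia 0.324 (decompensated
cirrhosis alone), symptomatic hernia 0.324 × (1 − decrement) with a
default 10% decrement (0.2916), death 0. Transition states charge
one-time penalties expressed as fractions of a best-health-state yearly
utility: incarceration 22.8%, flood 42.9%, elective surgery 8.8%,
emergent surgery 21.8%, complicated recovery 20.8%. The anchor itself
is never published directly; dividing each published penalty by its
published fraction gives five estimates agreeing within ~0.005
(0.649, 0.648, 0.648, 0.647, 0.644), so the anchor defaults to 0.65
and is a named config field. Storing (anchor, fraction) pairs rather
than raw decrements lets the sensitivity analyses vary the fractions
directly.

QALY accounting values state occupancy at every cycle *boundary*, with
the entry and exit boundaries at half weight (half-cycle correction):

    QALY = ½·U(s₀) + Σₜ₌₁ⁿ⁻¹ U(sₜ) + ½·U(sₙ) + Σ penalties + terminal

where U(s) is the occupancy-weighted base-state utility. Penalties are
instantaneous events, not state memberships, so they are never halved.
With all events, deaths and payoffs switched off this reduces exactly
to n_cycles × u_symptomatic, and a single cycle with death probability
p returns ½u + ½(1−p)u — both are pinned in the test suite.

### Terminal payoff

After the horizon, each surviving patient receives the projected
median life expectancy at the exit MELD-Na times the yearly utility of
their final base state, occupancy-weighted over the final state vector
(the mixture, not the modal state). Life expectancy is a regression on
log MELD-Na, `max(a + b·ln m, floor)` with floor 0.25 years to prevent
negative payoffs at extreme scores. Yearly utilities rescale the
per-cycle values by 365.25/180 (≈0.657 for resolved), consistent with
the ≈0.65 best-health anchor recovered from the penalty table.

## Risk models

* `p_nonop`: maximum-likelihood logistic regression of observed
  180-day death on MELD-Na among nonoperative patients (statsmodels).
* `p_elective`, `p_emergent`, `p_comp`, `p_ecomp`: patients are
  grouped by integer MELD-Na stratum, the external risk score's
  predicted probabilities are averaged per stratum, and an ordinary
  least-squares line is fitted through the stratum means (each stratum
  weighted equally — a deliberate choice over patient-level OLS,
  mirroring how the inputs were derived). Evaluations clamp to [0, 1].
* life expectancy: per-stratum median survival (Kaplan-Meier median
  when any record is censored, plain median otherwise — the estimator
  is not dictated by the source, so the censoring-aware one is used
  exactly when censoring is present), then OLS of the medians on
  ln(MELD-Na).

The engine consumes these through a plain callable interface, so a
user holding an exact per-MELD probability table (CSV with columns
`meld,p_elective,p_emergent,p_comp,p_ecomp,p_nonop`) can substitute it
unchanged; tabulated channels interpolate linearly between integer
scores and evaluate at the nearest endpoint beyond the table's span.

## Synthetic cohort

No patient-level data from the original referral cohort are
deposited, so the fitting stages run against a generated stand-in of
n = 2740 patients, 36.1% operative. The generator reproduces exactly
the structure the fits consume:

* referral MELD-Na: discretised log-normal matched per stratum to
  median 11 (IQR 7–16) nonoperative and 9 (6–13) operative;
* 180-day death: Bernoulli from the logistic law (default intercept
  −5.0, slope 0.12 — about 3% at MELD-Na 11 rising to 13% at 25);
* survival: deaths uniform within the first 180 days, survivors 180
  days plus an exponential tail whose scale is solved per stratum so
  the mixture median lands on a + b·ln(m) (default 12 − 3·ln m years);
  an optional knob applies independent (non-informative) censoring;
* operative-risk predictions: configurable lines in MELD-Na plus
  bounded Gaussian noise (sd 0.01), clipped to [0, 1] — defaults
  elective 0.012·m, emergent 0.02 + 0.018·m, complications
  0.06 + 0.007·m and 0.12 + 0.010·m;
* annual MELD-Na change: normal with mean 1.59, sd 1.0.

The operative default lines were chosen so the qualitative structure
of the emulated system holds: operative mortality exceeds the
nonoperative projection at every initial score (excess of roughly +6
to +17 points across 6–25) and rises steeply enough that a single
equivalence threshold falls inside the iterated 6–25 range (≈19–21
under the defaults, varying with the fitting seed). The generator does
**not** emulate comorbidities, labs, CTP class, the correlation
structure of a real surgical-risk score, or informative censoring —
so passing tests demonstrate the machinery (fits recover generating
laws; the engine and analyses are internally consistent), not clinical
calibration. Absolute thresholds from the defaults are illustrative;
clinical use requires the real per-MELD probability inputs.

A stratum whose 180-day mortality exceeds 50% cannot attain a median
survival above 180 days; in that regime the generator floors the tail
scale and delivers the nearest attainable median rather than failing.

## Decision analysis

Expected QALYs for both strategies are computed on the initial
MELD-Na grid 6–25 (1-point steps). The threshold is the sign change of
the surgical-minus-nonoperative difference, linearly interpolated
between the bracketing grid points; an exact grid zero is returned
as-is, and multiple sign changes raise an error (a single threshold is
the framing; silent selection would hide non-monotonicity). An
optional refinement bisects the bracket with real model runs for cases
where the difference is visibly curved.

## Uncertainty analyses

* **Microsimulation** (first-order): individual patients traverse the
  same event tree by random draws, vectorised over trials. The two
  strategies share the underlying uniform draws within a trial (common
  random numbers), so per-trial QALY differences isolate the decision.
  Exact ties — possible under pairing — count half toward the
  proportion favouring surgery. Means converge to the cohort
  expectation (asserted at n = 100 000 within 3 standard errors).
* **PSA** (second-order): the four fixed transition probabilities and
  the symptomatic decrement are drawn jointly from beta distributions
  whose central 95% mass spans each parameter's range; each draw is
  evaluated by cohort expectation (input uncertainty only — patient
  chance is integrated out). Beta shapes are found by solving the two
  quantile equations with a Newton-type root finder on (log α, log β),
  moment-matched start, verified to 1e-6 against the incomplete beta
  function.
* **Tornado**: one-way parameter sweeps at a fixed initial MELD-Na,
  ranked by the induced QALY-difference range. Default ranges are
  [0.75×, 2×] of base (the "25% down, 100% up" convention), exposed
  per-parameter because the convention is genuinely ambiguous; note
  the asymmetry pulls beta medians above base values, which is why PSA
  proportions above the threshold need not fall below one half.
* **Two-way sweep**: both complicated-recovery channels scaled
  together by 0.5×/1×/1.5×, threshold recomputed per factor.
* **Three-way sweep**: threshold surface over (recurrence probability,
  symptomatic decrement); monotone — more recurrence lowers the
  threshold, more symptom burden raises it.

Binomial proportions carry Wald 95% intervals by default (Wilson
available), appropriate at the trial counts used.

## Problem sizes and numerical choices

Default analysis sizes: cohort n = 2740; microsimulation 100 000
trials; PSA 20 000 trials in the bundled pipeline script (the
proportion's standard error at 20 000 is ≈0.35 points, ample for the
reported contrasts); parameter-recovery checks use n = 20 000 cohorts,
with the replicated-recovery property run at 20 replicates. All
randomness flows from explicit integer seeds through numpy
`default_rng`; every stochastic routine is bit-reproducible for a
fixed seed. Occupancy conservation is enforced to 1e-12 along the
whole trace; probabilities are validated after clamping and the
multinomial event split requires p_incarceration + p_flood ≤ 1.

## Known limitations

* No liver-transplant pathway, and no memory of past decompensation
  (a first-order chain: utilities depend only on the current state).
* Costs are out of scope; the outcome is QALYs only.
* MELD-Na drift is deterministic and uniform across live states.
* The within-cycle event tree is a declared resolution of the
  qualitative state diagram; other orderings (e.g. competing-risk
  adjustments within a cycle) are defensible and would change results
  slightly at the default probabilities.
* Default probability inputs are synthetic stand-ins; all absolute
  results under the defaults illustrate the method, not the clinic.
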