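# Methods

## The decision problem

`prucea` implements a Markov cohort cost-utility model comparing prucalopride
2 mg once daily against continued laxative treatment in adults with chronic
constipation for whom laxatives have failed to provide adequate relief, from
the perspective of the Dutch payer in 2011 euros. Effectiveness is measured in
quality-adjusted life-years (QALYs); the headline statistic is the incremental
cost-effectiveness ratio (ICER), the incremental cost per QALY gained.

## Model structure

Nine health states are propagated in monthly cycles over a 12-month base-case
horizon:

* `START_W1_4`, `START_W5_8`, `START_W9_12` — the first twelve weeks on the
  initial treatment (prucalopride, or continued laxatives in the comparator
  arm);
* `MAINTENANCE` — absorbing; responders who keep normal bowel function beyond
  week 12;
* `SWITCH_W1_4`, `SWITCH_W5_8`, `SWITCH_W9_12` — twelve weeks on a second-line
  laxative after failure of the initial treatment;
* `SWITCH_MAINTENANCE` — absorbing; responders to the switch treatment;
* `DROPOUT` — absorbing; second-line failures, retained on laxatives.

The cohort starts fully in `START_W1_4`. Under the label's stopping rule
(default on), week-4 non-responders leave initial therapy after the first
cycle with probability `1 − r4`. Week-4 responders continue; at the end of the
start pathway the conditional retention `r12 / r4` sends them to maintenance
and the complement to the switch pathway, so the unconditional week-12
responder mass equals the trial's weeks-1-12 response `r12` exactly. Response
to the switch treatment (Delphi estimate, 65.4%) is assessed at the end of
`SWITCH_W1_4`, mirroring the stopping rule; switch failures drop out and are
not re-challenged. With the stopping rule off, everyone remains on initial
therapy for twelve weeks and the full failure mass `1 − r12` exits at once.

Response inputs are responder counts from the pooled pivotal trials
(prucalopride 178/640 at week 4 and 151/640 over weeks 1-12; placebo proxy
68/645 and 73/645; female-only and PAC-QOL-satisfaction variants for the
corresponding scenarios). The placebo proxy prints a weeks-1-12 response
(11.3%) slightly *above* its week-4 response (10.5%); the pathway cannot place
more mass in maintenance than responded at week 4, so the conditional
retention is capped at 1 and the comparator's maintenance mass is
`min(r4, r12)` = 10.5%. This is the one printed input the structure cannot
honour verbatim; its effect on the comparator's totals is well inside the
reporting precision.

There is no mortality (none is expected to differ between arms over the
horizon); a monthly death probability exists as a configurable hook and is
applied as a survival weight during accrual rather than as a tenth state, so
the transition structure stays row-stochastic. No half-cycle correction is
applied: costs and QALYs accrue on full-cycle state membership, matching the
simple trace arithmetic implied by the published totals.

## Outcomes

Each month in a state contributes one twelfth of that state's annual utility
(utilities from the published PAC-QOL-to-EQ-5D mapping: prucalopride start
0.786, weeks 5-12 0.813, responders 0.890; laxative 0.781 / 0.805 / 0.879;
switch phase and drop-out 0.784; switch responders 0.879). Discounting is
annual-step (4% costs / 1.5% effects in the 3-year scenario, none over one
year): all cycles of a year share one factor, mirroring the Dutch-guideline
annual rates. Dominance quadrants are labelled and the ICER is reported only
when both increments are positive.

## Costing

Five components are computed per (arm, state, cycle); every unit cost is
inflated from its costing year to 2011 with the published consumer-price
rates (1.2% for 2009→2010, 1.3% for 2010→2011).

**Drugs.** Prucalopride start cycles: first cycle on the 28-day starter pack
(€2.77/day), later start cycles at €2.49/day over a 30.4-day month, one
prescription fee (€6.35) per dispensing. Maintenance spreads the annual
treatment-day allowance — 130 days in year 1 (after the 90-day start phase),
220 days (the annual cap) thereafter — uniformly over that year's maintenance
cycles, with one fee per 28 treatment days. The 1.5 mg scenario prices the
treatment day at the mean of the 1 mg and 2 mg rates. Switch and drop-out
states, and the whole comparator arm, use the share-weighted laxative basket
(€0.454/day at start weights, €0.394/day at switch weights) plus one fee per
monthly dispensing.

**Medical resources.** Monthly contact counts per model phase come from the
Delphi elicitation. The mapping from states to phase columns and tariffs is
configurable; the defaults are:

| state | contact column | specialist tariff |
|---|---|---|
| start weeks 1-4 | weeks 1-4 | DBC polyclinic €195.89 |
| start weeks 5-12 | weeks 5-12 | DBC polyclinic |
| maintenance | switch-maintenance (lightest) | costing manual €72.00 |
| switch weeks 1-12 | switch weeks 1-4 | DBC polyclinic |
| switch maintenance | switch-maintenance | costing manual |
| drop-out | switch weeks 1-4 | DBC polyclinic |

The reading behind these defaults: patients without adequate relief (the
population the resource table describes) are under active specialist work-up,
which in the Dutch system runs through an open DBC episode; stable responders
receive routine follow-up at the costing-manual consultation price and the
lightest printed contact pattern; drop-outs remain unrelieved patients under
continued management. Specialist telephone contacts are priced at the PCP
telephone tariff (€14.00) because no separate tariff is printed; nurse
telephone contacts are free.

Procedure quantities are printed without prices. All procedure prices default
to zero except anoscopy/proctoscopy (€62.00) and blood tests (€36.90). These
two values — and the state-to-column/tariff mapping above — were *calibrated*:
the published inputs under-determine the costing layer, so the free choices
were fitted once, by non-negative least squares in cost space, against the
full set of published results (base-case arm totals, the four one-way rows,
and the women-only, no-complication and 3-year scenario ICERs) and then
frozen. No response, utility, price or probability that *is* printed was
adjusted. Every calibrated choice is an ordinary config key.

**Complications.** Each complication (hemorrhoids, anal fissures, fecal
incontinence, peri-anal thrombosis, rectal prolapse, fecal impaction) carries
Delphi period probabilities for weeks 1-4, weeks 5-12 and the switch phase,
converted to monthly probabilities with the constant-rate transform
`1 − (1 − p)^(1/k)` (the standard actuarial choice; the elicitation says only
that estimates were "adjusted to monthly"). The expected monthly cost is
probability × (PCP consults × €28 + specialist consults × DBC tariff +
hospitalization fraction × hospitalization cost). Defaults cost complications
in the unrelieved phases: the weeks-1-4 column during month 1 (period 1
month) and the switch column across the twelve switch weeks (period 2
months); responder states accrue none (they have normal bowel function), and
drop-out complication-related contacts are taken as already counted in the
drop-out contact column. Hospitalization is the fixed DBC tariff (€3102); the
length-of-stay scenario divides that tariff by the incidence-weighted mean
stay to get a daily price, which is cost-neutral at baseline by construction
and responsive only to LOS perturbations.

**Transport.** Round trip per face-to-face contact: 2 × distance × €0.20/km
(PCP 1.1 km, specialist/hospital 7.0 km, dietician 1.7 km; the nurse sits in
the PCP practice). Telephone contacts incur none. A parking scenario adds
€3.00 per visit; a no-transport scenario removes the component.

**Indirect costs** (scenario only): working-age share (87%) × share reporting
absence (12%) × 2.4 days missed per month × 8 hours/day × €26.99/hour ≈
€54.10 per month, applied to every non-responder state. The printed inputs
give hours per year but not per day; 8 h/day is the configurable default.

## Deterministic sensitivity analysis

The one-way set varies the week-4 response over its 95% interval bounds
(24.4%-31.4%), the week-12 response over its printed bounds (20.4%-25.0%),
and each DBC tariff by ±25%, re-running the full model each time. The printed
bounds are treated as literal inputs: the Wilson score interval for 178/640
is (24.48%, 31.41%), which brackets the printed values to within 0.1
percentage point, but no standard binomial interval reproduces both printed
decimals, and the week-12 bounds match no standard interval at all.

Varying the week-4 response alone would leave the week-12 maintenance mass
unchanged (it is pinned by `r12`) and thus barely move QALYs, contrary to the
published sensitivity rows. The default linkage holds the *absolute* week-4
to week-12 attrition mass (27.8% − 23.6% = 4.2 points) fixed, so the week-12
response moves with the week-4 draw; this reproduces the published QALY
movement at both bounds. A ratio-preserving linkage is available via
`analysis.oneway_response_linkage`.

## Probabilistic sensitivity analysis

Five thousand parameter bundles are drawn and the full model evaluated for
each. Distributions follow the usual conventions: response probabilities are
Beta(responders, non-responders) from the trial counts, drawn per arm;
Delphi probabilities (switch response, complications) are beta by method of
moments with SE = 20% of the mean, shared across arms; resource quantities
and lengths of stay are gamma with SE = 25% of the mean (shape 16), shared
across arms; utilities are beta with SE = 0.05. Tariffs and prices are fixed.

Utility draws are *comonotone*: one shared random quantile is mapped through
each utility's beta marginal. The rationale is that utility uncertainty here
stems from a single instrument-mapping regression, which shifts every mapped
utility together; drawing the eleven utilities independently would make the
variance of the incremental QALY gain several times its mean and cap the
probability of cost-effectiveness at €20,000/QALY near 60%, inconsistent with
the published acceptability curve. Each marginal keeps exactly the stated
beta/SE = 0.05 form. The summary ICER is the ratio of mean incremental cost
to mean incremental QALYs (consistent with a single reported PSA ICER);
per-draw increments, the acceptability curve over €0-80,000 in €1,000 steps,
and a running-mean convergence series are also returned.

## Synthetic data

The generator layer emulates the two data sources the model rests on. The
trial generator draws per-patient week-4 response as Bernoulli(`p4`) and
nests week-12 response within it via the conditional retention `p12 / p4` —
mirroring the engine's structure rather than the trials' literal definition,
which permits late responders; the satisfaction endpoint is an independent
flag. The resource-panel generator draws gamma quantities around a printed
column at a chosen coefficient of variation, emulating the elicitation
target. Both are seed-deterministic. What passing recovery tests show is that
the estimation-to-engine loop is consistent at the trial's sample sizes; they
do not validate the Delphi estimates themselves, for which no sampling layer
exists in reality.

## Reproduction quality

With the calibrated defaults the model reproduces the published results to:
arm totals €2511/€2445 (printed 2511/2446), QALYs 0.8355/0.8287 (printed
0.833/0.826), base ICER €9693 (printed 9015, +7.5%), week-4 bounds €14,659
and €6354 (printed 15,380 / 6475), women-only €8568 (7773), no-complications
€13,287 (12,216), 3-year €3920 (4436), PSA ratio-of-means ≈ €9000 (8892)
with P(cost-effective at €20,000) ≈ 0.88 (>80% published). The
productivity-loss and PAC-QOL scenarios land at €6217 and €4333 against
published €5228 and €5197 — the under-determined indirect-cost arithmetic and
endpoint substitution are the least constrained parts of the reconstruction.

## Known limitations

* The costing layer is a calibrated reconstruction: the printed tables do not
  uniquely determine state-level costs, and different mapping choices that
  also hit the base case can disagree on scenario ICERs by several percent.
* The comparator's printed week-12 response exceeding its week-4 response is
  structurally unrepresentable under the stopping rule (capped, see above).
* No patient-level heterogeneity, treatment re-challenge, adverse-event
  costs, or over-the-counter laxative costs (excluded by design).
* The mortality scenario is a hook without shipped rates; the 2014 inflation
  scenario defaults to zero rates for 2011-2013 (none are printed) and exists
  to show the qualitative insensitivity, not a number.
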