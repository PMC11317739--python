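# Methods

## Scope and model overview

The package compares two index-procedure strategies for paroxysmal
atrial fibrillation — radiofrequency ablation first (RFA_first) and
cryoballoon ablation first (CBA_first) — by cost-minimization: clinical
equivalence is taken as given (supported by the meta-analysis engine),
and only costs differ. The model has two phases sharing one model-year
clock:

* a **decision tree** covering years 1–2: index ablation at entry,
  an optional second ablation at 6 months after recurrence, an optional
  third at 18 months after a further recurrence; and
* a **Markov cohort model** in annual cycles from year 2 (year 3 for
  patients who received a third ablation) to a horizon age of 110, over
  the states AF symptom (−), AF symptom (+), ischemic stroke (IS),
  post-IS and dead.

All transition probabilities are identical between strategies; the
strategies differ only in the index procedure's unit cost and
complication profile and in the repeat-procedure technology mix. This
makes every Markov cost bucket *exactly* equal between strategies — a
structural property the tests assert bit-for-bit — so the headline
difference is carried entirely by the tree.

## Decision tree

Stage probabilities use branch probabilities only:

* P(2nd ablation) = p_recur_first × p_reablate_2nd,
* P(3rd ablation) = P(2nd) × min(1, p_recur_first × rr_reablation) ×
  p_reablate_3rd.

The recurrence risk after a repeat procedure is the first-ablation risk
scaled by a relative risk of 1.61, capped at 1 so sensitivity extremes
cannot produce an invalid probability. No mortality attrition is applied
between stages: expected procedure counts deliberately ignore the 1.2%
per-procedure death risk. This, together with the discounting convention
below, is what reproduces the published cost rows to within rounding;
applying attrition moves the intervention rows by several thousand yen.
The interaction of tree-phase deaths with later procedures is therefore
a knowing simplification, not an oversight.

Repeat procedures are a technology mix estimated from claims data
(≥96% RFA regardless of index procedure). The third-stage mix is a
two-step composition: the second-stage mix propagated through the
conditional third-stage proportions.

**Discounting.** Procedures at 0 and 6 months fall in model year 1 and
are undiscounted; the 18-month procedure is discounted one full year.
Generally, a cost in model year *y* carries (1 + r)^−(y−1), r = 2%/year.

**Event buckets.** Serious adverse events comprise six complications
(esophageal injury, tamponade, PV stenosis, phrenic nerve palsy —
cryoballoon only —, vascular, groin), each probability × unit cost per
procedure performed. Per-procedure stroke (0.7%) and death (1.2%) are
separate: stroke costs split fatal/non-fatal at the 28-day case fatality
(7.3%) into their own report rows, and both events shape the Markov
entry state but never the serious-adverse-event row.

**Markov entry.** Stroke survivors enter the IS state regardless of AF
symptoms (stroke dominates). Death and stroke are applied independently
of the recurrence pathway: the AF+ share among non-stroke survivors
equals the unresolved-recurrence probability (declined repeats plus
recurrence after the final permitted ablation). Any alternative
interaction assumption cancels between strategies, so this choice
cannot move the headline difference.

## Markov model

Within a cycle, background death (age- and sex-blended life-table
probability; 67% male mix held fixed over time) resolves first; stroke
and recurrence then compete additively among survivors. Rows are then
exactly stochastic whenever p_IS + p_recurrence ≤ 1, which is validated
each cycle. Recurrence from AF− runs at 7.7%/year in the first two
Markov years (clocked from each sub-cohort's own entry year) and 4.1%
after; AF+ patients undergo no further ablation and cannot revert. The
IS state resolves in one cycle: death = 7.3% + 92.7% × 12.7%, survivors
to post-IS; repeat strokes are not modelled. Post-IS mortality is
max(8.5%, background), so the disease state is never safer than the
general population at high ages. No half-cycle correction is applied;
state costs accrue on start-of-cycle occupancy. Tree-phase stroke
survivors pass through the IS row once but accrue no event costs there
(charged in the tree already); only strokes incident within the Markov
phase are charged the fatal/non-fatal event costs.

## Parameters

All base-case values, including the one-way sensitivity ranges (95% CIs
where the source reports them, otherwise ±20%), live in the bundled
YAML configuration; costs are stored as exact integer JPY, arithmetic is
floating point, and reports render rounded to the yen (halves away from
zero), USD to the dollar at 150 JPY/USD. The sensitivity bounds are
consumed as printed rather than recomputed, and each must bracket its
base value (validated). One mix parameter (third ablation after a
cryoballoon second procedure, base 100%) has no published range and is
not varied. Rows printed as one shared value for both procedures vary
jointly in the DSA; procedure-specific rows vary independently.
Probability bounds that would leave [0, 1] are clipped with a warning.

A note recorded during verification: under the calibrated discounting
convention the discount rate barely touches the headline difference
(only the 18-month procedure is discounted, and its between-strategy
cost difference is ~¥140 scaled by a 3.3% branch probability), and a 0%
rate in fact *shrinks* the difference magnitude by under a yen. The
sensitivity suite asserts the sign and the (negligible) size rather than
a growth direction.

## Life table

No specific national life table is prescribed, so background mortality
defaults to a Gompertz–Makeham fixture, qx(age) = min(1, a + b·e^(c·age))
with a = 5×10⁻⁴, b = 3×10⁻⁵, c = 0.095, male column scaled ×1.6, closed
at qx = 1 by age 110. These values give a 64.6-year-old, 67%-male cohort
a remaining life expectancy near 16 years — a realistic order of
magnitude, but a fixture, not a demographic claim. Consequently the
absolute Markov bucket magnitudes and strategy totals are
fixture-dependent; the difference column, the tree rows and every
structural property are not. Users with a real life table can supply it
as a CSV (`age, qx_male, qx_female`).

## Synthetic study sets

The meta-analysis engine is validated by parameter recovery because the
underlying per-study event counts are not published as text. The
generator draws, per study: a baseline (RFA-arm) risk uniform in
[0.20, 0.45], per-arm sizes uniform in [25, 380], a study-level log risk
ratio Normal(ln RR_true, τ²), and binomial events per arm — the simplest
generative model consistent with the risk-ratio effect measure. Defaults
emulate the published evidence base (18 studies, about two-thirds
randomized). It does not emulate censoring or follow-up heterogeneity
(hazard-ratio inputs are exercised through their closed-form CI
back-calculation instead), selective publication, or arm-size
correlation with effect size — so passing recovery tests demonstrate
correctness of the pooling arithmetic and estimator behaviour under the
stated model, not robustness to those real-data features.

Observed behaviour under the seeded test conditions (k = 40, τ² = 0.04,
large arms, 500 replicates): absolute pooled bias < 0.02 on the log
scale, DerSimonian–Laird 95% CI coverage within 92–98% (DL is known to
run slightly below nominal at moderate k), τ̂² mean within 0.01 of
truth; on homogeneous null sets the fixed-effect CI covers RR = 1 at
95% ± 3% over 1000 replicates.

## Numerical and testing choices

* Pooling arithmetic is checked against a brute-force inverse-variance
  mean to 1e-12 and against statsmodels' `combine_effects` (DL) as an
  external oracle; the two routes are kept independent.
* The tree is checked against a 10⁶-individual vectorized
  microsimulation following the same branch probabilities (agreement
  within 3 Monte-Carlo standard errors on both cost rows, per strategy).
* The Markov engine is checked against the closed-form discounted
  annuity under constant hazard (relative error ≤ 1e-12).
* Continuity correction for zero cells: 0.5 added to all four 2×2 cells
  only when a zero cell occurs; a double-zero study without correction
  is an error, not a silent exclusion.
* Studies with under 6 months of follow-up are excluded; studies with
  undeterminable RFA type stay in the overall pool but are excluded from
  the contact-force subgroup split; no design weighting between RCTs and
  matched cohorts.
* Test problem sizes (500–1000 meta-analysis replicates, 10⁶ microsim
  individuals, 46 Markov cycles) were chosen so the full suite runs in
  seconds while keeping Monte-Carlo error well below the asserted
  tolerances.

## Known limitations

* Cost-minimization by construction: no utilities, QALYs or ICERs, and
  no effectiveness difference is representable.
* No probabilistic sensitivity analysis (one-way only) and no two-way
  interactions.
* Repeat strokes, anticoagulation-dependent stroke risk, and
  differential survival by sex are not modelled.
* The tree's no-attrition accounting slightly overstates late-procedure
  exposure (see above); it is retained as the calibrated convention.
* Absolute lifetime totals inherit the life-table fixture; treat them as
  illustrative unless a real table is supplied.
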