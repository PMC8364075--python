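# Methods

## Model structure

The model is a discrete-time Markov cohort simulation with 3-month
cycles, run from age 60 until cohort extinction (capped at age 120,
where residual mass is sent to death). The state space has 35 states:

- `CN_AN`, `CN_AP_unknown`, `CN_AP_known` — clinically normal, by
  amyloid status and whether PET has identified positivity. Amyloid
  positivity is treated as a biological trait: it survives clinical
  reversion, and so does PET knowledge of it.
- `MCI_AN`, `MCI_AP_unknown`, `MCI_AP_known` — the analogous MCI states.
  The cohort starts here (all-MCI initial condition, split by the
  prevalence of amyloid positivity and, under the PET strategy, by the
  scan's sensitivity/specificity).
- `MILD_undet_{annual,quarterly}_k`, k = 1…12 — undetected mild AD
  tunnel states indexed by cycles since onset, duplicated by the
  follow-up schedule the patient carried as an MCI patient (annual
  follow-up, or quarterly for PET-identified AP patients). The tunnel
  length K = detection cap / cycle length = 12.
- `MILD_treated`, `MOD_treated`, `SEV_treated` — detected (treated) AD.
  Moderate and severe AD are detected immediately on entry.
- `NONAD_exit` (non-AD dementia, absorbing, accrues nothing) and
  `DEATH`.

## Transition composition

Published transition probabilities are marginal annual values with no
stated joint structure. Each is converted to a per-cycle probability
under a constant hazard, `p_c = 1 − (1 − p_a)^(1/4)`, after any relative
risk adjustment on the annual scale. Within a row:

1. Death is applied first: `q = 1 − (1 − qx)^(m/4)` with life-table `qx`
   at floor(age) and excess-mortality multiplier m (1 except moderate
   2.57, severe 7.82).
2. The surviving mass is split among clinical destinations using the
   independently converted per-cycle probabilities, renormalised only if
   they sum above one; the residual stays in place.
3. Tunnel rows are composed hierarchically: death, then untreated
   worsening (mild→moderate 0.3220, mild→severe 0.0420 annual, no
   treatment adjustment), then detection applied to the mass that is
   still mild — with per-cycle hazard cycle/interval (0.25 under annual
   follow-up, 1.0 under quarterly), forced to 1 at k = K. Detection is
   a labelling event, not a clinical transition: composing it this way
   keeps clinical-tier dynamics exactly independent of the follow-up
   schedule, which is what makes the null-treatment invariant (below)
   hold to machine precision rather than approximately.

Matrices are rebuilt when the cohort's integer age increments (every 4
cycles) and are validated to be row-stochastic within 1e-12.

The detection hazard models visits as a constant per-cycle rate rather
than calendar-synchronised appointments; a cohort model cannot carry
individual visit phase, and the expected detection delay matches a
uniformly phased population.

## Strategies

Both arms share the natural history. Current practice: annual follow-up
for all MCI, quarterly for detected AD, no scan. PET strategy: one scan
at baseline (sensitivity 0.92, specificity 1.0, cost $1,041 charged
undiscounted at t = 0), quarterly follow-up for identified AP MCI.
False-negative AP patients keep annual follow-up and receive no
intervention effect — benefits are tied to being identified. The
optional "virtual intervention effect" (base 1, sensitivity bound 0.95)
multiplies only the identified-AP conversion probability.

## Economics

Utilities (0.874 CN, 0.80 MCI, 0.43/0.21/0.17 mild/moderate/severe AD)
and annual management costs (medical + non-medical, 2017 USD) attach to
the clinical tier regardless of detection, because the sources publish
one value per severity tier; the only detection-dependent cost is the
follow-up visit ($27/visit × cycle/interval visits per cycle,
fractional visits accruing smoothly). Accrual uses half-cycle
correction (mean of start- and end-of-cycle occupancy) discounted at
the cycle midpoint at 5 %/year. `NONAD_exit` and `DEATH` accrue
nothing.

The comparison reports ΔCost, ΔQALY and, when both deltas share a sign,
the ICER; otherwise a dominance label. `compare()` takes an optional
`qaly_tol` that treats |ΔQALY| below it as zero, for configurations
where the two arms are analytically identical and the difference is
round-off.

## Sensitivity analysis

One-way analysis reruns the full two-strategy pipeline at each bound of
each published range, holding everything else at base: prevalence
(0.3617–0.5556), conversion RR (3.53–15.20), PET cost (520–1561),
visit cost (14–41), treatment RR (0.70–0.93), intervention effect
(0.95–1), start age (60–80), and ±50 % on each tier's combined annual
management cost (medical and non-medical scaled jointly, preserving
their ratio). Entries are ordered by the absolute span between the two
ICERs, dominance-labelled or errored entries last, ties broken by
name. A start-age run simply enters the life table later.

## Evidence synthesis

The treatment RR (0.85) and the conversion RR (7.95) are consumed by
the model as point-estimate inputs; the `evidence` module reproduces
the arithmetic that produces such inputs from study-level 2×2 counts:
per-study risk ratio with SE of the log
`sqrt(1/e_t − 1/n_t + 1/e_c − 1/n_c)`, a continuity correction of +0.5
on all four counts when any cell is zero, and fixed-effect pooling by
inverse-variance weighting of log RRs (Mantel–Haenszel available as an
option; the two agree closely in practice). Cochran's Q and its
p-value are reported but never acted upon. The underlying trial counts
are not published and are not shipped.

## Synthetic life table

Background mortality requires a single-year national life table, which
is not redistributable here. The generator substitutes a Gompertz
curve `qx(age) = 1 − exp(−a·e^{b(age−60)})` with defaults a = 0.0045,
b = 0.095: qx(60) = 0.0045 and mortality doubling every ~7.3 years,
the magnitude and slope of 2010s East-Asian national tables (remaining
life expectancy at 60 ≈ 25 years). It is deliberately smooth — no
period effects, no accident hump, no old-age deceleration — so results
on it demonstrate model behaviour, not any country's published
numbers; reproducing those requires supplying the corresponding
national life-table CSV. The table is closed with qx = 1 at its final
age so the cohort is always extinguished.

Default run sizes: a base-case run is 241 cycles (60 years of 3-month
cycles) over 35 states; the full tornado is 44 cohort runs. The test
suite validates the trace against a 200,000-patient individual-level
Monte-Carlo simulator at cycles 4, 40 and 120.

## Numerical choices and invariants

- Row sums checked to 1e-12 at construction; occupancy conservation to
  1e-9 along the trace; extinction threshold 1e-9 of living mass.
- Products of probabilities and relative risks are clamped to [0, 1]
  (annual scale, before cycle conversion).
- Key analytic invariants, all enforced by tests: with treatment RR = 1
  and intervention effect = 1 the two arms have identical clinical-tier
  occupancy and PET is strictly dominated; ΔQALY is non-increasing in
  treatment RR; conversion RR = 1 collapses the AP/AN asymmetry; the
  annual↔cycle conversion round-trips exactly; a one-way entry with
  both bounds at base reproduces the base ICER bit-for-bit.

## Known limitations

- No probabilistic sensitivity analysis (one-way only, matching the
  analysis design this model implements).
- No individual-level heterogeneity beyond amyloid status; no repeat
  scanning; non-AD dementia is a costless absorbing exit.
- Whether annually followed MCI patients' visit costs accrue before AD
  detection was an open design point; this implementation charges them
  in both arms, which does not differentially advantage either
  strategy.
- The tunnel's detection hazard is schedule-dependent but memoryless
  within a cycle; calendar-synchronised visit timing would need an
  individual-level model.
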