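# Methods

## The costing model

Each treatment episode is costed from the service's perspective as
medication plus adviser time. Nothing else is included: central overheads
and user out-of-pocket costs (travel, childcare, lost work) are excluded
by construction, and no inflation adjustment is applied — all prices are
2015–16 figures, shipped in `src/quitcost/data/costs.yaml` and overridable
per run for other price years.

**Medication.** Every treatment/prescription-route combination has a
chronological dose pattern covering at most 12 weeks of service use (the
window over which the 12-week quit outcome is defined), with a price per
dose. A record's `k` dispensed doses are matched to the *first* `k`
pattern entries in chronological order — the only reading consistent with
a chronological dosing pattern when dose durations vary (varenicline
non-pharmacy and bupropion have 2-, then 4-week packs). Dose counts
recorded above the pattern maximum are capped at it, so courses recorded
beyond the standard treatment timeframe are not costed. Varenicline's
pre-quit prescription window (it is issued 8–14 days before the quit date)
is treated as inside the costed timeframe: the cap is on dose count, not
on calendar arithmetic, so the first pattern dose is always costable.

**Adviser time.** The "total contact time" variable is priced as-is at a
flat itemised hourly charge totalling £26.32 (the five components sum to
the total exactly, which the tests assert). No truncation is applied to
contact time beyond the recorded total, and the longer introductory
session is not separately priced — one flat rate throughout.

**Arithmetic.** All money is exact decimal GBP. The single rounding step
is half-up to the penny on each record's adviser cost; medication sums are
exact by construction. Group totals are therefore identical under any
partition of the cohort into subgroups, which is what lets per-factor
tables reconcile against the overall total to the penny.

## Exclusion rules

Raw service extracts contain episodes that cannot be analysed. Three
rules run in a fixed, logged order, attributing each removal to the first
matching rule so the counts always partition the input:

1. **date cutoff** — quit dates *strictly after* the cutoff (default
   2015-12-09) are removed: their 12-week outcome window was not complete
   at data compilation. The boundary date itself is retained. The cutoff
   is a parameter.
2. **pregnant** — pregnant users are served by a separate specialist
   pathway and are excluded from this costing.
3. **treatment count** — episodes with no, or more than one, recorded
   pharmacotherapy are presumed misrecorded and removed.

Repeat episodes by the same client are deliberately retained: the unit of
analysis is the treatment episode. Missing FTND or IMD never excludes a
record; it only drops the record from that factor's subgroup table, which
is why FTND/deprivation band counts sum to less than the cohort while
their percentages (computed over non-missing denominators) sum to 100.

## Covariate recoding

Age is banded 12–19 / 20–29 / 30–49 / 50–69 / 70+ (the first band covers
all ages ≤ 19; no service user is younger than 12). FTND is accepted on
the full 0–10 instrument range and banded 0–3 / 4–5 / 6–7 / 8–10. The raw
IMD decile (1 = most deprived) is inverted first — `11 − raw`, a
self-inverse map — so that a higher score reads as more deprived, then
banded 1–3 / 4–6 / 7–8 / 9–10 on the inverted scale.

## The bootstrap interval

The CPQ is a ratio of totals with two coupled sources of uncertainty: the
cost distributions within the quit/no-quit groups and the quit proportion
itself. The interval therefore resamples whole records with replacement
(N draws, N = group size; cost and quit status stay paired), recomputes
the CPQ per replicate, and reports empirical percentiles (linear
interpolation between order statistics) at 2.5% and 97.5%. Defaults:
1000 replicates, configurable upward.

Numerical choices worth knowing:

* **Zero-quit replicates** contribute +inf to the replicate distribution
  rather than being redrawn — redrawing would bias the upper tail
  downward. Percentiles stay finite while fewer than 2.5% of replicates
  are degenerate; the condition is logged when it occurs, and an interval
  with an infinite upper bound is reported honestly when it does not hold.
  Interpolating between two infinite order statistics is defined as +inf.
* **Substreams.** Each subgroup's resampling uses an independent random
  substream derived from the run seed and a stable hash of
  "factor/band", so adding or removing a factor never perturbs another
  factor's interval, and runs are bit-reproducible per seed.
* The percentile interval of a ratio need not contain the point estimate
  in pathological cases, so the code asserts only `lower ≤ upper`.

## The synthetic cohort generator

The generator exists so the pipeline and its statistical properties can be
exercised with known ground truth. Its default profile is calibrated to
the reference service cohort's published margins: treatment shares
0.801/0.187/0.004 (renormalised), 12-week quit probabilities 0.287 (NRT),
0.468 (varenicline), 0.543 (bupropion), the published age, gender, FTND
and deprivation compositions, FTND recorded for ~64% and IMD for ~90% of
records, and injection rates for excludable records matching the published
pre-exclusion marginals (12.4% late-dated, 5.1% pregnant, 27.1% no/multi
treatment).

Where the reference publishes no distribution, the defaults are chosen
once as realistic and fixed:

* **dose counts** per schedule follow a truncated-geometric pmf on
  0..max+3 (decay 0.80 for NRT, 0.95 for varenicline, 0.75 for
  bupropion) — monotone dropout-like decay whose support deliberately
  overshoots the cap so capping is exercised;
* **contact minutes** are truncated-normal on [0, 300] minutes, sd 40,
  with per-schedule means (NRT 103.8, varenicline 126.1/124.2 by route,
  bupropion 132.1) solved so each arm's implied expected cost per head
  lands on its published value (≈£115.31 / £193.23 / £122.99);
* **varenicline prescription route** splits 50/50 pharmacy/other;
* factors are drawn **independently** — the reference gives margins only.
  Quit probability depends on treatment alone by default; optional
  additive logit-scale adjustments per band can emulate age or dependence
  gradients.

Because every distribution is known, `true_cpq(profile, band)` returns
the population value `E[cost | band] / P(quit | band)` in closed form
(the truncated-normal mean is evaluated exactly; the per-record penny
rounding of adviser cost, a bias below half a penny, is ignored). The
test suite uses this for parameter recovery (sample CPQ within 2% of
truth for arms with ≥10% share, pooled over four n = 50,000 cohorts so the
bound sits beyond three standard errors) and interval coverage (the 95%
interval covers the true overall CPQ in 92–98% of 500 independent
simulated cohorts of 2000 raw episodes — sized to keep the check well
within a few minutes on one CPU).

What passing these tests does *not* show: behaviour under correlated
covariates, within-client dependence across repeat episodes, region
effects, or cost distributions unlike the calibrated ones — the generator
emulates margins, not the joint structure of real service data.

## ROI scenario parameters

For downstream return-on-investment modelling, each treatment arm
contributes its **uptake share** (arm count / cohort size) and **cost per
user** (arm total cost / arm count — cost per head regardless of quit
status), both computed from the costed cohort, plus a **relative 12-month
abstinence rate** against an untreated baseline (default 4%), which comes
from the external model's literature and is passed through from
configuration (defaults 2.14 / 2.24 / 1.6). The scenario file is a small
hand-editable YAML rather than any external tool's native format.

`expected_quitters_per_1000` composes these as
`1000 × baseline × Σ uptake × relative rate` and is exposed so the
arithmetic can be audited: published evaluations sometimes report headline
quitter counts computed under a different, undocumented denominator
convention, and such figures are not reproducible from these three
parameters alone — this package reports only what its stated formula
computes. Long-horizon outputs (QALYs, benefit–cost ratios) belong to the
external model and are out of scope; 12-month relapse assumptions are
carried as scenario metadata only.

## Known limitations

* Costs reflect one provider's 2015–16 price book; the config override is
  the supported route for other settings.
* The quit outcome is self-reported at 12 weeks, with all the usual
  caveats of routinely collected service data.
* NRT is priced as a single flat weekly combination rate; product-level
  NRT variation is not modelled.
* The generator's independence assumptions mean synthetic subgroup
  gradients (beyond treatment) are flat unless logit adjustments are
  supplied.
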