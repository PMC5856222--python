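# quitcost

Cost-per-quit analysis for smoking-cessation services.

Stop-smoking services support quit attempts with adviser sessions and
pharmacotherapy (nicotine replacement therapy, varenicline or bupropion).
Commissioners want to know what one successful quit costs in routine
practice, not just in trials. `quitcost` implements that analysis as a
tested, reusable pipeline over routinely collected service records: it
derives each treatment episode's cost from its dose schedule and adviser
contact time, filters the raw records to an analysable cohort, estimates
the cost-per-quit ratio with bootstrap confidence intervals overall and by
subgroup, and prepares the per-arm parameters a return-on-investment model
needs. A calibrated synthetic-cohort generator with closed-form ground
truth makes every stage testable without access to any real service data.

The package is aimed at health economists and public-health analysts
working with service-level stop-smoking data in Python.

## The statistic

For a group of `N` treatment episodes with total service cost `T` (summed
over quitters and non-quitters alike) and `n_quit` successful self-reported
12-week quits,

```
CPQ = T / n_quit
```

Each episode's cost has two parts:

* **medication** — the dispensed dose count `k`, capped at the schedule
  maximum, priced against the treatment's chronological dose pattern
  (NRT: 12 × 1-week doses at £19.95; varenicline via pharmacy: 6 × 2-week
  at £38.40; varenicline via other routes: 2+2+4+4 weeks at
  £38.40/£38.40/£76.80/£76.80; bupropion: 2+2+4 weeks at
  £34.73/£34.73/£69.45 — 2015–16 prices incl. prescription and VAT);
* **adviser time** — total contact minutes at an itemised £26.32/hour
  (adviser £23.65, room £0.20, equipment £0.49, travel £0.74, advertising
  £1.24), rounded half-up to the penny per record.

The CPQ's uncertainty couples the cost distribution with the quit
proportion, so the 95% interval resamples whole records with replacement
(cost and quit status kept together), recomputes CPQ per replicate
(1000 by default) and takes the 2.5th/97.5th percentiles. Subgroup tables
(age band, gender, treatment, FTND dependence band, inverted-IMD
deprivation band) run the same procedure within each band on independent,
seed-derived random substreams.

## Worked example

`examples/synthetic_cpq_analysis.py` draws 12,000 raw episodes from the
calibrated default profile, applies the exclusion rules and estimates CPQ:

```
raw episodes:      12000
removed per rule:  {'date_cutoff': 1434, 'pregnant': 557, 'treatment_count': 2743}
analysis cohort:   7266

                level     n total_cost cost_per_head n_quits quit_rate             mean_cpq_ci
              overall 7,266 955,747.08        131.54   2,401     33.04 398.06 (384.96, 413.89)
        treatment:NRT 5,831 685,403.70        117.54   1,678     28.78 408.46 (391.19, 427.43)
treatment:varenicline 1,406 266,765.38        189.73     705     50.14 378.39 (358.19, 400.20)
  treatment:bupropion    29   3,578.00        123.38      18     62.07 198.78 (139.89, 298.07)

analytic (population) CPQ implied by the generator profile:
  overall                  £403.63
  treatment:NRT            £401.78
  treatment:varenicline    £412.88
  treatment:bupropion      £226.50
```

Reading the overall row: the 7,266 retained episodes cost £955,747 in
total (£131.54 per head); 2,401 users (33.0%) reported quitting at 12
weeks, so each quit cost £398.06 on average, with a 95% bootstrap interval
of £384.96–£413.89 that covers the population value (£403.63) implied by
the generating profile. The bupropion row illustrates why rare-arm
estimates are indicative only: ~0.4% of the cohort receives it.

The other examples cost a single episode step by step
(`examples/cost_one_episode.py`) and derive ROI scenario parameters —
per-arm uptake share, cost per user, relative abstinence — plus the
projected quitters per 1000 treated smokers
(`examples/roi_scenario.py`).

A thin CLI wraps the same functions:

```
quitcost simulate --n 9116 --seed 42 --out cohort.csv
quitcost run --input cohort.csv --factors age,gender,treatment,ftnd,deprivation \
             --boot 1000 --seed 20160313 --out results/
quitcost roi-params --input cohort.csv --rates NRT=2.14,varenicline=2.24,bupropion=1.6 \
             --out scenario.yaml
```

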