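# Unit costs and dose schedules for the 2015-2016 financial year.
# Prices are GBP, include prescription charge and VAT, and are stored as
# strings so they load as exact decimals.
version: "2015-2016"

# Itemised adviser contact charge, GBP per hour of contact time.
hourly_components:
  adviser: "23.65"
  room: "0.20"
  equipment: "0.49"
  travel: "0.74"
  advertising: "1.24"

# Chronological dose packs covering up to 12 weeks of service use.
# dose_pattern_weeks[i] is the duration covered by dose i+1;
# price_per_dose[i] is what that dose costs.  A record's dispensed dose
# count is capped at max (= length of the pattern) when costing.
schedules:
  - treatment: NRT
    pathway: all
    dose_pattern_weeks: [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
    price_per_dose: ["19.95", "19.95", "19.95", "19.95", "19.95", "19.95",
                     "19.95", "19.95", "19.95", "19.95", "19.95", "19.95"]
  - treatment: varenicline
    pathway: pharmacy
    dose_pattern_weeks: [2, 2, 2, 2, 2, 2]
    price_per_dose: ["38.40", "38.40", "38.40", "38.40", "38.40", "38.40"]
  - treatment: varenicline
    pathway: other
    dose_pattern_weeks: [2, 2, 4, 4]
    price_per_dose: ["38.40", "38.40", "76.80", "76.80"]
  - treatment: bupropion
    pathway: all
    dose_pattern_weeks: [2, 2, 4]
    price_per_dose: ["34.73", "34.73", "69.45"]
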