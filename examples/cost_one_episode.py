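"""Cost a single treatment episode from its dose count and contact time.

Builds one service record — a varenicline user prescribed through a
pharmacy, six two-week dose packs dispensed, 105 minutes of adviser
contact — and prints the cost breakdown the analysis assigns to it.
"""

import datetime

from quitcost import ServiceRecord, cost_record, dose_schedule

record = ServiceRecord(
    client_id="EX0001",
    quit_date=datetime.date(2015, 5, 4),
    pregnant=False,
    treatments=frozenset({"varenicline"}),
    pathway="pharmacy",
    doses_dispensed=6,
    contact_minutes=105.0,
    quit_12wk=1,
    age_years=34,
    gender="male",
    ftnd=6,
    imd_raw=3,
    region="Walsall",
)

schedule = dose_schedule("varenicline", "pharmacy")
costed = cost_record(record)

print(f"dose pattern (weeks):    {schedule.dose_pattern}")
print(f"price per dose (GBP):    {tuple(map(str, schedule.price_per_dose))}")
print(f"doses costed:            {costed.doses_costed} "
      f"(dispensed {record.doses_dispensed}, cap {schedule.max_doses})")
print(f"medication cost:         £{costed.medication_cost}")
print(f"adviser cost:            £{costed.adviser_cost} "
      f"({record.contact_minutes:.0f} min at £26.32/h)")
print(f"total episode cost:      £{costed.total_cost}")

# The medication part is six £38.40 packs; the adviser part is
# 105/60 hours at the itemised £26.32 hourly charge, rounded to the penny.
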