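"""Per-episode service costs: pharmacotherapy dose packs plus adviser time.

Each episode's cost has two parts.  Medication cost follows the treatment's
chronological dose schedule: the k dispensed doses are matched to the first
k pattern entries, and k is capped at the schedule maximum so that nothing
beyond the standard 12-week course is costed.  Adviser cost is total contact
minutes priced at a flat itemised hourly charge (adviser time, room,
equipment, travel, advertising).

All money is exact decimal GBP; the only rounding is half-up to the penny
on the adviser cost at record level, so cohort totals reconcile exactly
under any partition into subgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import IO, Iterable, Mapping, Sequence

import yaml

from .errors import ConfigurationError, ValidationError
from .records import ServiceRecord

logger = logging.getLogger(__name__)

PENNY = Decimal("0.01")

#: Full support window; dose patterns never cover more than this.
MAX_WEEKS = 12


def money(value: Decimal | int | str) -> Decimal:
    """Quantize to the penny, rounding half-up."""
    return Decimal(value).quantize(PENNY, rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class CostSchedule:
    """The chronological dose pattern and prices for one treatment/pathway.

    ``dose_pattern`` holds each dose's duration in weeks; ``price_per_dose``
    is aligned with it.  ``max_doses`` is the pattern length: dispensed dose
    counts above it are capped when costing.
    """

    treatment: str
    pathway: str  # "pharmacy", "other" or "all"
    dose_pattern: tuple[int, ...]
    price_per_dose: tuple[Decimal, ...]

    def __post_init__(self) -> None:
        if len(self.dose_pattern) != len(self.price_per_dose):
            raise ValidationError(
                "dose_pattern and price_per_dose must have equal length")
        if sum(self.dose_pattern) > MAX_WEEKS:
            raise ValidationError(
                f"dose pattern covers {sum(self.dose_pattern)} weeks; "
                f"maximum is {MAX_WEEKS}")
        if any(p < 0 for p in self.price_per_dose):
            raise ValidationError("dose prices must be >= 0")

    @property
    def max_doses(self) -> int:
        return len(self.dose_pattern)

    def cumulative_price(self, k: int) -> Decimal:
        """Cost of the first ``min(k, max_doses)`` doses."""
        k = min(k, self.max_doses)
        return sum(self.price_per_dose[:k], Decimal("0.00"))


@dataclass(frozen=True)
class CostRate:
    """The itemised hourly charge for adviser contact time (GBP/hour)."""

    hourly_components: Mapping[str, Decimal]

    @property
    def hourly_total(self) -> Decimal:
        return sum(self.hourly_components.values(), Decimal("0.00"))


@dataclass(frozen=True)
class CostedRecord:
    """A service record together with its derived costs."""

    record: ServiceRecord
    medication_cost: Decimal
    adviser_cost: Decimal
    total_cost: Decimal
    doses_costed: int

    def __post_init__(self) -> None:
        if self.total_cost != self.medication_cost + self.adviser_cost:
            raise ValidationError("total_cost must equal medication + adviser")
        if min(self.medication_cost, self.adviser_cost) < 0:
            raise ValidationError("costs must be >= 0")


def _parse_config(doc: dict) -> tuple[CostRate, dict[tuple[str, str], CostSchedule]]:
    try:
        rate = CostRate(hourly_components={
            k: Decimal(str(v)) for k, v in doc["hourly_components"].items()
        })
        schedules: dict[tuple[str, str], CostSchedule] = {}
        for entry in doc["schedules"]:
            sched = CostSchedule(
                treatment=entry["treatment"],
                pathway=entry["pathway"],
                dose_pattern=tuple(int(w) for w in entry["dose_pattern_weeks"]),
                price_per_dose=tuple(Decimal(str(p))
                                     for p in entry["price_per_dose"]),
            )
            schedules[(sched.treatment, sched.pathway)] = sched
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed cost config: {exc}") from None
    return rate, schedules


def load_cost_config(
    source: str | IO[str] | None = None,
) -> tuple[CostRate, dict[tuple[str, str], CostSchedule]]:
    """Load the hourly rate and dose schedules.

    With no argument, loads the packaged 2015-2016 defaults; otherwise reads
    the same YAML layout from a path or stream, allowing callers to re-cost
    under different price years.
    """
    if source is None:
        text = resources.files("quitcost.data").joinpath("costs.yaml").read_text()
        doc = yaml.safe_load(text)
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    return _parse_config(doc)


_DEFAULT_RATE, _DEFAULT_SCHEDULES = load_cost_config()


def default_cost_rate() -> CostRate:
    """The packaged 2015-2016 itemised hourly charge (totals £26.32/hour)."""
    return _DEFAULT_RATE


def default_schedules() -> dict[tuple[str, str], CostSchedule]:
    return dict(_DEFAULT_SCHEDULES)


def schedule_key(treatment: str, pathway: str) -> tuple[str, str]:
    """Resolve (treatment, pathway) to a schedule table key.

    Only varenicline's schedule depends on the prescription route; the other
    treatments use their "all"-pathway schedule.
    """
    if treatment == "varenicline":
        return (treatment, "pharmacy" if pathway == "pharmacy" else "other")
    return (treatment, "all")


def dose_schedule(
    treatment: str,
    pathway: str = "other",
    schedules: Mapping[tuple[str, str], CostSchedule] | None = None,
) -> CostSchedule:
    """Look up the dose schedule for a treatment and prescription route."""
    table = _DEFAULT_SCHEDULES if schedules is None else schedules
    key = schedule_key(treatment, pathway)
    if key not in table:
        raise ValidationError(f"no dose schedule for treatment={treatment!r}, "
                              f"pathway={pathway!r}")
    return table[key]


def medication_cost(record: ServiceRecord, schedule: CostSchedule) -> Decimal:
    """Price the dispensed doses against the schedule, capped at its maximum.

    Doses are matched to the first k pattern entries in chronological order,
    k = min(dispensed, max), so courses recorded beyond the standard
    treatment timeframe are not costed.
    """
    if len(record.treatments) != 1:
        raise ValidationError(
            f"record {record.client_id!r} has {len(record.treatments)} "
            "treatments; cost requires exactly one")
    if record.treatment != schedule.treatment:
        raise ValidationError(
            f"schedule is for {schedule.treatment!r} but record has "
            f"{record.treatment!r}")
    return schedule.cumulative_price(record.doses_dispensed)


def adviser_cost(contact_minutes: float, rate: CostRate | None = None) -> Decimal:
    """Price total contact time at the itemised hourly charge.

    Rounded half-up to the penny at the record level; this is the only
    rounding in the costing chain.
    """
    if contact_minutes < 0:
        raise ValidationError("contact_minutes must be >= 0")
    if rate is None:
        rate = _DEFAULT_RATE
    exact = Decimal(str(contact_minutes)) / Decimal(60) * rate.hourly_total
    return money(exact)


def cost_record(
    record: ServiceRecord,
    rate: CostRate | None = None,
    schedules: Mapping[tuple[str, str], CostSchedule] | None = None,
) -> CostedRecord:
    """Derive one record's medication, adviser and total cost."""
    sched = dose_schedule(record.treatment, record.pathway, schedules)
    med = medication_cost(record, sched)
    adv = adviser_cost(record.contact_minutes, rate)
    return CostedRecord(
        record=record,
        medication_cost=med,
        adviser_cost=adv,
        total_cost=med + adv,
        doses_costed=min(record.doses_dispensed, sched.max_doses),
    )


def cost_records(
    records: Sequence[ServiceRecord],
    rate: CostRate | None = None,
    schedules: Mapping[tuple[str, str], CostSchedule] | None = None,
) -> list[CostedRecord]:
    """Cost every record in the (post-exclusion) cohort."""
    costed = [cost_record(r, rate, schedules) for r in records]
    total = sum((c.total_cost for c in costed), Decimal("0.00"))
    logger.info("costed %d records, total £%s", len(costed), total)
    return costed
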