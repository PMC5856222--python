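"""Service-user treatment episodes: parsing, validation and exclusion filtering.

One record is one treatment episode at a stop-smoking service: the client's
demographics, the pharmacotherapy dispensed, total adviser contact time over
the (up to) 12-week support window, and the self-reported quit status at 12
weeks.  Repeat episodes by the same client are deliberately kept as separate
records — the analysis is of episodes, not people.

The exclusion filter removes, in a fixed and logged order, episodes that
cannot be costed or assessed: quit dates too close to data compilation for
the 12-week outcome to be complete, pregnant clients (served by a separate
specialist pathway), and episodes with no or several pharmacotherapies
recorded (presumed misrecording).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

TREATMENTS = ("NRT", "varenicline", "bupropion")
PATHWAYS = ("pharmacy", "other")
GENDERS = ("male", "female")

#: Last quit date retained by default: 12 weeks + margin before the data
#: compilation date, so every retained episode has a complete outcome window.
DEFAULT_CUTOFF = datetime.date(2015, 12, 9)

#: Exclusion rules in application order; a record is attributed to the first
#: rule that matches and never counted again.
EXCLUSION_RULES = ("date_cutoff", "pregnant", "treatment_count")

#: Logical field -> default CSV column name.
DEFAULT_COLUMNS = {
    "client_id": "client_id",
    "quit_date": "quit_date",
    "pregnant": "pregnant",
    "treatments": "treatments",
    "pathway": "pathway",
    "doses_dispensed": "doses_dispensed",
    "contact_minutes": "contact_minutes",
    "quit_12wk": "quit_12wk",
    "age_years": "age_years",
    "gender": "gender",
    "ftnd": "ftnd",
    "imd_raw": "imd_raw",
    "region": "region",
}

#: Fields that may be blank in the input and stay missing in the record.
OPTIONAL_FIELDS = ("ftnd", "imd_raw")

#: Separator for multi-treatment cells in CSV round trips.
TREATMENT_SEP = ";"


@dataclass(frozen=True)
class ServiceRecord:
    """One treatment episode.

    ``treatments`` may be empty or hold several names before exclusion
    filtering; the costed analysis cohort always has exactly one.
    ``pathway`` only matters for varenicline, whose dose pack pattern differs
    between pharmacy dispensing and other prescription routes.  ``ftnd`` is
    the Fagerstrom Test for Nicotine Dependence score (0-10, higher = more
    dependent); ``imd_raw`` is the Index of Multiple Deprivation decile on
    the raw scale where 1 = most deprived.
    """

    client_id: str
    quit_date: datetime.date
    pregnant: bool
    treatments: frozenset[str]
    pathway: str
    doses_dispensed: int
    contact_minutes: float
    quit_12wk: int
    age_years: int
    gender: str
    ftnd: int | None
    imd_raw: int | None
    region: str

    def __post_init__(self) -> None:
        if self.quit_12wk not in (0, 1):
            raise ValidationError(
                f"quit_12wk must be 0 or 1, got {self.quit_12wk!r}")
        if not self.treatments <= set(TREATMENTS):
            unknown = self.treatments - set(TREATMENTS)
            raise ValidationError(f"unknown treatment(s): {sorted(unknown)}")
        if self.pathway not in PATHWAYS:
            raise ValidationError(f"pathway must be one of {PATHWAYS}, "
                                  f"got {self.pathway!r}")
        if self.gender not in GENDERS:
            raise ValidationError(f"gender must be one of {GENDERS}, "
                                  f"got {self.gender!r}")
        if self.doses_dispensed < 0:
            raise ValidationError("doses_dispensed must be >= 0")
        if self.contact_minutes < 0:
            raise ValidationError("contact_minutes must be >= 0")
        if self.age_years < 0:
            raise ValidationError("age_years must be >= 0")
        if self.ftnd is not None and not 0 <= self.ftnd <= 10:
            raise ValidationError(f"ftnd must be in 0..10, got {self.ftnd}")
        if self.imd_raw is not None and not 1 <= self.imd_raw <= 10:
            raise ValidationError(
                f"imd_raw must be in 1..10, got {self.imd_raw}")

    @property
    def treatment(self) -> str:
        """The single recorded treatment; only valid after exclusions."""
        if len(self.treatments) != 1:
            raise ValidationError(
                f"record {self.client_id!r} has {len(self.treatments)} "
                "treatments; exclusions not applied?")
        return next(iter(self.treatments))


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping for one pass of :func:`apply_exclusions`.

    ``n_removed_by_rule`` attributes every removed record to the *first*
    matching rule in ``rule_order``, so the counts always partition the
    input: ``n_input == n_retained + sum(n_removed_by_rule.values())``.
    """

    n_input: int
    n_removed_by_rule: Mapping[str, int]
    n_retained: int
    rule_order: tuple[str, ...] = EXCLUSION_RULES
    cutoff_date: datetime.date = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        removed = sum(self.n_removed_by_rule.values())
        if self.n_input != self.n_retained + removed:
            raise ValidationError(
                f"exclusion counts do not partition the input: "
                f"{self.n_input} != {self.n_retained} + {removed}")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_by_rule": dict(self.n_removed_by_rule),
            "n_retained": self.n_retained,
            "rule_order": list(self.rule_order),
            "cutoff_date": self.cutoff_date.isoformat(),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def _parse_bool(raw: str, row: int, column: str) -> bool:
    val = raw.strip().lower()
    if val in ("1", "true", "yes", "y"):
        return True
    if val in ("0", "false", "no", "n"):
        return False
    raise ValidationError(f"row {row}: cannot parse {column}={raw!r} as boolean")


def _parse_int(raw: str, row: int, column: str) -> int:
    try:
        return int(raw.strip())
    except ValueError:
        raise ValidationError(
            f"row {row}: cannot parse {column}={raw!r} as integer") from None


def read_records(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[ServiceRecord]:
    """Read service records from delimited text with a header row.

    ``column_map`` maps logical field names (keys of ``DEFAULT_COLUMNS``) to
    the column names actually present in the file; unmapped fields use the
    default names.  Blank cells in the optional ``ftnd`` / ``imd_raw``
    columns become missing values; blank cells elsewhere are errors.
    Dates must be ISO-8601 (YYYY-MM-DD).
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(
                f"column_map has unknown logical fields: {sorted(unknown)}")
        colmap.update(column_map)

    frame = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in colmap.values() if c not in frame.columns]
    if missing_cols:
        raise ConfigurationError(
            f"input is missing required column(s): {missing_cols}")

    records: list[ServiceRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        cell = {f: getattr(row, colmap[f]) for f in colmap}
        try:
            quit_date = datetime.date.fromisoformat(cell["quit_date"].strip())
        except ValueError:
            raise ValidationError(
                f"row {i}: cannot parse quit_date={cell['quit_date']!r} "
                "as ISO-8601 date") from None
        treatments = frozenset(
            t.strip() for t in cell["treatments"].split(TREATMENT_SEP)
            if t.strip()
        )
        pathway = cell["pathway"].strip() or "other"
        try:
            rec = ServiceRecord(
                client_id=cell["client_id"].strip(),
                quit_date=quit_date,
                pregnant=_parse_bool(cell["pregnant"], i, "pregnant"),
                treatments=treatments,
                pathway=pathway,
                doses_dispensed=_parse_int(cell["doses_dispensed"], i,
                                           "doses_dispensed"),
                contact_minutes=float(cell["contact_minutes"]),
                quit_12wk=_parse_int(cell["quit_12wk"], i, "quit_12wk"),
                age_years=_parse_int(cell["age_years"], i, "age_years"),
                gender=cell["gender"].strip(),
                ftnd=(None if cell["ftnd"].strip() == ""
                      else _parse_int(cell["ftnd"], i, "ftnd")),
                imd_raw=(None if cell["imd_raw"].strip() == ""
                         else _parse_int(cell["imd_raw"], i, "imd_raw")),
                region=cell["region"].strip(),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    logger.info("read %d service records", len(records))
    return records


def write_records(records: Iterable[ServiceRecord], path: str | IO[str],
                  delimiter: str = ",") -> None:
    """Emit records as CSV readable by :func:`read_records` (default columns)."""
    rows = []
    for r in records:
        rows.append({
            "client_id": r.client_id,
            "quit_date": r.quit_date.isoformat(),
            "pregnant": int(r.pregnant),
            "treatments": TREATMENT_SEP.join(sorted(r.treatments)),
            "pathway": r.pathway,
            "doses_dispensed": r.doses_dispensed,
            "contact_minutes": r.contact_minutes,
            "quit_12wk": r.quit_12wk,
            "age_years": r.age_years,
            "gender": r.gender,
            "ftnd": "" if r.ftnd is None else r.ftnd,
            "imd_raw": "" if r.imd_raw is None else r.imd_raw,
            "region": r.region,
        })
    pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS)).to_csv(
        path, sep=delimiter, index=False)


def apply_exclusions(
    records: Sequence[ServiceRecord],
    cutoff_date: datetime.date = DEFAULT_CUTOFF,
) -> tuple[list[ServiceRecord], ExclusionReport]:
    """Filter the raw episodes down to the analysis cohort.

    Rules, applied in order with first-match attribution:

    1. ``date_cutoff`` — quit date strictly after ``cutoff_date`` (the
       12-week outcome could not yet be complete at data compilation);
    2. ``pregnant`` — pregnant clients (separate specialist service);
    3. ``treatment_count`` — no pharmacotherapy, or more than one, recorded.

    Repeat episodes of the same client are retained.  Returns the retained
    records (input order preserved) and an :class:`ExclusionReport`.
    """
    removed = {rule: 0 for rule in EXCLUSION_RULES}
    retained: list[ServiceRecord] = []
    for rec in records:
        if rec.quit_date > cutoff_date:
            removed["date_cutoff"] += 1
        elif rec.pregnant:
            removed["pregnant"] += 1
        elif len(rec.treatments) != 1:
            removed["treatment_count"] += 1
        else:
            retained.append(rec)
    report = ExclusionReport(
        n_input=len(records),
        n_removed_by_rule=removed,
        n_retained=len(retained),
        cutoff_date=cutoff_date,
    )
    logger.info(
        "exclusions: %d in, removed %s, %d retained",
        report.n_input, dict(removed), report.n_retained)
    return retained, report
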