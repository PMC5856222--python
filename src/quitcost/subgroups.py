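"""Recode raw covariates into the analysis categories.

Age, nicotine dependence (FTND) and deprivation (IMD) are binned into the
display bands used throughout the tabulated results; the raw IMD decile is
inverted first so that a higher score means *more* deprived, which reads
more naturally when discussing a deprivation gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .errors import ValidationError
from .records import ServiceRecord

# (label, low, high) with inclusive bounds; high=None means open-ended.
# The youngest band is labelled "12-19" for display although it covers all
# ages <= 19: no service user is younger than 12.
AGE_BANDS = (
    ("12-19", 0, 19),
    ("20-29", 20, 29),
    ("30-49", 30, 49),
    ("50-69", 50, 69),
    ("70+", 70, None),
)

# FTND is scored 0-10 by the standard instrument.
FTND_BANDS = (
    ("0-3", 0, 3),
    ("4-5", 4, 5),
    ("6-7", 6, 7),
    ("8-10", 8, 10),
)

# Bands on the INVERTED deprivation scale (1 = least deprived .. 10 = most).
DEPRIVATION_BANDS = (
    ("1-3", 1, 3),
    ("4-6", 4, 6),
    ("7-8", 7, 8),
    ("9-10", 9, 10),
)

GENDER_LEVELS = ("male", "female")
TREATMENT_LEVELS = ("NRT", "varenicline", "bupropion")


def _bin(value: int, bands, what: str) -> str:
    for label, lo, hi in bands:
        if value >= lo and (hi is None or value <= hi):
            return label
    raise ValidationError(f"{what}={value} is outside the binnable range")


def bin_age(age_years: int) -> str:
    """Age in years -> display band."""
    if age_years < 0:
        raise ValidationError(f"age_years must be >= 0, got {age_years}")
    return _bin(age_years, AGE_BANDS, "age_years")


def bin_ftnd(ftnd: int | None) -> str | None:
    """FTND score (0-10) -> band; missing stays missing."""
    if ftnd is None:
        return None
    if not 0 <= ftnd <= 10:
        raise ValidationError(f"ftnd must be in 0..10, got {ftnd}")
    return _bin(ftnd, FTND_BANDS, "ftnd")


def invert_imd(imd_raw: int) -> int:
    """Flip the IMD decile so higher = more deprived.

    Raw scale: 1 = most deprived.  Inverted: 1 = least deprived, 10 = most.
    Self-inverse on 1..10.
    """
    if not 1 <= imd_raw <= 10:
        raise ValidationError(f"imd_raw must be in 1..10, got {imd_raw}")
    return 11 - imd_raw


def bin_deprivation(inverted: int | None) -> str | None:
    """Inverted deprivation score (1-10) -> band; missing stays missing."""
    if inverted is None:
        return None
    if not 1 <= inverted <= 10:
        raise ValidationError(
            f"inverted deprivation must be in 1..10, got {inverted}")
    return _bin(inverted, DEPRIVATION_BANDS, "deprivation")


@dataclass(frozen=True)
class SubgroupLabels:
    """The analysis categories for one record; FTND/deprivation may be missing."""

    age_band: str
    gender: str
    treatment: str
    ftnd_band: str | None
    deprivation_band: str | None


def label_record(record: ServiceRecord) -> SubgroupLabels:
    """Derive every factor band for one post-exclusion record."""
    return SubgroupLabels(
        age_band=bin_age(record.age_years),
        gender=record.gender,
        treatment=record.treatment,
        ftnd_band=bin_ftnd(record.ftnd),
        deprivation_band=(
            None if record.imd_raw is None
            else bin_deprivation(invert_imd(record.imd_raw))
        ),
    )


def label_records(records: Sequence[ServiceRecord]) -> list[SubgroupLabels]:
    return [label_record(r) for r in records]


#: Factor name -> (accessor on SubgroupLabels, bands in display order).
FACTORS: dict[str, tuple[Callable[[SubgroupLabels], str | None], tuple[str, ...]]] = {
    "age": (lambda l: l.age_band, tuple(b[0] for b in AGE_BANDS)),
    "gender": (lambda l: l.gender, GENDER_LEVELS),
    "treatment": (lambda l: l.treatment, TREATMENT_LEVELS),
    "ftnd": (lambda l: l.ftnd_band, tuple(b[0] for b in FTND_BANDS)),
    "deprivation": (lambda l: l.deprivation_band,
                    tuple(b[0] for b in DEPRIVATION_BANDS)),
}

FACTOR_NAMES = tuple(FACTORS)
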