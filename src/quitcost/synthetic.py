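"""Synthetic service cohorts with known ground truth.

The generator draws treatment episodes whose marginal composition matches a
:class:`CohortProfile`: categorical shares for age band, gender, treatment,
dependence (FTND) and deprivation; a per-treatment quit probability; dose
counts from a distribution that deliberately overshoots the schedule maxima
(so cost capping is exercised); and contact minutes from a truncated normal.
A configurable fraction of records is injected with the features the
exclusion filter must catch — late quit dates, pregnancy flags, and no or
multiple recorded treatments.

Because every distribution is known, the population cost-per-quit of any
band is available in closed form (:func:`true_cpq`), which is what makes
parameter-recovery and interval-coverage experiments possible without any
real data.

Factors are drawn independently of each other: the profile encodes margins
only.  Real service data has correlated covariates, repeat-episode
dependence within clients and region effects, none of which are emulated.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from . import costing
from .errors import ValidationError
from .records import DEFAULT_CUTOFF, ServiceRecord
from .subgroups import (AGE_BANDS, DEPRIVATION_BANDS, FACTORS, FTND_BANDS,
                        TREATMENT_LEVELS)

#: Study window for quit dates.
STUDY_START = datetime.date(2013, 3, 15)
STUDY_END = datetime.date(2016, 3, 16)

#: Raw-value sampling range for each age band (the open-ended band is capped
#: at a realistic maximum age).
_AGE_RANGES = {"12-19": (12, 19), "20-29": (20, 29), "30-49": (30, 49),
               "50-69": (50, 69), "70+": (70, 90)}

#: Schedule key -> (treatment, pathway argument) for the costing table.
SCHEDULE_KEYS = {
    "NRT": ("NRT", "other"),
    "varenicline_pharmacy": ("varenicline", "pharmacy"),
    "varenicline_other": ("varenicline", "other"),
    "bupropion": ("bupropion", "other"),
}

_REGIONS = ("East Sussex", "Sandwell", "Telford and Wrekin", "Walsall",
            "Worcester")


def _geometric_pmf(decay: float, kmax: int) -> dict[int, float]:
    w = decay ** np.arange(kmax + 1)
    w = w / w.sum()
    return {k: float(p) for k, p in enumerate(w)}


@dataclass
class CohortProfile:
    """Everything the generator needs, and the analytic truth derives from.

    ``factor_probs`` are per-factor categorical distributions over band
    labels (each summing to 1).  ``quit_prob`` maps treatment to the
    Bernoulli success probability of the 12-week quit; optional
    ``quit_logit_adjust`` adds per-band shifts on the logit scale, allowing
    age or dependence gradients.  ``doses_probs`` and ``contact_params`` are
    keyed by dose-schedule key (varenicline splits by prescription route
    with ``pathway_probs``).  ``missing_prob`` controls how often FTND/IMD
    are unrecorded.  The three injection probabilities produce records the
    exclusion rules must remove.
    """

    factor_probs: dict[str, dict[str, float]]
    quit_prob: dict[str, float]
    pathway_probs: dict[str, float]
    doses_probs: dict[str, dict[int, float]]
    contact_params: dict[str, tuple[float, float]]  # key -> (mean, sd)
    contact_bounds: tuple[float, float] = (0.0, 300.0)
    missing_prob: dict[str, float] = field(
        default_factory=lambda: {"ftnd": 0.0, "imd": 0.0})
    quit_logit_adjust: dict[str, dict[str, float]] = field(default_factory=dict)
    pregnancy_prob: float = 0.0
    multi_treatment_prob: float = 0.0
    late_date_prob: float = 0.0
    regions: tuple[str, ...] = _REGIONS

    def validate(self) -> None:
        for factor, probs in self.factor_probs.items():
            if factor not in FACTORS:
                raise ValidationError(f"unknown factor {factor!r}")
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValidationError(
                    f"factor {factor!r} probabilities sum to {total}, not 1")
            _, bands = FACTORS[factor]
            if set(probs) - set(bands):
                raise ValidationError(
                    f"factor {factor!r} has unknown bands "
                    f"{sorted(set(probs) - set(bands))}")
        for key, pmf in self.doses_probs.items():
            total = sum(pmf.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValidationError(
                    f"doses pmf for {key!r} sums to {total}, not 1")
        if not math.isclose(sum(self.pathway_probs.values()), 1.0,
                            abs_tol=1e-6):
            raise ValidationError("pathway probabilities must sum to 1")
        scalars = {
            **{f"quit_prob[{t}]": p for t, p in self.quit_prob.items()},
            **{f"missing_prob[{k}]": p for k, p in self.missing_prob.items()},
            "pregnancy_prob": self.pregnancy_prob,
            "multi_treatment_prob": self.multi_treatment_prob,
            "late_date_prob": self.late_date_prob,
        }
        for name, p in scalars.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} is not a probability")

    def clean(self) -> "CohortProfile":
        """A copy with all exclusion-rule injections switched off."""
        return dataclasses.replace(
            self, pregnancy_prob=0.0, multi_treatment_prob=0.0,
            late_date_prob=0.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["doses_probs"] = {k: {str(i): p for i, p in pmf.items()}
                            for k, pmf in self.doses_probs.items()}
        return d


def default_profile() -> CohortProfile:
    """The profile calibrated to the reference cohort's printed margins.

    Treatment shares, quit probabilities, age/gender/FTND/deprivation
    compositions and FTND/IMD missingness reproduce the observed summary
    table; dose-count decay and contact-minute means are set so the implied
    expected cost per head per treatment matches the observed cost-per-head
    column (NRT ~ £115.31, varenicline ~ £193.23, bupropion ~ £122.99).
    Injection rates default to the observed pre-exclusion marginal rates.
    """
    def norm(counts: Sequence[float]) -> list[float]:
        total = sum(counts)
        return [c / total for c in counts]

    age = norm([509, 1189, 3911, 2955, 538])
    gender = norm([4249, 4867])
    treatment = norm([0.801, 0.187, 0.004])
    ftnd = norm([1534, 1884, 1676, 766])
    deprivation = norm([886, 1838, 2157, 3321])

    profile = CohortProfile(
        factor_probs={
            "age": dict(zip((b[0] for b in AGE_BANDS), age)),
            "gender": dict(zip(("male", "female"), gender)),
            "treatment": dict(zip(TREATMENT_LEVELS, treatment)),
            "ftnd": dict(zip((b[0] for b in FTND_BANDS), ftnd)),
            "deprivation": dict(zip((b[0] for b in DEPRIVATION_BANDS),
                                    deprivation)),
        },
        quit_prob={"NRT": 0.287, "varenicline": 0.468, "bupropion": 0.543},
        pathway_probs={"pharmacy": 0.5, "other": 0.5},
        # Truncated-geometric dose counts on 0..max+3; slower decay for
        # varenicline reflects pack-based adherence.
        doses_probs={
            "NRT": _geometric_pmf(0.80, 15),
            "varenicline_pharmacy": _geometric_pmf(0.95, 9),
            "varenicline_other": _geometric_pmf(0.95, 7),
            "bupropion": _geometric_pmf(0.75, 6),
        },
        # Means solved so expected cost per head hits the per-treatment
        # targets at the £26.32/h adviser rate; sd 40 min, bounds [0, 300].
        contact_params={
            "NRT": (103.80, 40.0),
            "varenicline_pharmacy": (126.06, 40.0),
            "varenicline_other": (124.17, 40.0),
            "bupropion": (132.09, 40.0),
        },
        missing_prob={"ftnd": 1 - 5860 / 9116, "imd": 1 - 8202 / 9116},
        pregnancy_prob=802 / 15682,
        multi_treatment_prob=4254 / 15682,
        late_date_prob=1950 / 15682,
    )
    profile.validate()
    return profile


@dataclass
class SyntheticCohort:
    """A generated cohort plus the profile and analytic truth behind it."""

    records: list[ServiceRecord]
    profile: CohortProfile
    seed: int
    true_cpq_by_band: dict[str, float]

    def truth_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps({
            "seed": self.seed,
            "n_records": len(self.records),
            "true_cpq_by_band": self.true_cpq_by_band,
            "profile": self.profile.to_dict(),
        }, **kwargs)


def _truncnorm_mean(mu: float, sigma: float,
                    bounds: tuple[float, float]) -> float:
    a, b = (bounds[0] - mu) / sigma, (bounds[1] - mu) / sigma
    return float(truncnorm.mean(a, b, loc=mu, scale=sigma))


def _expected_medication_cost(profile: CohortProfile, key: str) -> float:
    treatment, pathway = SCHEDULE_KEYS[key]
    sched = costing.dose_schedule(treatment, pathway)
    return sum(p * float(sched.cumulative_price(k))
               for k, p in profile.doses_probs[key].items())


def _expected_cost_by_treatment(profile: CohortProfile) -> dict[str, float]:
    """E[total cost | treatment], marginal over prescription route."""
    rate = float(costing.default_cost_rate().hourly_total)
    e_cost: dict[str, float] = {}
    for t in TREATMENT_LEVELS:
        if t == "varenicline":
            keys = [("varenicline_pharmacy", profile.pathway_probs["pharmacy"]),
                    ("varenicline_other", profile.pathway_probs["other"])]
        else:
            keys = [(t, 1.0)]
        total = 0.0
        for key, w in keys:
            mu, sigma = profile.contact_params[key]
            e_adv = _truncnorm_mean(mu, sigma, profile.contact_bounds) / 60 * rate
            total += w * (_expected_medication_cost(profile, key) + e_adv)
        e_cost[t] = total
    return e_cost


def _logit(p: float) -> float:
    # degenerate probabilities map to +-inf so logit-scale shifts are no-ops
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    return math.log(p / (1 - p))


def _sigmoid(x: float) -> float:
    if x < -40:
        return 0.0
    if x > 40:
        return 1.0
    return 1 / (1 + math.exp(-x))


def _quit_prob_given(profile: CohortProfile, treatment: str,
                     fixed: Mapping[str, str]) -> float:
    """P(quit | treatment, fixed factor bands), marginal over the rest.

    Only factors named in ``quit_logit_adjust`` need marginalising; for a
    factor that can be missing, the unrecorded level carries no adjustment.
    """
    base = _logit(profile.quit_prob[treatment])
    adjust = {f: a for f, a in profile.quit_logit_adjust.items()
              if f != "treatment"}
    if "treatment" in profile.quit_logit_adjust:
        base += profile.quit_logit_adjust["treatment"].get(treatment, 0.0)
    free = [f for f in adjust if f not in fixed]
    total, weight_sum = 0.0, 0.0

    def rec(i: int, weight: float, shift: float) -> None:
        nonlocal total, weight_sum
        if i == len(free):
            for f, band in fixed.items():
                if f in adjust:
                    shift += adjust[f].get(band, 0.0)
            total += weight * _sigmoid(base + shift)
            weight_sum += weight
            return
        f = free[i]
        miss_key = "ftnd" if f == "ftnd" else ("imd" if f == "deprivation"
                                               else None)
        p_miss = profile.missing_prob.get(miss_key, 0.0) if miss_key else 0.0
        if p_miss > 0:
            rec(i + 1, weight * p_miss, shift)
        for band, p in profile.factor_probs[f].items():
            rec(i + 1, weight * (1 - p_miss) * p, shift + adjust[f].get(band, 0.0))

    rec(0, 1.0, 0.0)
    return total / weight_sum


def true_cpq(profile: CohortProfile, band: str = "overall") -> float:
    """The population CPQ the sample statistic estimates, in closed form.

    ``band`` is "overall" or "<factor>:<band>" (e.g. "treatment:NRT",
    "age:20-29").  The value is E[cost | band] / P(quit | band) under the
    profile; because factors are drawn independently, cost depends on the
    band only through treatment.  The record-level penny rounding of the
    adviser cost is ignored (bias below half a penny per record).
    """
    e_cost = _expected_cost_by_treatment(profile)
    t_probs = profile.factor_probs["treatment"]
    if band == "overall":
        condition: dict[str, str] = {}
        treatments = list(TREATMENT_LEVELS)
    else:
        factor, _, level = band.partition(":")
        if factor not in FACTORS or not level:
            raise ValidationError(f"bad band spec {band!r}")
        if factor == "treatment":
            if t_probs.get(level, 0.0) <= 0:
                raise ValidationError(f"band {band!r} has zero probability")
            condition, treatments = {}, [level]
        else:
            if profile.factor_probs[factor].get(level, 0.0) <= 0:
                raise ValidationError(f"band {band!r} has zero probability")
            condition, treatments = {factor: level}, list(TREATMENT_LEVELS)

    weights = np.array([t_probs[t] for t in treatments])
    weights = weights / weights.sum()
    num = float(sum(w * e_cost[t] for w, t in zip(weights, treatments)))
    den = float(sum(w * _quit_prob_given(profile, t, condition)
                    for w, t in zip(weights, treatments)))
    if den == 0:
        raise ValidationError(f"band {band!r} has zero quit probability; "
                              "CPQ undefined")
    return num / den


def _all_bands(profile: CohortProfile) -> list[str]:
    out = ["overall"]
    for factor, probs in profile.factor_probs.items():
        out.extend(f"{factor}:{band}" for band, p in probs.items() if p > 0)
    return out


def _sample_banded(rng: np.random.Generator, n: int,
                   probs: Mapping[str, float],
                   ranges: Mapping[str, tuple[int, int]]) -> np.ndarray:
    """Sample a raw integer uniformly within a band sampled from ``probs``."""
    bands = list(probs)
    idx = rng.choice(len(bands), size=n, p=[probs[b] for b in bands])
    lo = np.array([ranges[b][0] for b in bands])[idx]
    hi = np.array([ranges[b][1] for b in bands])[idx]
    return lo + (rng.random(n) * (hi - lo + 1)).astype(np.int64)


def generate_cohort(profile: CohortProfile, n: int, seed: int) -> SyntheticCohort:
    """Draw ``n`` treatment episodes from the profile, bit-reproducibly.

    Injected excludable records (late quit date, pregnancy, no/multiple
    treatment) are otherwise ordinary draws, so the retained cohort after
    exclusion filtering follows the clean profile distribution exactly.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    profile.validate()
    rng = np.random.default_rng(seed)

    age = _sample_banded(rng, n, profile.factor_probs["age"], _AGE_RANGES)
    gender_levels = list(profile.factor_probs["gender"])
    gender = np.array(gender_levels)[
        rng.choice(len(gender_levels), size=n,
                   p=list(profile.factor_probs["gender"].values()))]
    t_levels = list(profile.factor_probs["treatment"])
    t_idx = rng.choice(len(t_levels), size=n,
                       p=list(profile.factor_probs["treatment"].values()))
    treatment = np.array(t_levels)[t_idx]

    ftnd_ranges = {b: (lo, hi) for b, lo, hi in FTND_BANDS}
    ftnd_raw = _sample_banded(rng, n, profile.factor_probs["ftnd"], ftnd_ranges)
    ftnd_missing = rng.random(n) < profile.missing_prob.get("ftnd", 0.0)

    depr_ranges = {b: (lo, hi) for b, lo, hi in DEPRIVATION_BANDS}
    inverted = _sample_banded(rng, n, profile.factor_probs["deprivation"],
                              depr_ranges)
    imd_raw = 11 - inverted
    imd_missing = rng.random(n) < profile.missing_prob.get("imd", 0.0)

    pathway = np.where(
        (treatment == "varenicline")
        & (rng.random(n) < profile.pathway_probs["pharmacy"]),
        "pharmacy", "other")

    sched_key = np.where(
        treatment == "varenicline",
        np.where(pathway == "pharmacy", "varenicline_pharmacy",
                 "varenicline_other"),
        treatment)

    doses = np.zeros(n, dtype=np.int64)
    minutes = np.zeros(n)
    for key in SCHEDULE_KEYS:  # fixed iteration order for determinism
        mask = sched_key == key
        m = int(mask.sum())
        if m == 0:
            continue
        pmf = profile.doses_probs[key]
        counts = np.array(list(pmf))
        doses[mask] = counts[rng.choice(len(counts), size=m,
                                        p=list(pmf.values()))]
        mu, sigma = profile.contact_params[key]
        a, b = ((profile.contact_bounds[0] - mu) / sigma,
                (profile.contact_bounds[1] - mu) / sigma)
        raw = truncnorm.rvs(a, b, loc=mu, scale=sigma, size=m, random_state=rng)
        minutes[mask] = np.round(raw, 1)

    base_logit = np.array([_logit(profile.quit_prob[t]) for t in treatment])
    if profile.quit_logit_adjust:
        band_of = {
            "age": np.array([_bin_label(a, AGE_BANDS) for a in age]),
            "gender": gender,
            "treatment": treatment,
            "ftnd": np.where(ftnd_missing, "",
                             [_bin_label(v, FTND_BANDS) for v in ftnd_raw]),
            "deprivation": np.where(
                imd_missing, "",
                [_bin_label(v, DEPRIVATION_BANDS) for v in inverted]),
        }
        for factor, adj in profile.quit_logit_adjust.items():
            shifts = np.array([adj.get(b, 0.0) for b in band_of[factor]])
            base_logit = base_logit + shifts
    with np.errstate(over="ignore"):
        quit = (rng.random(n) < 1 / (1 + np.exp(-base_logit))).astype(np.int64)

    clean_days = (DEFAULT_CUTOFF - STUDY_START).days
    late_days = (STUDY_END - DEFAULT_CUTOFF).days
    day_offset = (rng.random(n) * (clean_days + 1)).astype(np.int64)
    late = rng.random(n) < profile.late_date_prob
    late_offset = 1 + (rng.random(n) * late_days).astype(np.int64)

    pregnant = rng.random(n) < profile.pregnancy_prob
    multi = rng.random(n) < profile.multi_treatment_prob
    multi_empty = rng.random(n) < 0.5  # no treatment vs an extra one
    second_pick = rng.integers(0, 2, size=n)

    region_idx = rng.choice(len(profile.regions), size=n)

    records: list[ServiceRecord] = []
    for i in range(n):
        if late[i]:
            qdate = DEFAULT_CUTOFF + datetime.timedelta(int(late_offset[i]))
        else:
            qdate = STUDY_START + datetime.timedelta(int(day_offset[i]))
        if multi[i]:
            if multi_empty[i]:
                treatments = frozenset()
            else:
                others = [t for t in TREATMENT_LEVELS if t != treatment[i]]
                treatments = frozenset({str(treatment[i]),
                                        others[int(second_pick[i])]})
        else:
            treatments = frozenset({str(treatment[i])})
        records.append(ServiceRecord(
            client_id=f"S{i:06d}",
            quit_date=qdate,
            pregnant=bool(pregnant[i]),
            treatments=treatments,
            pathway=str(pathway[i]),
            doses_dispensed=int(doses[i]),
            contact_minutes=float(minutes[i]),
            quit_12wk=int(quit[i]),
            age_years=int(age[i]),
            gender=str(gender[i]),
            ftnd=None if ftnd_missing[i] else int(ftnd_raw[i]),
            imd_raw=None if imd_missing[i] else int(imd_raw[i]),
            region=profile.regions[int(region_idx[i])],
        ))

    truth = {band: true_cpq(profile, band) for band in _all_bands(profile)}
    return SyntheticCohort(records=records, profile=profile, seed=seed,
                           true_cpq_by_band=truth)


def _bin_label(value: int, bands) -> str:
    for label, lo, hi in bands:
        if value >= lo and (hi is None or value <= hi):
            return label
    raise ValidationError(f"{value} outside bands")


def expected_exclusions(profile: CohortProfile, n: int) -> dict[str, float]:
    """Expected removal count per rule under first-match attribution.

    The date rule fires first, then pregnancy, then treatment count; the
    injection flags are independent, so later rules see the survivors of
    earlier ones.
    """
    p_late = profile.late_date_prob
    p_preg = profile.pregnancy_prob
    p_multi = profile.multi_treatment_prob
    return {
        "date_cutoff": n * p_late,
        "pregnant": n * (1 - p_late) * p_preg,
        "treatment_count": n * (1 - p_late) * (1 - p_preg) * p_multi,
    }
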