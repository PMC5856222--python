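"""Per-treatment-arm scenario parameters for downstream return-on-investment
modelling.

From a costed cohort, each pharmacotherapy arm contributes three numbers to
a national roll-out scenario: its uptake share (fraction of the cohort
prescribed that arm), its cost per user (cost per head regardless of quit
status), and a relative 12-month abstinence rate against an untreated
baseline.  The relative rates and the baseline come from the external
model's literature, not from the cohort, and are passed through from
configuration.  The ROI model itself (Markov projection of QALYs and
benefit-cost ratios) is out of scope here; this module only prepares and
audits its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal
from typing import IO, Mapping, Sequence

import yaml

from .costing import CostedRecord
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: 12-month abstinence multipliers vs the 4% untreated baseline, as used by
#: the external ROI model's literature for each pharmacotherapy.
DEFAULT_RELATIVE_RATES = {"NRT": 2.14, "varenicline": 2.24, "bupropion": 1.6}

DEFAULT_BASELINE = 0.04


@dataclass(frozen=True)
class RoiArm:
    treatment: str
    uptake_share: float
    cost_per_user: float
    relative_abstinence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.uptake_share <= 1.0:
            raise ValidationError("uptake_share must be in [0, 1]")
        if self.relative_abstinence < 0:
            raise ValidationError("relative_abstinence must be >= 0")


@dataclass(frozen=True)
class RoiScenario:
    """The per-arm parameters plus the shared untreated baseline."""

    arms: tuple[RoiArm, ...]
    baseline_abstinence: float = DEFAULT_BASELINE
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(a.uptake_share for a in self.arms)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"uptake shares sum to {total}, expected 1")

    def to_dict(self) -> dict:
        return {
            "baseline_abstinence": self.baseline_abstinence,
            "arms": [
                {
                    "treatment": a.treatment,
                    "uptake_share": round(a.uptake_share, 6),
                    "cost_per_user": round(a.cost_per_user, 2),
                    "relative_abstinence": a.relative_abstinence,
                }
                for a in self.arms
            ],
            "metadata": dict(self.metadata),
        }

    def to_yaml(self, stream: IO[str] | None = None) -> str | None:
        return yaml.safe_dump(self.to_dict(), stream, sort_keys=True)


def scenario_from_aggregates(
    arm_stats: Mapping[str, tuple[int, float]],
    relative_rates: Mapping[str, float] | None = None,
    baseline: float = DEFAULT_BASELINE,
    metadata: Mapping[str, object] | None = None,
) -> RoiScenario:
    """Build a scenario from per-arm (n, total cost) aggregates.

    Arms present in ``relative_rates`` but absent from the aggregates are
    omitted with a warning.
    """
    rates = DEFAULT_RELATIVE_RATES if relative_rates is None else relative_rates
    missing = set(rates) - set(arm_stats)
    for arm in sorted(missing):
        logger.warning("arm %s has a relative rate but no cohort records; "
                       "omitted from the scenario", arm)
    absent_rate = set(arm_stats) - set(rates)
    if absent_rate:
        raise ValidationError(
            f"no relative abstinence rate supplied for arm(s) "
            f"{sorted(absent_rate)}")
    cohort_n = sum(n for n, _ in arm_stats.values())
    if cohort_n == 0:
        raise ValidationError("empty cohort")
    arms = tuple(
        RoiArm(
            treatment=t,
            uptake_share=n / cohort_n,
            cost_per_user=total / n,
            relative_abstinence=rates[t],
        )
        for t, (n, total) in arm_stats.items()
    )
    return RoiScenario(arms=arms, baseline_abstinence=baseline,
                       metadata=dict(metadata or {}))


def derive_scenario(
    costed: Sequence[CostedRecord],
    relative_rates: Mapping[str, float] | None = None,
    baseline: float = DEFAULT_BASELINE,
    metadata: Mapping[str, object] | None = None,
) -> RoiScenario:
    """Compute the scenario parameters from a costed cohort.

    Uptake shares and cost per user come from the data; the relative rates
    and baseline are configuration (external-literature values).
    """
    if not costed:
        raise ValidationError("empty cohort")
    stats: dict[str, tuple[int, float]] = {}
    order = ("NRT", "varenicline", "bupropion")
    for t in order:
        group = [c for c in costed if c.record.treatment == t]
        if group:
            total = sum((c.total_cost for c in group), Decimal("0.00"))
            stats[t] = (len(group), float(total))
    return scenario_from_aggregates(stats, relative_rates, baseline, metadata)


def expected_quitters_per_1000(scenario: RoiScenario) -> float:
    """Projected 12-month quitters per 1000 treated smokers.

    Computed as ``1000 * baseline * sum(uptake_share * relative_abstinence)``
    over the arms: each treated smoker is on exactly one arm, whose
    12-month abstinence probability is the untreated baseline times the
    arm's relative rate.  The formula is deliberately exposed so the
    scenario arithmetic can be audited — published service evaluations
    sometimes report headline quitter counts computed under a different
    (undocumented) denominator convention, and those are not reproducible
    from these three parameters alone.
    """
    return 1000.0 * scenario.baseline_abstinence * sum(
        a.uptake_share * a.relative_abstinence for a in scenario.arms)
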