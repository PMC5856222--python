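"""The cost-per-quit statistic and its bootstrap percentile interval.

Cost per quit (CPQ) is a ratio of totals: CPQ = T / n_quit, where T is the
summed service cost over every episode in a group (quitters and
non-quitters alike) and n_quit the number of successful 12-week quits.  Its
sampling uncertainty has two coupled sources — the cost distribution within
each outcome group and the quit proportion itself — so the confidence
interval resamples whole records with replacement, keeping each record's
cost and quit status together, and takes percentiles of the replicate CPQ
distribution.

Replicates with zero quits contribute +inf to the replicate distribution
rather than being redrawn, which would bias the upper tail downward; the
percentiles stay finite whenever fewer than ``upper_percentile`` percent of
replicates are degenerate, and the condition is logged when it occurs.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Sequence

import numpy as np

from .costing import CostedRecord
from .errors import ValidationError
from .subgroups import FACTORS, SubgroupLabels

logger = logging.getLogger(__name__)

#: Cap on index draws held in memory at once while bootstrapping.
_CHUNK_CELLS = 4_000_000


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings: replicate count, interval percentiles, seed."""

    n_replicates: int = 1000
    lower_percentile: float = 2.5
    upper_percentile: float = 97.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not 0 < self.lower_percentile < self.upper_percentile < 100:
            raise ValidationError(
                "percentiles must satisfy 0 < lower < upper < 100")


@dataclass(frozen=True)
class CPQEstimate:
    """One row of a CPQ table: point estimates plus the bootstrap interval.

    ``mean_cpq`` is +inf when the group has no quits.  The percentile
    interval of a ratio need not bracket the point estimate in pathological
    cases, so only ``ci_lower <= ci_upper`` is guaranteed.
    """

    label: str
    n: int
    total_cost: float
    cost_per_head: float
    n_quits: int
    quit_rate: float  # percent
    mean_cpq: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "total_cost": round(self.total_cost, 2),
            "cost_per_head": round(self.cost_per_head, 2),
            "n_quits": self.n_quits,
            "quit_rate": round(self.quit_rate, 2),
            "mean_cpq": round(self.mean_cpq, 2),
            "ci_lower": round(self.ci_lower, 2),
            "ci_upper": round(self.ci_upper, 2),
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def point_cpq(costed: Sequence[CostedRecord]) -> tuple[Decimal, int, float]:
    """Total cost, quit count and mean CPQ for a group of costed records.

    Accumulation is exact decimal; the ratio is returned as a float.  A
    group with no quits has an undefined (infinite) CPQ, which is logged.
    """
    if not costed:
        raise ValidationError("point_cpq requires a non-empty group")
    total = sum((c.total_cost for c in costed), Decimal("0.00"))
    n_quits = sum(c.record.quit_12wk for c in costed)
    if n_quits == 0:
        logger.warning("group of %d records has no quits; CPQ undefined",
                       len(costed))
        return total, 0, math.inf
    return total, n_quits, float(total) / n_quits


def _arrays(costed: Sequence[CostedRecord]) -> tuple[np.ndarray, np.ndarray]:
    costs = np.array([float(c.total_cost) for c in costed])
    quits = np.array([c.record.quit_12wk for c in costed], dtype=np.int64)
    return costs, quits


def bootstrap_replicates(
    costed: Sequence[CostedRecord],
    config: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """The replicate CPQ distribution from case resampling.

    Each replicate draws N records with replacement (N = group size),
    keeping cost and quit status paired, and recomputes CPQ.  Zero-quit
    replicates yield +inf.  Deterministic given the generator state.
    """
    if not costed:
        raise ValidationError("bootstrap requires a non-empty group")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    costs, quits = _arrays(costed)
    n = len(costed)
    reps = np.empty(config.n_replicates)
    batch = max(1, min(config.n_replicates, _CHUNK_CELLS // max(n, 1)))
    done = 0
    while done < config.n_replicates:
        m = min(batch, config.n_replicates - done)
        idx = rng.integers(0, n, size=(m, n))
        rep_t = costs[idx].sum(axis=1)
        rep_q = quits[idx].sum(axis=1)
        with np.errstate(divide="ignore"):
            reps[done:done + m] = np.where(rep_q > 0, rep_t / np.maximum(rep_q, 1),
                                           np.inf)
        done += m
    n_degenerate = int(np.isinf(reps).sum())
    if n_degenerate:
        logger.warning("%d of %d bootstrap replicates had zero quits",
                       n_degenerate, config.n_replicates)
    return reps


def bootstrap_ci(
    costed: Sequence[CostedRecord],
    config: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the group CPQ.

    Empirical percentiles with linear interpolation between order
    statistics, at ``config.lower_percentile`` / ``config.upper_percentile``.
    """
    reps = np.sort(bootstrap_replicates(costed, config, rng))
    return (_percentile(reps, config.lower_percentile),
            _percentile(reps, config.upper_percentile))


def _percentile(sorted_reps: np.ndarray, q: float) -> float:
    """Linear interpolation between order statistics, robust to +inf ties
    (interpolating between two infinite order statistics is +inf, where
    naive arithmetic would give nan)."""
    pos = (len(sorted_reps) - 1) * q / 100.0
    lo_i = int(math.floor(pos))
    hi_i = int(math.ceil(pos))
    lo_v, hi_v = float(sorted_reps[lo_i]), float(sorted_reps[hi_i])
    if lo_v == hi_v:
        return lo_v
    return lo_v + (pos - lo_i) * (hi_v - lo_v)


def subgroup_rng(seed: int, factor: str, band: str) -> np.random.Generator:
    """An independent, deterministic substream for one subgroup's resampling.

    Derived from the run seed and a stable hash of "factor/band", so adding
    or reordering factors never perturbs another subgroup's interval.
    """
    key = zlib.crc32(f"{factor}/{band}".encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def estimate(
    costed: Sequence[CostedRecord],
    label: str,
    config: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> CPQEstimate:
    """Point estimates plus bootstrap interval for one group of records."""
    total, n_quits, mean = point_cpq(costed)
    lo, hi = bootstrap_ci(costed, config, rng)
    n = len(costed)
    return CPQEstimate(
        label=label,
        n=n,
        total_cost=float(total),
        cost_per_head=float(total) / n,
        n_quits=n_quits,
        quit_rate=100.0 * n_quits / n,
        mean_cpq=mean,
        ci_lower=lo,
        ci_upper=hi,
        n_boot=config.n_replicates,
        seed=config.seed,
    )


def overall_estimate(
    costed: Sequence[CostedRecord],
    config: BootstrapConfig,
) -> CPQEstimate:
    """The whole-cohort CPQ estimate, on its own random substream."""
    return estimate(costed, "overall", config,
                    rng=subgroup_rng(config.seed, "overall", "all"))


def subgroup_table(
    costed: Sequence[CostedRecord],
    labels: Sequence[SubgroupLabels],
    factor: str,
    config: BootstrapConfig,
) -> list[CPQEstimate]:
    """One CPQ estimate per band of ``factor``, in display order.

    Records missing the factor's value are omitted from this factor's table
    (they still count in the overall estimate).  Empty bands are omitted
    with a warning.  Each band's bootstrap runs on an independent substream
    derived from the run seed.
    """
    if len(costed) != len(labels):
        raise ValidationError("costed and labels must be aligned")
    if factor not in FACTORS:
        raise ValidationError(
            f"unknown factor {factor!r}; expected one of {tuple(FACTORS)}")
    accessor, bands = FACTORS[factor]
    out: list[CPQEstimate] = []
    for band in bands:
        group = [c for c, l in zip(costed, labels) if accessor(l) == band]
        if not group:
            logger.warning("factor %s band %s has no records; omitted",
                           factor, band)
            continue
        out.append(estimate(group, f"{factor}:{band}", config,
                            rng=subgroup_rng(config.seed, factor, band)))
    return out
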