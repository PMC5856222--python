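"""CPQ ratio statistic and bootstrap percentile intervals."""

import itertools
import math
from decimal import Decimal

import numpy as np
import pytest

from quitcost import (BootstrapConfig, ValidationError, bootstrap_ci,
                      estimate, label_records, overall_estimate, point_cpq,
                      subgroup_table)
from quitcost.cpq import bootstrap_replicates, subgroup_rng


def enumerate_replicate_distribution(costs, quits):
    """Exact bootstrap-replicate CPQ distribution by brute force.

    Enumerates every resample multiset of size n (with multinomial weight)
    and returns (values, probabilities); zero-quit multisets map to +inf.
    Independent of the Monte-Carlo path it checks.
    """
    n = len(costs)
    values, probs = [], []
    for combo in itertools.combinations_with_replacement(range(n), n):
        counts = np.bincount(combo, minlength=n)
        weight = (math.factorial(n) /
                  math.prod(math.factorial(int(c)) for c in counts)) / n ** n
        total = float(sum(c * cost for c, cost in zip(counts, costs)))
        n_quit = int(sum(c * q for c, q in zip(counts, quits)))
        values.append(total / n_quit if n_quit else math.inf)
        probs.append(weight)
    order = np.argsort(values)
    return np.array(values)[order], np.array(probs)[order]


def exact_percentile(values, probs, pct):
    """Step-function quantile of a discrete distribution."""
    cdf = np.cumsum(probs)
    return values[np.searchsorted(cdf, pct / 100.0)]


class TestPointCPQ:
    def test_printed_style_row(self, make_costed):
        """Total £49,133 over 509 episodes with 116 quits gives the familiar
        £423.56 CPQ for the youngest band."""
        group = [make_costed(0, 1) for _ in range(115)]
        group += [make_costed(49133, 1)]
        group += [make_costed(0, 0) for _ in range(509 - 116)]
        total, n_quits, mean = point_cpq(group)
        assert total == Decimal("49133.00")
        assert n_quits == 116
        assert round(mean, 2) == 423.56

    def test_single_record_identity(self, make_costed):
        _, _, mean = point_cpq([make_costed(278.88, 1)])
        assert mean == pytest.approx(278.88)

    def test_hand_ratio(self, make_costed):
        group = [make_costed(100, int(i < 4)) for i in range(10)]
        total, n_quits, mean = point_cpq(group)
        assert (float(total), n_quits, mean) == (1000.0, 4, 250.0)

    def test_zero_quits_is_flagged_infinite(self, make_costed):
        _, n_quits, mean = point_cpq([make_costed(100, 0)])
        assert n_quits == 0 and math.isinf(mean)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            point_cpq([])


class TestBootstrapCI:
    def test_degenerate_identical_records_give_point_interval(self, make_costed):
        group = [make_costed(150, 1) for _ in range(5)]
        lo, hi = bootstrap_ci(group, BootstrapConfig(n_replicates=200, seed=3))
        assert lo == hi == pytest.approx(150.0)

    def test_bit_identical_per_seed_and_different_across_seeds(self, make_costed):
        group = [make_costed(50 * (i + 1), i % 2) for i in range(20)]
        ci_a = bootstrap_ci(group, BootstrapConfig(seed=11))
        ci_b = bootstrap_ci(group, BootstrapConfig(seed=11))
        ci_c = bootstrap_ci(group, BootstrapConfig(seed=12))
        assert ci_a == ci_b
        assert ci_a != ci_c

    def test_zero_quit_replicates_go_to_upper_tail(self, make_costed):
        # 1 quit in 4 records: ~32% of resamples have no quits, so the upper
        # percentile must be +inf rather than biased downward by redrawing.
        group = [make_costed(100, int(i == 0)) for i in range(4)]
        reps = bootstrap_replicates(group,
                                    BootstrapConfig(n_replicates=500, seed=5))
        assert np.isinf(reps).mean() == pytest.approx((3 / 4) ** 4, abs=0.08)
        lo, hi = bootstrap_ci(group, BootstrapConfig(n_replicates=500, seed=5))
        assert math.isinf(hi) and math.isfinite(lo)

    def test_matches_enumeration_oracle_on_tiny_cohort(self, make_costed):
        """Monte-Carlo percentiles converge to the exact multinomial
        enumeration on a 5-record cohort."""
        costs = [100, 100, 200, 300, 300]
        quits = [1, 1, 0, 1, 1]
        group = [make_costed(c, q) for c, q in zip(costs, quits)]
        values, probs = enumerate_replicate_distribution(costs, quits)
        finite = np.isfinite(values)
        spread = values[finite].max() - values[finite].min()
        config = BootstrapConfig(n_replicates=20000, seed=9)
        lo, hi = bootstrap_ci(group, config)
        assert lo == pytest.approx(exact_percentile(values, probs, 2.5),
                                   abs=0.02 * spread)
        assert hi == pytest.approx(exact_percentile(values, probs, 97.5),
                                   abs=0.02 * spread)

    def test_interval_width_shrinks_with_sample_size(self, make_costed):
        """At a fixed data-generating process the percentile interval
        narrows as the group grows."""
        rng = np.random.default_rng(2)
        widths = []
        for n in (100, 1000, 5000):
            group = [make_costed(round(float(c), 2), int(q))
                     for c, q in zip(rng.gamma(4.0, 30.0, n),
                                     rng.random(n) < 0.3)]
            lo, hi = bootstrap_ci(group, BootstrapConfig(seed=4))
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestSubgroupTable:
    def test_partition_into_treatment_rows(self, make_costed):
        group = (
            [make_costed(100, 1, treatments=frozenset({"NRT"}))] * 4
            + [make_costed(200, 0, treatments=frozenset({"varenicline"}))] * 3
            + [make_costed(150, 1, treatments=frozenset({"bupropion"}))] * 2
        )
        labels = label_records([c.record for c in group])
        table = subgroup_table(group, labels, "treatment", BootstrapConfig(seed=1))
        assert [e.label for e in table] == [
            "treatment:NRT", "treatment:varenicline", "treatment:bupropion"]
        assert [e.n for e in table] == [4, 3, 2]

    def test_missing_factor_values_omitted_from_table_only(self, make_costed):
        group = [make_costed(100, 1, ftnd=(7 if i % 2 else None))
                 for i in range(10)]
        labels = label_records([c.record for c in group])
        table = subgroup_table(group, labels, "ftnd", BootstrapConfig(seed=1))
        assert sum(e.n for e in table) == 5
        overall = overall_estimate(group, BootstrapConfig(seed=1))
        assert overall.n == 10

    def test_reconciliation_with_overall_when_nothing_missing(self, make_costed):
        group = [make_costed(37.5 * (i + 1), i % 3 == 0,
                             gender="male" if i % 2 else "female")
                 for i in range(30)]
        labels = label_records([c.record for c in group])
        table = subgroup_table(group, labels, "gender", BootstrapConfig(seed=1))
        total, n_quits, _ = point_cpq(group)
        assert sum(e.total_cost for e in table) == pytest.approx(float(total))
        assert sum(e.n_quits for e in table) == n_quits

    def test_empty_band_omitted_with_warning(self, make_costed, caplog):
        group = [make_costed(100, 1, treatments=frozenset({"NRT"}))] * 3
        labels = label_records([c.record for c in group])
        with caplog.at_level("WARNING"):
            table = subgroup_table(group, labels, "treatment",
                                   BootstrapConfig(seed=1))
        assert [e.label for e in table] == ["treatment:NRT"]
        assert "no records" in caplog.text

    def test_substreams_isolate_subgroups(self, make_costed):
        """A band's interval is unchanged by which other factors are run."""
        a = subgroup_rng(7, "gender", "male")
        b = subgroup_rng(7, "gender", "male")
        c = subgroup_rng(7, "age", "20-29")
        assert a.integers(0, 1 << 30, 5).tolist() == \
            b.integers(0, 1 << 30, 5).tolist()
        assert a.integers(0, 1 << 30, 5).tolist() != \
            c.integers(0, 1 << 30, 5).tolist()

    def test_estimate_fields_are_consistent(self, make_costed):
        group = [make_costed(120, i % 2) for i in range(8)]
        est = estimate(group, "g", BootstrapConfig(seed=2))
        assert est.cost_per_head == pytest.approx(est.total_cost / est.n)
        assert est.quit_rate == pytest.approx(100 * est.n_quits / est.n)
        assert est.mean_cpq == pytest.approx(est.total_cost / est.n_quits)
        assert est.ci_lower <= est.ci_upper
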