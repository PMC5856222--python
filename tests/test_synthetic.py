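"""Synthetic cohort generator: defaults, determinism, analytic ground truth."""

import dataclasses
import math

import numpy as np
import pytest

from quitcost import (ValidationError, apply_exclusions, cost_records,
                      default_profile, expected_exclusions, generate_cohort,
                      point_cpq, true_cpq)
from quitcost.synthetic import CohortProfile, _geometric_pmf


class TestDefaultProfile:
    def test_treatment_shares_match_reference_margins(self):
        probs = default_profile().factor_probs["treatment"]
        ref = np.array([0.801, 0.187, 0.004])
        got = np.array([probs["NRT"], probs["varenicline"], probs["bupropion"]])
        assert got == pytest.approx(ref / ref.sum())

    def test_quit_probabilities_match_reference_margins(self):
        q = default_profile().quit_prob
        assert (q["NRT"], q["varenicline"], q["bupropion"]) == \
            (0.287, 0.468, 0.543)

    def test_missingness_matches_reference_denominators(self):
        miss = default_profile().missing_prob
        assert 1 - miss["ftnd"] == pytest.approx(5860 / 9116)
        assert 1 - miss["imd"] == pytest.approx(8202 / 9116)

    def test_profile_passes_its_own_invariants(self):
        default_profile().validate()

    def test_implied_cost_per_head_matches_calibration_targets(self):
        """The contact/dose distributions were solved so each treatment's
        expected cost per head lands on its reference value."""
        from quitcost.synthetic import _expected_cost_by_treatment
        e_cost = _expected_cost_by_treatment(default_profile())
        assert e_cost["NRT"] == pytest.approx(115.31, abs=0.05)
        assert e_cost["varenicline"] == pytest.approx(193.23, abs=0.05)
        assert e_cost["bupropion"] == pytest.approx(122.99, abs=0.05)


class TestGenerateCohort:
    def test_same_seed_is_bit_identical(self):
        profile = default_profile()
        a = generate_cohort(profile, 300, seed=5)
        b = generate_cohort(profile, 300, seed=5)
        assert a.records == b.records
        assert generate_cohort(profile, 300, seed=6).records != a.records

    def test_treatment_shares_within_three_binomial_ses(self):
        profile = default_profile().clean()
        cohort = generate_cohort(profile, 1000, seed=1)
        n = len(cohort.records)
        for t, p in profile.factor_probs["treatment"].items():
            share = sum(r.treatment == t for r in cohort.records) / n
            se = math.sqrt(p * (1 - p) / n)
            assert abs(share - p) <= 3 * se + 1e-12

    def test_degenerate_profile_gives_exact_cpq(self):
        """With quit probability one and a constant cost, the pipeline CPQ
        is that cost exactly: the ratio degenerates to cost per head."""
        profile = default_profile().clean()
        profile.quit_prob = {t: 1.0 for t in profile.quit_prob}
        profile.factor_probs["treatment"] = {
            "NRT": 1.0, "varenicline": 0.0, "bupropion": 0.0}
        profile.doses_probs["NRT"] = {0: 1.0}
        profile.contact_params["NRT"] = (60.0, 1e-9)
        cohort = generate_cohort(profile, 50, seed=2)
        costed = cost_records(cohort.records)
        _, _, mean = point_cpq(costed)
        assert mean == pytest.approx(26.32, abs=0.01)

    def test_injected_records_are_caught_by_exclusions(self):
        profile = default_profile()
        n = 4000
        cohort = generate_cohort(profile, n, seed=3)
        _, report = apply_exclusions(cohort.records)
        expected = expected_exclusions(profile, n)
        for rule, exp in expected.items():
            got = report.n_removed_by_rule[rule]
            se = math.sqrt(exp * (1 - exp / n))
            assert abs(got - exp) <= 3 * se, (rule, got, exp)
        assert report.n_input == report.n_retained + sum(
            report.n_removed_by_rule.values())

    def test_raw_values_are_consistent_with_sampled_bands(self):
        cohort = generate_cohort(default_profile(), 500, seed=4)
        for r in cohort.records:
            assert r.ftnd is None or 0 <= r.ftnd <= 10
            assert r.imd_raw is None or 1 <= r.imd_raw <= 10
            assert 12 <= r.age_years <= 90
            assert 0 <= r.contact_minutes <= 300
            # pathway only carries meaning when varenicline was dispensed
            if r.treatments and "varenicline" not in r.treatments:
                assert r.pathway == "other"

    def test_invalid_profile_rejected(self):
        profile = default_profile()
        profile.factor_probs["gender"] = {"male": 0.7, "female": 0.2}
        with pytest.raises(ValidationError):
            generate_cohort(profile, 10, seed=0)


class TestTrueCPQ:
    def _flat_profile(self, quit_p: float) -> CohortProfile:
        profile = default_profile().clean()
        profile.quit_prob = {t: quit_p for t in profile.quit_prob}
        for key in profile.doses_probs:
            profile.doses_probs[key] = {0: 1.0}
            profile.contact_params[key] = (120.0, 1e-9)
        return profile

    def test_constant_cost_closed_form(self):
        # cost is exactly 2 hours of adviser time; quit probability 0.4
        profile = self._flat_profile(0.4)
        assert true_cpq(profile, "overall") == pytest.approx(
            2 * 26.32 / 0.4, rel=1e-6)

    def test_two_level_cost_mixture_by_hand(self):
        """NRT costs 2h contact, varenicline 2h + one £38.40 dose; the
        overall CPQ is the share-weighted mean cost over the share-weighted
        quit probability."""
        profile = self._flat_profile(0.5)
        profile.factor_probs["treatment"] = {
            "NRT": 0.6, "varenicline": 0.4, "bupropion": 0.0}
        profile.doses_probs["varenicline_pharmacy"] = {1: 1.0}
        profile.doses_probs["varenicline_other"] = {1: 1.0}
        cost = 0.6 * (2 * 26.32) + 0.4 * (2 * 26.32 + 38.40)
        assert true_cpq(profile, "overall") == pytest.approx(cost / 0.5,
                                                             rel=1e-6)
        assert true_cpq(profile, "treatment:varenicline") == pytest.approx(
            (2 * 26.32 + 38.40) / 0.5, rel=1e-6)

    def test_zero_quit_probability_is_signalled(self):
        profile = self._flat_profile(0.0)
        with pytest.raises(ValidationError, match="undefined"):
            true_cpq(profile, "overall")

    def test_zero_probability_band_is_signalled(self):
        profile = default_profile()
        profile.factor_probs["treatment"] = {
            "NRT": 1.0, "varenicline": 0.0, "bupropion": 0.0}
        with pytest.raises(ValidationError):
            true_cpq(profile, "treatment:varenicline")

    def test_logit_adjustment_shifts_band_truth(self):
        profile = default_profile().clean()
        profile.quit_logit_adjust = {"age": {"12-19": -0.5}}
        young = true_cpq(profile, "age:12-19")
        old = true_cpq(profile, "age:50-69")
        assert young > old  # lower quit odds -> higher cost per quit

    def test_sample_cpq_converges_to_truth(self):
        """Parameter recovery at moderate n: the pipeline CPQ lands within
        a few percent of the analytic value for the majority arm."""
        profile = default_profile().clean()
        cohort = generate_cohort(profile, 8000, seed=11)
        costed = cost_records(cohort.records)
        _, _, mean = point_cpq(costed)
        assert mean == pytest.approx(cohort.true_cpq_by_band["overall"],
                                     rel=0.05)


def test_geometric_pmf_shape():
    pmf = _geometric_pmf(0.5, 3)
    assert sum(pmf.values()) == pytest.approx(1.0)
    assert pmf[0] / pmf[1] == pytest.approx(2.0)
    assert set(pmf) == {0, 1, 2, 3}
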