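import itertools
import math

import numpy as np
import pytest

from hypoburden import (
    PatientRecord,
    PowerSpec,
    build_comparison_tables,
    fisher_or_chisq,
    hodges_lehmann,
    power_two_sample_t,
    required_n,
    wilcoxon_ranksum,
)
from hypoburden.cohort_stats import median_iqr, round2
from tests.conftest import make_series


def hl_oracle(a, b):
    """Pure-python pairwise-difference median (independent of numpy paths)."""
    diffs = sorted(x - y for x in a for y in b)
    n = len(diffs)
    mid = n // 2
    return diffs[mid] if n % 2 else 0.5 * (diffs[mid - 1] + diffs[mid])


def exact_wilcoxon_oracle(a, b):
    """Two-sided p by enumerating all rank assignments (no ties)."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    m, n = len(a), len(b)
    u_obs = sum(ranks[v] for v in a) - m * (m + 1) / 2
    center = m * n / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, m + n + 1), m):
        u = sum(combo) - m * (m + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


class TestHodgesLehmann:
    def test_identical_samples_zero_shift(self):
        shift, lo, hi = hodges_lehmann([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert shift == 0.0
        assert lo <= 0.0 <= hi

    def test_small_example(self):
        shift, _, _ = hodges_lehmann([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert shift == -3.0

    def test_location_equivariance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=15)
        b = rng.normal(size=12)
        s0, lo0, hi0 = hodges_lehmann(a, b)
        s1, lo1, hi1 = hodges_lehmann(a + 2.5, b)
        assert s1 == pytest.approx(s0 + 2.5)
        assert lo1 == pytest.approx(lo0 + 2.5)
        assert hi1 == pytest.approx(hi0 + 2.5)

    def test_matches_brute_force_over_sizes(self):
        rng = np.random.default_rng(11)
        for m in range(1, 31, 4):
            for n in range(1, 31, 5):
                a = list(rng.normal(size=m))
                b = list(rng.normal(size=n))
                shift, lo, hi = hodges_lehmann(a, b)
                assert shift == pytest.approx(hl_oracle(a, b))
                assert lo <= shift <= hi

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            hodges_lehmann([], [1.0])


class TestWilcoxon:
    def test_tiny_exact_case(self):
        assert wilcoxon_ranksum([1.0, 2.0], [3.0, 4.0]) == pytest.approx(1.0 / 3.0)

    def test_identical_constant_samples(self):
        assert wilcoxon_ranksum([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for m, n in [(2, 2), (3, 4), (5, 5), (6, 6), (2, 9), (4, 7)]:
            vals = rng.permutation(np.arange(1.0, m + n + 1))
            a, b = list(vals[:m]), list(vals[m:])
            assert wilcoxon_ranksum(a, b) == pytest.approx(
                exact_wilcoxon_oracle(a, b), abs=1e-12
            )

    def test_asymptotic_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            vals = rng.permutation(np.arange(1.0, 13.0))
            a, b = list(vals[:6]), list(vals[6:])
            p_exact = exact_wilcoxon_oracle(a, b)
            p_asym = wilcoxon_ranksum(a, b, exact_max_total=0)  # force approximation
            assert abs(p_exact - p_asym) < 0.02


class TestFisherChisq:
    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_or_chisq([[30, 30], [0, 0]])

    def test_balanced_table_p_one(self):
        p, used = fisher_or_chisq([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)
        assert used == "fisher_exact"  # expected counts all 1 < 5

    def test_expected_rule_selects_chi_square(self):
        # 20/30 vs 28/30 patients with events: all expected cells >= 5
        p, used = fisher_or_chisq([[20, 10], [28, 2]])
        assert used == "chi_square"
        assert p < 0.05

    def test_expected_rule_selects_fisher(self):
        p, used = fisher_or_chisq([[1, 5], [4, 2]])
        assert used == "fisher_exact"
        assert 0 < p <= 1


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        spec = PowerSpec(0.5, 0.5, 0.51, alpha=0.05)
        assert power_two_sample_t(spec, 30) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_n_d_alpha(self):
        base = PowerSpec(0.5, 0.2, 0.51)
        powers_n = [power_two_sample_t(base, n) for n in (5, 10, 20, 40, 100)]
        assert all(x < y for x, y in zip(powers_n, powers_n[1:]))
        powers_d = [
            power_two_sample_t(PowerSpec(0.5, 0.5 - d, 1.0), 20) for d in (0.1, 0.3, 0.6, 1.0)
        ]
        assert all(x < y for x, y in zip(powers_d, powers_d[1:]))
        powers_a = [
            power_two_sample_t(PowerSpec(0.5, 0.2, 0.51, alpha=a), 20)
            for a in (0.01, 0.05, 0.10)
        ]
        assert all(x < y for x, y in zip(powers_a, powers_a[1:]))

    def test_large_n_power_approaches_one(self):
        spec = PowerSpec(0.6, 0.5, 1.0)  # d = 0.1
        assert power_two_sample_t(spec, 10_000) > 0.99

    def test_trial_plan_sample_size(self):
        # planning means 0.5 vs 0.12 mmHg, SD 0.51 -> d = 0.745 -> 30/group
        spec = PowerSpec(0.5, 0.12, 0.51)
        assert required_n(spec) == 30
        assert power_two_sample_t(spec, 30) >= 0.80
        assert power_two_sample_t(spec, 29) < 0.80

    def test_doubling_effect_quarters_n(self):
        n1 = required_n(PowerSpec(0.5, 0.5 - 0.3, 1.0))
        n2 = required_n(PowerSpec(0.5, 0.5 - 0.6, 1.0))
        assert 3.5 <= n1 / n2 <= 4.5

    def test_minimal_power_target_floor(self):
        spec = PowerSpec(0.5, 0.1, 0.51, power_target=0.06)
        assert required_n(spec) == 2

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            required_n(PowerSpec(0.5, 0.5, 0.51))

    def test_half_even_reporting(self):
        assert round2(0.375) == 0.38
        assert round2(0.125) == 0.12


def _flat_patient(pid, arm, map_value=75.0):
    t = np.arange(0.0, 7200.0, 20.0)
    series = make_series(t, np.full(len(t), map_value), patient_id=pid)
    return PatientRecord(series, arm, 300.0, 60.0)


class TestReportTables:
    def test_structural_completeness(self, trial_cohort):
        tables = build_comparison_tables(trial_cohort)
        burden = tables["burden"]
        assert set(burden["threshold_mmHg"]) == {65.0, 50.0, 110.0, 130.0}
        assert set(burden["window"]) == {"full", "induction20"}
        assert set(burden["variable"]) == {
            "n_events", "total_duration_min", "pct_time", "auc_mmHg_min", "twa_mmHg",
        }
        assert (tables["patients_with_events"]["hpi_n"] == 30).all()
        assert len(tables["latencies"]) == 1

    def test_zero_event_cohort(self):
        recs = [_flat_patient(f"h{i}", "HPI") for i in range(3)] + [
            _flat_patient(f"c{i}", "Control") for i in range(3)
        ]
        tables = build_comparison_tables(recs)
        burden = tables["burden"]
        assert (burden["hpi_median"] == 0).all()
        assert (burden["control_median"] == 0).all()
        assert (burden["hl_shift"] == 0).all()
        assert (burden["p_value"] == 1.0).all()

    def test_permutation_invariance(self, trial_cohort):
        t1 = build_comparison_tables(trial_cohort)["burden"]
        shuffled = list(trial_cohort)[::-1]
        t2 = build_comparison_tables(shuffled)["burden"]
        for col in ("hpi_median", "control_median", "hl_shift", "p_value"):
            np.testing.assert_allclose(t1[col].to_numpy(), t2[col].to_numpy())

    def test_median_iqr_type7(self):
        med, q1, q3 = median_iqr([1.0, 2.0, 3.0, 4.0])
        assert (med, q1, q3) == (2.5, 1.75, 3.25)
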