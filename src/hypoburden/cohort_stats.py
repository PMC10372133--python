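"""Two-arm comparison statistics and the trial planning calculation.

Continuous outcomes are summarized as median (25th–75th IQR) per arm and
compared with the two-sample Wilcoxon rank-sum test together with the
Hodges-Lehmann estimate of location shift and its asymptotic 95% CI (the
median of all between-group pairwise differences, CI bounds taken at order
statistics from the normal approximation to the Mann-Whitney null).
Categorical outcomes use Pearson's chi-square, falling back to Fisher's
exact test when any expected cell count is below 5.

The planning calculation evaluates two-sample t-test power exactly via the
noncentral t distribution (df = 2n-2, noncentrality d*sqrt(n/2)) and
inverts it for the required per-group sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .burden_metrics import cohort_burden_table
from .episode_detection import detect_alarms, detect_episodes
from .protocol_engine import treatment_latencies
from .timeseries_io import ARM_CONTROL, ARM_HPI, PatientRecord


def round2(x: float) -> float:
    """Two-decimal reporting with round-half-to-even (banker's rounding)."""
    return round(float(x), 2)


def median_iqr(values: Sequence[float]) -> Tuple[float, float, float]:
    """Median with 25th/75th percentiles (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    return (
        float(np.median(v)),
        float(np.quantile(v, 0.25)),
        float(np.quantile(v, 0.75)),
    )


def fmt_median_iqr(values: Sequence[float], nd: int = 2) -> str:
    med, q1, q3 = median_iqr(values)
    return f"{med:.{nd}f} ({q1:.{nd}f}, {q3:.{nd}f})"


# ---------------------------------------------------------------------------
# nonparametric two-sample machinery
# ---------------------------------------------------------------------------

def hodges_lehmann(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    conf: float = 0.95,
) -> Tuple[float, float, float]:
    """Hodges-Lehmann shift estimate (a - b) with asymptotic CI.

    The estimate is the median of all m*n pairwise differences; the CI
    bounds are the k-th and (mn+1-k)-th ordered differences with k from
    the normal approximation to the null Mann-Whitney distribution.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    mn = diffs.size
    shift = float(np.median(diffs))
    m, n = a.size, b.size
    z = stats.norm.ppf(0.5 + conf / 2.0)
    c = mn / 2.0 - z * math.sqrt(m * n * (m + n + 1) / 12.0)
    k = max(1, int(math.floor(c)))
    return shift, float(diffs[k - 1]), float(diffs[mn - k])


def wilcoxon_ranksum(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    continuity: bool = True,
    exact_max_total: int = 12,
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses full enumeration of the null distribution when the pooled size is
    at most ``exact_max_total`` and there are no ties; otherwise the normal
    approximation with tie correction and (by default) continuity
    correction.  Two identical constant samples give p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= exact_max_total and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=continuity
    )
    return float(min(res.pvalue, 1.0))


def fisher_or_chisq(table_2x2: Sequence[Sequence[int]]) -> Tuple[float, str]:
    """p-value for a 2x2 table, choosing the test by expected frequencies.

    Pearson chi-square without continuity correction when all expected
    cells are >= 5, otherwise Fisher's exact test (two-sided, sum of
    hypergeometric probabilities <= observed).
    """
    tbl = np.asarray(table_2x2, dtype=float)
    if tbl.shape != (2, 2) or (tbl < 0).any() or not np.allclose(tbl, np.round(tbl)):
        raise ValueError("expected a 2x2 table of non-negative integer counts")
    row = tbl.sum(axis=1)
    col = tbl.sum(axis=0)
    total = tbl.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate table: a margin is zero")
    expected = np.outer(row, col) / total
    if (expected < 5).any():
        _, p = stats.fisher_exact(tbl.astype(int), alternative="two-sided")
        return float(p), "fisher_exact"
    chi2, p, _, _ = stats.chi2_contingency(tbl, correction=False)
    return float(p), "chi_square"


@dataclass
class GroupComparison:
    """A two-arm comparison of one continuous variable."""

    variable_name: str
    group_a_median: float
    group_a_iqr: Tuple[float, float]
    group_b_median: float
    group_b_iqr: Tuple[float, float]
    hl_shift: float
    hl_ci_low: float
    hl_ci_high: float
    p_value: float
    test_used: str = "wilcoxon"


def compare_groups(
    name: str, sample_a: Sequence[float], sample_b: Sequence[float]
) -> GroupComparison:
    """Median/IQR + Hodges-Lehmann + Wilcoxon comparison (a vs b)."""
    med_a, q1a, q3a = median_iqr(sample_a)
    med_b, q1b, q3b = median_iqr(sample_b)
    shift, lo, hi = hodges_lehmann(sample_a, sample_b)
    p = wilcoxon_ranksum(sample_a, sample_b)
    return GroupComparison(name, med_a, (q1a, q3a), med_b, (q1b, q3b), shift, lo, hi, p)


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Planning assumptions for a two-group t-test on mean TWA."""

    mean_control: float
    mean_treat: float
    sd: float
    alpha: float = 0.05
    power_target: float = 0.80
    n_per_group: int = 30

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power_target < 1:
            raise ValueError("power_target must be in (0, 1)")

    @property
    def effect_size_d(self) -> float:
        return abs(self.mean_control - self.mean_treat) / self.sd


def power_two_sample_t(spec: PowerSpec, n_per_group: Optional[int] = None) -> float:
    """Exact two-sided power from the noncentral t distribution."""
    n = spec.n_per_group if n_per_group is None else n_per_group
    if n < 2:
        raise ValueError("n_per_group must be >= 2")
    df = 2 * n - 2
    nc = spec.effect_size_d * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def required_n(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest per-group n with power >= ``spec.power_target``."""
    if spec.effect_size_d == 0:
        raise ValueError("effect size is zero; no finite sample size achieves power")
    lo, hi = 2, 2
    while power_two_sample_t(spec, hi) < spec.power_target:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise ValueError(f"required n exceeds {n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_two_sample_t(spec, mid) >= spec.power_target:
            hi = mid
        else:
            lo = mid + 1
    return hi


# ---------------------------------------------------------------------------
# trial report tables
# ---------------------------------------------------------------------------

_BURDEN_VARS = (
    ("n_events", "Events per patient"),
    ("total_duration_min", "Duration of events per patient, min"),
    ("pct_time", "Percentage of time beyond threshold"),
    ("auc_mmHg_min", "Area beyond threshold per patient, mmHg*min"),
    ("twa_mmHg", "TWA beyond threshold per patient, mmHg"),
)


def _split_arms(records: Sequence[PatientRecord]) -> Tuple[List[PatientRecord], List[PatientRecord]]:
    a = [r for r in records if r.arm == ARM_HPI]
    b = [r for r in records if r.arm == ARM_CONTROL]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 patients per arm")
    return a, b


def _cohort_latencies(records: Sequence[PatientRecord]) -> Dict[str, List[float]]:
    """Pooled onset-to-treatment latencies per arm.

    Intervention-arm onsets are risk-index alarms; control-arm onsets are
    hypotensive-episode starts.
    """
    out: Dict[str, List[float]] = {ARM_HPI: [], ARM_CONTROL: []}
    for rec in records:
        if rec.arm == ARM_HPI:
            if "hpi" not in rec.series.channels:
                continue
            onsets = detect_alarms(rec.series)
        else:
            onsets = detect_episodes(rec.series, 65.0, "below")
        out[rec.arm].extend(treatment_latencies(rec, onsets))
    return out


def build_comparison_tables(
    records: Sequence[PatientRecord],
    burden_table: Optional[pd.DataFrame] = None,
    thresholds=None,
) -> Dict[str, pd.DataFrame]:
    """Assemble the trial's report tables from a cohort.

    Returns a dict of DataFrames:

    ``burden``
        per window x threshold x variable: arm medians/IQRs, Hodges-Lehmann
        shift with CI, Wilcoxon p, plus total event counts per dataset.
    ``patients_with_events``
        per window x threshold: patients with >= 1 event, proportions and
        the chi-square/Fisher p with the test actually used.
    ``treatments``
        cumulative dose per treatment kind among treated patients.
    ``latencies``
        pooled onset-to-treatment latencies per arm with the HL comparison.
    """
    arm_a, arm_b = _split_arms(records)
    if burden_table is None:
        burden_table = cohort_burden_table(records, thresholds=thresholds)

    burden_rows = []
    cat_rows = []
    for (window, th, direction), grp in burden_table.groupby(
        ["window", "threshold_mmHg", "direction"], sort=False
    ):
        ga = grp[grp["arm"] == ARM_HPI]
        gb = grp[grp["arm"] == ARM_CONTROL]
        for var, label in _BURDEN_VARS:
            cmpres = compare_groups(label, ga[var].to_numpy(), gb[var].to_numpy())
            burden_rows.append(
                {
                    "window": window,
                    "threshold_mmHg": th,
                    "direction": direction,
                    "variable": var,
                    "label": label,
                    "hpi_median": cmpres.group_a_median,
                    "hpi_q1": cmpres.group_a_iqr[0],
                    "hpi_q3": cmpres.group_a_iqr[1],
                    "control_median": cmpres.group_b_median,
                    "control_q1": cmpres.group_b_iqr[0],
                    "control_q3": cmpres.group_b_iqr[1],
                    "hl_shift": cmpres.hl_shift,
                    "hl_ci_low": cmpres.hl_ci_low,
                    "hl_ci_high": cmpres.hl_ci_high,
                    "p_value": cmpres.p_value,
                    "test_used": cmpres.test_used,
                    "hpi_total_events": int(ga["n_events"].sum()),
                    "control_total_events": int(gb["n_events"].sum()),
                }
            )
        wa = int((ga["n_events"] > 0).sum())
        wb = int((gb["n_events"] > 0).sum())
        na, nb = len(ga), len(gb)
        table = [[wa, na - wa], [wb, nb - wb]]
        try:
            p_cat, used = fisher_or_chisq(table)
        except ValueError:
            p_cat, used = float("nan"), "degenerate"
        cat_rows.append(
            {
                "window": window,
                "threshold_mmHg": th,
                "direction": direction,
                "hpi_with_events": wa,
                "hpi_n": na,
                "control_with_events": wb,
                "control_n": nb,
                "p_value": p_cat,
                "test_used": used,
            }
        )

    # cumulative doses per kind among patients who received the drug
    tx_rows = []
    kinds = sorted(
        {ev.kind for r in records for ev in r.treatments}
    )
    for kind in kinds:
        doses = {ARM_HPI: [], ARM_CONTROL: []}
        for rec in records:
            tot = sum(ev.dose for ev in rec.treatments if ev.kind == kind)
            if tot > 0:
                doses[rec.arm].append(tot)
        da, db = doses[ARM_HPI], doses[ARM_CONTROL]
        row = {
            "kind": kind,
            "hpi_n_patients": len(da),
            "control_n_patients": len(db),
        }
        if da:
            row["hpi_median"], row["hpi_q1"], row["hpi_q3"] = median_iqr(da)
        if db:
            row["control_median"], row["control_q1"], row["control_q3"] = median_iqr(db)
        if da and db:
            row["hl_shift"], row["hl_ci_low"], row["hl_ci_high"] = hodges_lehmann(da, db)
            row["p_value"] = wilcoxon_ranksum(da, db)
        tx_rows.append(row)

    lat = _cohort_latencies(records)
    lat_rows = []
    if lat[ARM_HPI] and lat[ARM_CONTROL]:
        cmpres = compare_groups("onset_to_treatment_s", lat[ARM_HPI], lat[ARM_CONTROL])
        lat_rows.append(
            {
                "variable": "onset_to_treatment_s",
                "hpi_median": cmpres.group_a_median,
                "hpi_q1": cmpres.group_a_iqr[0],
                "hpi_q3": cmpres.group_a_iqr[1],
                "hpi_n": len(lat[ARM_HPI]),
                "control_median": cmpres.group_b_median,
                "control_q1": cmpres.group_b_iqr[0],
                "control_q3": cmpres.group_b_iqr[1],
                "control_n": len(lat[ARM_CONTROL]),
                "hl_shift": cmpres.hl_shift,
                "hl_ci_low": cmpres.hl_ci_low,
                "hl_ci_high": cmpres.hl_ci_high,
                "p_value": cmpres.p_value,
            }
        )

    return {
        "burden": pd.DataFrame(burden_rows),
        "patients_with_events": pd.DataFrame(cat_rows),
        "treatments": pd.DataFrame(tx_rows),
        "latencies": pd.DataFrame(lat_rows),
    }
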