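"""Incremental AUC, cross-over contrasts, exact signed-rank test, power."""

from __future__ import annotations

from datetime import timedelta
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glucotrial.core import InsufficientDataError
from glucotrial.mtt import (
    AUCConvention,
    DegenerateInputError,
    IncompleteSubjectError,
    MTTLabel,
    MTTResult,
    crossover_contrasts,
    exact_wilcoxon_signed_rank,
    incremental_auc,
    power_by_simulation,
    stratify_by_baseline_auc,
)

from conftest import T0, TABLE1, make_trace


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def rectangle_auc(values, baseline, step_min=15.0, positive_only=True, m=4096):
    """Midpoint-rectangle refinement of the piecewise-linear increment curve.

    Midpoint sums are exact on each linear piece, so this integrates the same
    curve as the trapezoid rule by an independent route.
    """
    inc = [v - baseline for v in values]
    if positive_only:
        inc = [max(0.0, x) for x in inc]
    total = 0.0
    for a, b in zip(inc, inc[1:]):
        h = step_min / m
        mids = (np.arange(m) + 0.5) * h
        total += float(np.sum(a + (b - a) * mids / step_min) * h)
    return total


def signed_rank_null_cdf(n):
    """Closed-form null distribution of W+ for untied ranks 1..n (subset-sum DP)."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=object)
    counts[0] = 1
    for r in range(1, n + 1):
        counts[r:] = counts[r:] + counts[:-r].copy()
    total = 2**n
    cdf = np.cumsum(counts)
    return [Fraction(int(c), total) for c in cdf]


# ---------------------------------------------------------------------------
# incremental_auc
# ---------------------------------------------------------------------------


def test_constant_trace_has_zero_auc_under_both_conventions():
    trace = make_trace([100.0] * 9)
    for conv in AUCConvention:
        assert incremental_auc(trace, T0, convention=conv).auc == 0.0


def test_nine_point_meal_curve_matches_hand_trapezoid():
    # increments [0,20,40,50,40,30,20,10,0]; interval means * 15 sum to 3150
    trace = make_trace([100, 120, 140, 150, 140, 130, 120, 110, 100])
    res = incremental_auc(trace, T0)
    assert res.auc == pytest.approx(3150.0, abs=1e-9)
    assert res.baseline_glucose == 100.0
    assert res.n_points_used == 9
    assert not res.interpolated


def test_dip_below_baseline_separates_conventions():
    trace = make_trace([100, 90, 80, 75, 80, 85, 90, 95, 100])
    pos = incremental_auc(trace, T0, convention=AUCConvention.POSITIVE_ONLY)
    net = incremental_auc(trace, T0, convention=AUCConvention.NET)
    assert pos.auc == 0.0
    assert net.auc < 0.0


def test_off_grid_t0_interpolates_baseline_and_flags():
    trace = make_trace([100.0 + i for i in range(20)])
    res = incremental_auc(trace, T0 + timedelta(minutes=7.5), duration_min=120)
    assert res.interpolated
    assert res.baseline_glucose == pytest.approx(100.5)


def test_insufficient_coverage_raises():
    trace = make_trace([100.0] * 5)  # only 1 h of data
    with pytest.raises(InsufficientDataError):
        incremental_auc(trace, T0)
    with pytest.raises(ValueError):
        incremental_auc(trace, T0 + timedelta(days=1))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.lists(
        st.floats(min_value=41.0, max_value=400.0, allow_nan=False),
        min_size=9,
        max_size=9,
    ),
    st.sampled_from([True, False]),
)
def test_trapezoid_matches_rectangle_refinement_oracle(values, positive_only):
    trace = make_trace(values)
    conv = AUCConvention.POSITIVE_ONLY if positive_only else AUCConvention.NET
    auc = incremental_auc(trace, T0, convention=conv).auc
    oracle = rectangle_auc(values, values[0], positive_only=positive_only)
    assert auc == pytest.approx(oracle, rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# crossover_contrasts
# ---------------------------------------------------------------------------


def _results_from_deltas(subject, d_placebo, d_product, base=2000.0):
    mk = lambda label, auc: MTTResult(
        subject_id=subject,
        label=label,
        t0=T0,
        baseline_glucose=95.0,
        auc=auc,
        n_points_used=9,
        interpolated=False,
        convention=AUCConvention.NET,
    )
    return [
        mk(MTTLabel.BEGIN_PLACEBO, base),
        mk(MTTLabel.END_PLACEBO, base + d_placebo),
        mk(MTTLabel.BEGIN_PRODUCT, base),
        mk(MTTLabel.END_PRODUCT, base + d_product),
    ]


@pytest.mark.parametrize("subject", list(TABLE1))
def test_contrast_reproduces_pilot_table(subject):
    _, d_placebo, d_product, dd = TABLE1[subject]
    contrast = crossover_contrasts(_results_from_deltas(subject, d_placebo, d_product))
    assert contrast.delta_auc_placebo == pytest.approx(d_placebo, abs=1e-9)
    assert contrast.delta_auc_product == pytest.approx(d_product, abs=1e-9)
    assert contrast.delta_delta_auc == pytest.approx(dd, abs=1e-9)


def test_equal_arms_give_zero_contrast_and_missing_label_raises():
    contrast = crossover_contrasts(_results_from_deltas("S1", 500.0, 500.0))
    assert contrast.delta_delta_auc == 0.0
    with pytest.raises(IncompleteSubjectError):
        crossover_contrasts(_results_from_deltas("S1", 1.0, 2.0)[:3])


# ---------------------------------------------------------------------------
# exact_wilcoxon_signed_rank
# ---------------------------------------------------------------------------


def test_pilot_contrast_values_give_exact_14_64():
    dd = [row[3] for row in TABLE1.values()]
    res = exact_wilcoxon_signed_rank(dd, alternative="less")
    assert res.w_plus == 6.0
    assert res.n_effective == 6
    assert res.method == "exact_enumeration"
    assert res.p_value == 14 / 64


def test_all_negative_and_single_value_edge_cases():
    res = exact_wilcoxon_signed_rank([-3.0, -1.0, -2.5, -0.7, -9.0], "less")
    assert res.w_plus == 0.0
    assert res.p_value == 1 / 32
    single = exact_wilcoxon_signed_rank([-3.0], "less")
    assert single.p_value == 0.5
    with pytest.raises(DegenerateInputError):
        exact_wilcoxon_signed_rank([0.0, 0.0], "less")


@pytest.mark.parametrize("n", [3, 5, 8, 10])
@pytest.mark.parametrize("alternative", ["less", "greater"])
def test_enumeration_matches_closed_form_null_cdf(n, alternative):
    """Tie-free p-values must equal the closed-form signed-rank null CDF."""
    rng = np.random.default_rng(n * 100 + (alternative == "less"))
    cdf = signed_rank_null_cdf(n)
    max_sum = n * (n + 1) // 2
    for _ in range(20):
        x = rng.normal(0.3, 1.0, n)
        res = exact_wilcoxon_signed_rank(x, alternative)
        w = int(round(res.w_plus))
        if alternative == "less":
            expected = cdf[w]
        else:
            expected = 1 - (cdf[w - 1] if w > 0 else Fraction(0))
        assert res.p_value == pytest.approx(float(expected), abs=1e-12)


@pytest.mark.parametrize("alternative", ["less", "greater", "two_sided"])
def test_agrees_with_scipy_exact_on_tie_free_data(alternative):
    rng = np.random.default_rng(17)
    scipy_alt = {"less": "less", "greater": "greater", "two_sided": "two-sided"}
    for _ in range(10):
        x = rng.normal(-0.4, 1.0, 12)
        ours = exact_wilcoxon_signed_rank(x, alternative)
        ref = stats.wilcoxon(x, alternative=scipy_alt[alternative], method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_exact_under_midranked_ties_by_direct_enumeration():
    # tied absolute values: mid-ranks; enumeration stays a valid exact law
    x = [2.0, -2.0, 3.0, -1.0, 1.0]
    res = exact_wilcoxon_signed_rank(x, "less")
    ranks = stats.rankdata(np.abs(x))
    w_obs = ranks[np.array(x) > 0].sum()
    count = 0
    for mask in range(2**5):
        signs = [(mask >> i) & 1 for i in range(5)]
        w = sum(r for r, s in zip(ranks, signs) if s)
        count += w <= w_obs + 1e-9
    assert res.p_value == pytest.approx(count / 32)


def test_normal_approximation_close_to_exact_law_at_n30():
    n = 30
    cdf = signed_rank_null_cdf(n)
    rng = np.random.default_rng(30)
    for _ in range(15):
        x = rng.normal(-0.3, 1.0, n)
        res = exact_wilcoxon_signed_rank(x, "less")
        assert res.method == "normal_approx"
        exact_p = float(cdf[int(round(res.w_plus))])
        assert res.p_value == pytest.approx(exact_p, abs=0.02)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.lists(
        st.floats(
            min_value=-1e4, max_value=1e4, allow_nan=False, exclude_min=True
        ).filter(lambda v: abs(v) > 1e-6),
        min_size=2,
        max_size=12,
    )
)
def test_sign_flip_antisymmetry(values):
    """Negating every value maps alternative less <-> greater with identical p."""
    res_less = exact_wilcoxon_signed_rank(values, "less")
    res_greater = exact_wilcoxon_signed_rank([-v for v in values], "greater")
    assert res_less.p_value == pytest.approx(res_greater.p_value, abs=1e-12)
    total = res_less.n_effective * (res_less.n_effective + 1) / 2
    assert res_less.w_plus + res_greater.w_plus == pytest.approx(total)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


def test_baseline_stratification_recovers_responder_groups(table1):
    baselines = {sid: row[0] for sid, row in table1.items()}
    for cutoff in (900.0, 1000.0, 1200.0, 1500.0):
        strata = stratify_by_baseline_auc(baselines, cutoff)
        assert sorted(strata.low) == ["3", "5", "6"]
        assert sorted(strata.high) == ["1", "2", "4"]
    with pytest.raises(ValueError):
        stratify_by_baseline_auc(baselines, 100.0)  # below the minimum
    with pytest.raises(ValueError):
        stratify_by_baseline_auc({"a": 5.0, "b": 5.0}, 5.0)  # degenerate range


# ---------------------------------------------------------------------------
# power_by_simulation
# ---------------------------------------------------------------------------


def test_power_under_null_matches_size():
    est = power_by_simulation(0.0, 1000.0, 10, alpha=0.05, n_sim=4000, seed=2)
    # the exact test is conservative at n=10 (discrete support), so the
    # rejection rate sits at the largest attainable level below alpha
    assert est.power <= 0.05 + 3 * est.mc_se
    assert est.power > 0.01


def test_power_increases_with_sample_size():
    lo = power_by_simulation(-800.0, 1200.0, 10, n_sim=4000, seed=3)
    hi = power_by_simulation(-800.0, 1200.0, 35, n_sim=4000, seed=3)
    se = np.hypot(lo.mc_se, hi.mc_se)
    assert hi.power > lo.power - 3 * se
    assert hi.power > lo.power  # comfortably separated at this effect size


def test_power_validates_inputs():
    with pytest.raises(ValueError):
        power_by_simulation(0.0, 1.0, 10, n_sim=10)
    with pytest.raises(ValueError):
        power_by_simulation(0.0, 0.0, 10)
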