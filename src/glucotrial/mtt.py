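"""Meal-tolerance-test cross-over analysis.

The primary endpoint of the trial design this package targets: each subject
performs a fasted standardized-meal test (MTT) at the beginning and end of both
cross-over periods.  Per test, the incremental area under the glucose curve
(iAUC) over two hours is computed against the glucose level at t=0 (Wolever
convention: increments below baseline are ignored by default).  Per arm,
dAUC = AUC_end - AUC_begin; per subject, ddAUC = dAUC_product - dAUC_placebo.
The one-sided Wilcoxon signed-rank test of H0: ddAUC >= 0 against
H1: ddAUC < 0 is computed exactly by enumerating all sign assignments, which
remains exact under mid-ranked ties.  Power for future designs is estimated by
Monte-Carlo simulation under a normal effect law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import GlucoseTrace, InsufficientDataError, _as_aware

__all__ = [
    "AUCConvention",
    "MTTLabel",
    "MTTResult",
    "CrossoverContrast",
    "SignedRankResult",
    "PowerEstimate",
    "StratificationResult",
    "DegenerateInputError",
    "IncompleteSubjectError",
    "incremental_auc",
    "crossover_contrasts",
    "exact_wilcoxon_signed_rank",
    "stratify_by_baseline_auc",
    "power_by_simulation",
]

#: Exact enumeration of the 2^n sign assignments is used up to this n;
#: beyond it the normal approximation with continuity correction applies.
EXACT_ENUMERATION_LIMIT = 20


class DegenerateInputError(ValueError):
    """All paired differences are zero: the signed-rank test is undefined."""


class IncompleteSubjectError(KeyError):
    """A subject lacks one of the four labelled MTTs."""


class AUCConvention(str, Enum):
    POSITIVE_ONLY = "positive_only"  # Wolever incremental AUC (default)
    NET = "net"  # signed increments kept


class MTTLabel(str, Enum):
    BEGIN_PLACEBO = "begin_placebo"
    END_PLACEBO = "end_placebo"
    BEGIN_PRODUCT = "begin_product"
    END_PRODUCT = "end_product"


@dataclass(frozen=True)
class MTTResult:
    subject_id: str
    label: MTTLabel | None
    t0: datetime
    baseline_glucose: float
    auc: float  # (mg/dL)*min
    n_points_used: int
    interpolated: bool
    convention: AUCConvention = AUCConvention.POSITIVE_ONLY


@dataclass(frozen=True)
class CrossoverContrast:
    subject_id: str
    delta_auc_placebo: float
    delta_auc_product: float

    @property
    def delta_delta_auc(self) -> float:
        return self.delta_auc_product - self.delta_auc_placebo


@dataclass(frozen=True)
class SignedRankResult:
    w_plus: float
    n_effective: int
    p_value: float
    alternative: str
    method: str  # "exact_enumeration" or "normal_approx"


@dataclass(frozen=True)
class PowerEstimate:
    n_subjects: int
    alpha: float
    effect_mean: float
    effect_sd: float
    n_sim: int
    power: float
    mc_se: float
    seed: int | None


@dataclass(frozen=True)
class StratificationResult:
    cutoff: float
    low: tuple[str, ...]  # baseline AUC < cutoff
    high: tuple[str, ...]  # baseline AUC >= cutoff


def incremental_auc(
    trace: GlucoseTrace,
    t0: datetime,
    duration_min: float = 120.0,
    convention: AUCConvention | str = AUCConvention.POSITIVE_ONLY,
    label: MTTLabel | None = None,
) -> MTTResult:
    """Incremental AUC of the 2-h MTT window starting at ``t0``.

    The evaluation grid is anchored at ``t0`` with the trace's nominal step
    (15 min default), closed at both ends: nine points for two hours.  The
    baseline is the glucose at t=0 — the sample there, or linearly
    interpolated between the bracketing samples when ``t0`` is off-grid (the
    result is then flagged ``interpolated``).  Increments are integrated by
    the trapezoid rule; under ``positive_only`` negative increments are zeroed
    first (Wolever incremental AUC), under ``net`` they are kept.

    Requires a sample at or before ``t0`` and coverage of >= 75% of the grid
    points (a grid point is covered when a sample lies within one nominal
    interval of it); otherwise :class:`~glucotrial.core.InsufficientDataError`.
    ``n_points_used`` counts the covered grid points.
    """
    convention = AUCConvention(convention)
    t0 = _as_aware(t0)
    if not trace.samples:
        raise InsufficientDataError("empty trace")
    if t0 > trace.end:
        raise ValueError(f"t0 {t0} lies after the trace end {trace.end}")
    if t0 < trace.start:
        raise InsufficientDataError(f"no sample at or before t0 {t0}")

    step_min = trace.nominal_interval / timedelta(minutes=1)
    n_grid = int(round(duration_min / step_min)) + 1
    grid = t0.timestamp() + np.arange(n_grid) * step_min * 60.0

    times = trace.times_epoch()
    vals = trace.values()
    tol_s = 60.0  # a grid point is "sampled" if a sample lies within 1 min

    grid_vals = np.empty(n_grid)
    covered = 0
    interpolated = False
    for i, g in enumerate(grid):
        j = int(np.argmin(np.abs(times - g)))
        if abs(times[j] - g) <= step_min * 60.0:
            covered += 1
        if abs(times[j] - g) <= tol_s:
            grid_vals[i] = vals[j]
            continue
        right = int(np.searchsorted(times, g))
        if right == 0 or right == times.size:
            raise InsufficientDataError(
                f"MTT window [{t0}, +{duration_min:g} min] extends beyond the trace"
            )
        left = right - 1
        frac = (g - times[left]) / (times[right] - times[left])
        grid_vals[i] = vals[left] + frac * (vals[right] - vals[left])
        interpolated = True
    if covered < 0.75 * n_grid:
        raise InsufficientDataError(
            f"only {covered}/{n_grid} grid points covered in the MTT window "
            f"[{t0}, +{duration_min:g} min]"
        )

    baseline = grid_vals[0]
    increments = grid_vals - baseline
    if convention is AUCConvention.POSITIVE_ONLY:
        increments = np.clip(increments, 0.0, None)
    auc = float(np.trapezoid(increments, dx=step_min))
    return MTTResult(
        subject_id=trace.subject_id,
        label=label,
        t0=t0,
        baseline_glucose=float(baseline),
        auc=auc,
        n_points_used=covered,
        interpolated=interpolated,
        convention=convention,
    )


def crossover_contrasts(
    mtt_results: Sequence[MTTResult],
    design=None,
) -> CrossoverContrast:
    """Per-subject contrast from the four labelled MTTs.

    dAUC_arm = AUC at the end of the arm minus AUC at its beginning;
    ddAUC = dAUC_product - dAUC_placebo.  ``design`` is accepted for
    cross-checking the subject id but is not needed for the arithmetic.
    """
    by_label = {r.label: r for r in mtt_results}
    missing = [lab.value for lab in MTTLabel if lab not in by_label]
    if missing:
        raise IncompleteSubjectError(
            f"subject missing MTT labels: {', '.join(missing)}"
        )
    subject_ids = {r.subject_id for r in mtt_results}
    if len(subject_ids) != 1:
        raise ValueError(f"MTT results from multiple subjects: {sorted(subject_ids)}")
    (subject_id,) = subject_ids
    if design is not None and design.subject_id != subject_id:
        raise ValueError(
            f"design is for {design.subject_id}, MTT results for {subject_id}"
        )
    d_placebo = by_label[MTTLabel.END_PLACEBO].auc - by_label[MTTLabel.BEGIN_PLACEBO].auc
    d_product = by_label[MTTLabel.END_PRODUCT].auc - by_label[MTTLabel.BEGIN_PRODUCT].auc
    return CrossoverContrast(
        subject_id=subject_id,
        delta_auc_placebo=d_placebo,
        delta_auc_product=d_product,
    )


def _signed_rank_null_sums(ranks: np.ndarray) -> np.ndarray:
    """All 2^n values of W+ over the sign assignments of the given ranks."""
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    return sums


def exact_wilcoxon_signed_rank(
    values: Sequence[float],
    alternative: str = "less",
) -> SignedRankResult:
    """Wilcoxon signed-rank test of the symmetric-about-zero null.

    Zeros are dropped; absolute values receive mid-ranks under ties; W+ is the
    sum of ranks of positive values.  For n <= 20 the p-value comes from full
    enumeration of all 2^n sign assignments of the observed ranks — exact even
    with mid-ranked ties.  For larger n a normal approximation with continuity
    correction is used (mean sum(r)/2, variance sum(r^2)/4, both valid under
    mid-ranks); the method is recorded in the result.

    ``alternative="less"`` tests H1: the distribution is shifted below zero
    (small W+ is evidence); ``"greater"`` and ``"two_sided"`` as usual.
    """
    if alternative not in ("less", "greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    v = np.asarray(values, dtype=float)
    v = v[v != 0.0]
    n = v.size
    if n == 0:
        raise DegenerateInputError("all values are zero")
    ranks = stats.rankdata(np.abs(v))
    w_plus = float(ranks[v > 0].sum())

    eps = 1e-9
    if n <= EXACT_ENUMERATION_LIMIT:
        sums = _signed_rank_null_sums(ranks)
        p_less = float(np.mean(sums <= w_plus + eps))
        p_greater = float(np.mean(sums >= w_plus - eps))
        method = "exact_enumeration"
    else:
        mu = ranks.sum() / 2.0
        sigma = math.sqrt(float((ranks**2).sum()) / 4.0)
        p_less = float(stats.norm.cdf((w_plus - mu + 0.5) / sigma))
        p_greater = float(stats.norm.sf((w_plus - mu - 0.5) / sigma))
        method = "normal_approx"
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return SignedRankResult(
        w_plus=w_plus,
        n_effective=n,
        p_value=p,
        alternative=alternative,
        method=method,
    )


def stratify_by_baseline_auc(
    baseline_aucs: Mapping[str, float],
    cutoff: float = 1000.0,
) -> StratificationResult:
    """Split subjects into low (< cutoff) and high (>= cutoff) baseline-AUC groups.

    The cutoff must lie strictly between the minimum and maximum observed
    values so both groups are non-empty.
    """
    if not baseline_aucs:
        raise ValueError("no baseline AUC values supplied")
    vals = list(baseline_aucs.values())
    lo, hi = min(vals), max(vals)
    if not lo < cutoff < hi:
        raise ValueError(
            f"cutoff {cutoff} must lie strictly inside the data range ({lo}, {hi})"
        )
    low = tuple(s for s, v in baseline_aucs.items() if v < cutoff)
    high = tuple(s for s, v in baseline_aucs.items() if v >= cutoff)
    return StratificationResult(cutoff=cutoff, low=low, high=high)


def power_by_simulation(
    effect_mean: float,
    effect_sd: float,
    n_subjects: int,
    alpha: float = 0.05,
    alternative: str = "less",
    n_sim: int = 20_000,
    seed: int | None = None,
) -> PowerEstimate:
    """Monte-Carlo power of the one-sided signed-rank test.

    Each replicate draws ``n_subjects`` per-subject ddAUC values from
    N(effect_mean, effect_sd^2) and applies the signed-rank test at level
    ``alpha`` (rejection when p <= alpha); power is the rejection fraction,
    with its binomial Monte-Carlo standard error.  The per-replicate p-values
    use the same conventions as :func:`exact_wilcoxon_signed_rank` — the exact
    enumeration null for n <= 20, the continuity-corrected normal beyond.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    if effect_sd <= 0:
        raise ValueError("effect_sd must be positive")
    if alternative not in ("less", "greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    x = rng.normal(effect_mean, effect_sd, size=(n_sim, n_subjects))
    ranks = stats.rankdata(np.abs(x), axis=1)  # ties have measure zero
    w = np.sum(ranks * (x > 0), axis=1)

    eps = 1e-9
    if n_subjects <= EXACT_ENUMERATION_LIMIT:
        sums = np.sort(_signed_rank_null_sums(np.arange(1.0, n_subjects + 1.0)))
        total = sums.size
        p_less = np.searchsorted(sums, w + eps, side="right") / total
        p_greater = (total - np.searchsorted(sums, w - eps, side="left")) / total
    else:
        mu = n_subjects * (n_subjects + 1) / 4.0
        sigma = math.sqrt(n_subjects * (n_subjects + 1) * (2 * n_subjects + 1) / 24.0)
        p_less = stats.norm.cdf((w - mu + 0.5) / sigma)
        p_greater = stats.norm.sf((w - mu - 0.5) / sigma)
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = np.minimum(1.0, 2.0 * np.minimum(p_less, p_greater))
    power = float(np.mean(p <= alpha))
    mc_se = math.sqrt(power * (1.0 - power) / n_sim)
    return PowerEstimate(
        n_subjects=n_subjects,
        alpha=alpha,
        effect_mean=effect_mean,
        effect_sd=effect_sd,
        n_sim=n_sim,
        power=power,
        mc_se=mc_se,
        seed=seed,
    )
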