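"""Diagnostic-accuracy statistics for the max-VAF urine test.

Covers everything reported downstream of the binary call: 2x2 tables with
sensitivity/specificity and exact (Clopper-Pearson) binomial confidence
intervals, ROC curves and AUC from a threshold sweep of the max-VAF score,
age-band false-positive rates among disease-free patients, rank-based group
comparisons of VAF distributions, a gene-by-stratum detection table for
incident disease, and the relative risk of future recurrence for
test-positive vs test-negative surveillance patients.

Percentages print with round-half-away-from-zero (so 73.24 -> 73, 94.80 ->
95), matching clinical reporting conventions rather than banker's rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import SampleCall, per_gene_calls, ThresholdLike
from .panel import Panel, SampleMeta, STRATA, stratum_of
from .quantify import MaxVafStat

__all__ = [
    "TwoByTwo",
    "ProportionCI",
    "RocResult",
    "RelativeRisk",
    "GroupComparison",
    "round_half_away",
    "percent",
    "exact_binomial_ci",
    "sens_spec",
    "sens_spec_from_counts",
    "roc_auc",
    "relative_risk",
    "age_band_fpr",
    "compare_groups",
    "stratified_table",
    "DEFAULT_AGE_BANDS",
]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (0.5 -> 1), unlike numpy's half-to-even."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def percent(x: float, decimals: int = 0) -> float:
    """A proportion as a printed percentage (half-away-from-zero)."""
    return round_half_away(100.0 * x, decimals)


@dataclass(frozen=True)
class TwoByTwo:
    """Disease-by-call counts (or exposure-by-event for relative risk)."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("negative cell count")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class ProportionCI:
    k: int
    n: int
    point: float
    lower: float
    upper: float
    level: float

    def percent_str(self, decimals: int = 0) -> str:
        fmt = f"%.{decimals}f"
        return (
            f"{fmt % percent(self.point, decimals)}% "
            f"({self.level:.0%} CI {fmt % percent(self.lower, decimals)}-"
            f"{fmt % percent(self.upper, decimals)}%)"
        )


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Clopper-Pearson exact binomial interval via beta quantiles.

    lower = Beta(alpha/2; k, n-k+1), upper = Beta(1-alpha/2; k+1, n-k);
    the boundaries k=0 and k=n pin the respective limit to 0 or 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.isf(alpha / 2, k + 1, n - k))
    return ProportionCI(k=k, n=n, point=k / n, lower=lower, upper=upper, level=level)


def sens_spec_from_counts(
    tp: int, fn: int, fp: int, tn: int, level: float = 0.95
) -> tuple[TwoByTwo, Optional[ProportionCI], Optional[ProportionCI]]:
    """Sensitivity and specificity with exact CIs from a 2x2 table.

    A zero denominator yields ``None`` for that statistic rather than an
    exception (the table itself is still returned).
    """
    t = TwoByTwo(tp, fn, fp, tn)
    sens = exact_binomial_ci(tp, t.n_diseased, level) if t.n_diseased else None
    spec = exact_binomial_ci(tn, t.n_healthy, level) if t.n_healthy else None
    return t, sens, spec


def sens_spec(
    calls: Sequence[SampleCall],
    labels: Sequence[SampleMeta],
    level: float = 0.95,
) -> tuple[TwoByTwo, Optional[ProportionCI], Optional[ProportionCI]]:
    """Pair calls with disease labels and compute sensitivity/specificity."""
    status = {m.sample_id: m.bc_status for m in labels}
    tp = fn = fp = tn = 0
    for c in calls:
        if c.sample_id not in status:
            raise ValueError(f"call for unlabelled sample {c.sample_id}")
        diseased = status[c.sample_id]
        if diseased:
            tp, fn = tp + c.positive, fn + (not c.positive)
        else:
            fp, tn = fp + c.positive, tn + (not c.positive)
    return sens_spec_from_counts(tp, fn, fp, tn, level)


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    """ROC points (1-specificity, sensitivity) and trapezoidal AUC.

    The sweep treats every distinct observed score as a candidate threshold
    with the same strict-> rule as the classifier; the trapezoid over those
    points equals the Mann-Whitney U statistic scaled by n1*n2, with tied
    score pairs given half credit.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_auc(scores: Sequence[float], diseased: Sequence[bool]) -> RocResult:
    """Threshold-sweep ROC and AUC for a score (here: per-sample max VAF)."""
    y = np.asarray(diseased, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size or y.size == 0:
        raise ValueError("scores and labels must be equal-length, non-empty")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes present")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative counts at each distinct-score boundary: call positive if > t
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


# ---------------------------------------------------------------------------
# relative risk


@dataclass(frozen=True)
class RelativeRisk:
    risk_exposed: float
    risk_unexposed: float
    rr: float
    lower: float
    upper: float
    level: float
    method: str
    continuity_corrected: bool


def relative_risk(
    a: int, b: int, c: int, d: int, level: float = 0.95
) -> RelativeRisk:
    """Risk ratio for a 2x2 of exposed (a events, b non-events) vs
    unexposed (c events, d non-events), with a Katz log-normal CI.

    Zero event cells get a 0.5 continuity correction (flagged) for the
    ratio and CI; an unexposed arm with zero events and no correction
    would be infinite.
    """
    if a + b <= 0 or c + d <= 0:
        raise ValueError("each exposure arm needs at least one subject")
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    risk_e = a / (a + b)
    risk_u = c / (c + d)
    corrected = a == 0 or c == 0
    if corrected:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = float(a), float(b), float(c), float(d)
    rr = (a_ / (a_ + b_)) / (c_ / (c_ + d_))
    if not corrected:
        rr = risk_e / risk_u  # exact ratio when well-defined
    z = sps.norm.isf((1 - level) / 2)
    se = math.sqrt(1 / a_ - 1 / (a_ + b_) + 1 / c_ - 1 / (c_ + d_))
    log_rr = math.log(rr) if rr > 0 else -math.inf
    return RelativeRisk(
        risk_exposed=risk_e,
        risk_unexposed=risk_u,
        rr=rr,
        lower=math.exp(log_rr - z * se),
        upper=math.exp(log_rr + z * se),
        level=level,
        method="katz-log",
        continuity_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# age-band false-positive rates

DEFAULT_AGE_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 50.0),
    (50.0, 65.0),
    (65.0, math.inf),
)


def age_band_fpr(
    calls: Sequence[SampleCall],
    labels: Sequence[SampleMeta],
    bands: Sequence[tuple[float, float]] = DEFAULT_AGE_BANDS,
) -> pd.DataFrame:
    """False-positive rate per age band among disease-free samples.

    Bands are half-open [lo, hi).  Returns one row per band with n,
    positives and rate (NaN when the band is empty).  Diseased samples are
    rejected — the caller filters the cohort.
    """
    meta = {m.sample_id: m for m in labels}
    rows = []
    for lo, hi in bands:
        n = pos = 0
        for c in calls:
            m = meta.get(c.sample_id)
            if m is None:
                raise ValueError(f"call for unlabelled sample {c.sample_id}")
            if m.bc_status:
                raise ValueError(
                    f"sample {c.sample_id} has disease; age-band FPR is for "
                    "disease-free samples only"
                )
            if lo <= m.age < hi:
                n += 1
                pos += c.positive
        label = f"[{lo:g},{hi:g})" if math.isfinite(hi) else f">={lo:g}"
        rows.append(
            {
                "band": label,
                "age_lo": lo,
                "age_hi": hi,
                "n": n,
                "positives": pos,
                "fpr": pos / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class GroupComparison:
    median_a: float
    median_b: float
    p_value: float
    statistic: float
    method: str


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "asymptotic",
    alternative: str = "two-sided",
) -> GroupComparison:
    """Mann-Whitney rank-sum comparison of two VAF distributions.

    The asymptotic normal approximation with tie correction is the default
    (sample sizes here are in the hundreds); medians are reported alongside
    so the headline summary never depends on the test choice.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupComparison(
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        method=f"mann-whitney-{method}",
    )


# ---------------------------------------------------------------------------
# gene-by-stratum detection table


def stratified_table(
    vaf_table: pd.DataFrame,
    labels: Sequence[SampleMeta],
    panel: Panel,
    threshold: ThresholdLike,
    gene_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Detection counts per gene across stage/grade strata of incident BC.

    Columns are the reporting strata plus "All BCs" and "Non-BCs"; rows are
    genes, an "Any" row (samples positive in >=1 gene — identical to the
    sample-level call), an "n" row, and sensitivity/specificity rows as
    printed percentages (NaN where undefined).  Disease-free samples
    contribute only to the Non-BCs column; unknown strata route to
    "Other BC".
    """
    meta = {m.sample_id: m for m in labels}
    genes = list(gene_order) if gene_order is not None else panel.genes
    cols = list(STRATA) + ["All BCs", "Non-BCs"]
    counts = {g: {c: 0 for c in cols} for g in genes}
    any_row = {c: 0 for c in cols}
    totals = {c: 0 for c in cols}

    for sid, sub in vaf_table.groupby("sample_id", sort=False):
        m = meta.get(str(sid))
        if m is None:
            raise ValueError(f"VAF table sample {sid} missing from labels")
        flags = per_gene_calls(sub, panel, threshold)
        if m.bc_status:
            strat = stratum_of(m)
            sample_cols = [strat, "All BCs"]
        else:
            sample_cols = ["Non-BCs"]
        for col in sample_cols:
            totals[col] += 1
            any_row[col] += flags["Any"]
            for g in genes:
                counts[g][col] += flags.get(g, False)

    rows = {g: counts[g] for g in genes}
    rows["Any"] = any_row
    rows["n"] = totals
    df = pd.DataFrame(rows).T[cols]

    sens = {
        c: (percent(any_row[c] / totals[c]) if totals[c] and c != "Non-BCs" else np.nan)
        for c in cols
    }
    spec = {
        c: (
            percent(1 - any_row[c] / totals[c])
            if c == "Non-BCs" and totals[c]
            else np.nan
        )
        for c in cols
    }
    df.loc["Sensitivity"] = pd.Series(sens)
    df.loc["Specificity"] = pd.Series(spec)
    return df
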