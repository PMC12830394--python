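"""Diagnostic-performance and agreement statistics.

The battery mirrors what a staging study reports: empirical ROC with the
Youden-index operating point and confusion metrics, intraclass correlation
(two-way random effects, absolute agreement, single measures), Bland-Altman
agreement, Kruskal-Wallis with Bonferroni-adjusted Dunn post hoc tests,
one-way ANOVA, Lilliefors-corrected Kolmogorov-Smirnov normality screening,
and per-stage descriptive tables.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import AnalysisError


# --------------------------------------------------------------------------
# ROC / Youden
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    youden_j: float
    ci_auc: tuple[float, float]
    curve: np.ndarray  # ordered (fpr, tpr) pairs

    def to_dict(self) -> dict:
        return {
            "auc": round(self.auc, 2),
            "cutoff": round(self.cutoff, 2),
            "sensitivity_pct": int(np.floor(100 * self.sensitivity + 0.5)),
            "specificity_pct": int(np.floor(100 * self.specificity + 0.5)),
            "ppv_pct": (None if np.isnan(self.ppv)
                        else int(np.floor(100 * self.ppv + 0.5))),
            "npv_pct": (None if np.isnan(self.npv)
                        else int(np.floor(100 * self.npv + 0.5))),
            "accuracy_pct": int(np.floor(100 * self.accuracy + 0.5)),
            "youden_j": round(self.youden_j, 3),
            "ci_auc": [round(self.ci_auc[0], 2), round(self.ci_auc[1], 2)],
        }


def _confusion_at(values: np.ndarray, labels: np.ndarray, cutoff: float
                  ) -> tuple[float, float, float, float, float]:
    pred = values >= cutoff
    tp = float(np.sum(pred & (labels == 1)))
    fp = float(np.sum(pred & (labels == 0)))
    fn = float(np.sum(~pred & (labels == 1)))
    tn = float(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp > 0 else np.nan
    npv = tn / (tn + fn) if tn + fn > 0 else np.nan
    acc = (tp + tn) / labels.size
    return sens, spec, ppv, npv, acc


def roc_analysis(
    values: Sequence[float], labels: Sequence[int],
    positive_direction: str = "higher",
    n_boot: int = 2000, seed: int = 0,
) -> ROCResult:
    """Empirical ROC with the Youden-index operating point.

    Positive class = higher stiffness.  The cutoff is an observed value with
    the convention "value >= cutoff is test-positive"; ties in the Youden
    index break toward higher specificity, then the lower cutoff.  The AUC
    confidence interval is a seeded stratified bootstrap (percentile,
    resampling within each class so both classes persist).
    """
    if positive_direction != "higher":
        raise AnalysisError("only positive_direction='higher' is supported")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape:
        raise AnalysisError("values and labels must align")
    if len(np.unique(labels)) < 2:
        raise AnalysisError("both classes must be present")

    fpr, tpr, _ = _sk_roc_curve(labels, values)
    auc = float(np.trapezoid(tpr, fpr))

    # exhaustive scan over observed values as candidate cutoffs
    cand = np.unique(values)
    sens = np.array([np.mean(values[labels == 1] >= c) for c in cand])
    spec = np.array([np.mean(values[labels == 0] < c) for c in cand])
    j = sens + spec - 1.0
    best = j == j.max()
    best &= spec == spec[best].max()
    cutoff = float(cand[best][0])  # cand ascending: first is the lowest

    se, sp, ppv, npv, acc = _confusion_at(values, labels, cutoff)

    rng = np.random.default_rng(seed)
    pos, neg = values[labels == 1], values[labels == 0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        vp = rng.choice(pos, pos.size, replace=True)
        vn = rng.choice(neg, neg.size, replace=True)
        v = np.concatenate([vn, vp])
        y = np.concatenate([np.zeros(vn.size, int), np.ones(vp.size, int)])
        f, t, _ = _sk_roc_curve(y, v)
        boot[b] = np.trapezoid(t, f)
    lo, hi = np.percentile(boot, [2.5, 97.5])

    return ROCResult(auc=auc, cutoff=cutoff, sensitivity=se, specificity=sp,
                     ppv=ppv, npv=npv, accuracy=acc, youden_j=se + sp - 1.0,
                     ci_auc=(float(lo), float(hi)),
                     curve=np.column_stack([fpr, tpr]))


def auc_concordance(values: Sequence[float], labels: Sequence[int]) -> float:
    """Pairwise-concordance (Mann-Whitney) AUC, ties counted one half.

    Independent of the trapezoidal route; used as a cross-check oracle.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = values[labels == 1][:, None]
    neg = values[labels == 0][None, :]
    return float(np.mean((pos > neg) + 0.5 * (pos == neg)))


# --------------------------------------------------------------------------
# Agreement: ICC and Bland-Altman
# --------------------------------------------------------------------------

@dataclass
class AgreementResult:
    icc: float | None = None
    icc_ci: tuple[float, float] | None = None
    mean_diff: float | None = None
    sd_diff: float | None = None
    loa: tuple[float, float] | None = None
    loa_1sd: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        out = {}
        if self.icc is not None:
            out["icc"] = round(self.icc, 3)
            out["icc_ci"] = [round(self.icc_ci[0], 3), round(self.icc_ci[1], 3)]
        if self.mean_diff is not None:
            out["mean_diff"] = round(self.mean_diff, 3)
            out["sd_diff"] = round(self.sd_diff, 3)
            out["loa"] = [round(x, 3) for x in self.loa]
            out["loa_1sd"] = [round(x, 3) for x in self.loa_1sd]
        return out


def icc(matrix: np.ndarray, model: str = "icc2_1",
        confidence: float = 0.95) -> AgreementResult:
    """Single-measure, absolute-agreement, two-way random-effects ICC.

    Computed from the two-way ANOVA mean squares (subjects x raters, no
    missing cells); the confidence interval is the standard F-based one.
    Identical columns with subject variation return ICC = 1 with a warning
    (zero residual variance).
    """
    if model != "icc2_1":
        raise AnalysisError(f"unsupported ICC model {model!r}")
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise AnalysisError("need >= 3 subjects and >= 2 raters")
    if not np.all(np.isfinite(X)):
        raise AnalysisError("missing cells are not supported")
    n, k = X.shape
    if np.all(X == X[:, [0]]):
        if np.ptp(X[:, 0]) == 0:
            warnings.warn("zero total variance: ICC undefined", stacklevel=2)
            return AgreementResult(icc=np.nan, icc_ci=(np.nan, np.nan))
        warnings.warn("identical rater columns: ICC = 1 by convention",
                      stacklevel=2)
        return AgreementResult(icc=1.0, icc_ci=(1.0, 1.0))
    gm = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ss_rows = k * np.sum((row_m - gm) ** 2)
    ss_cols = n * np.sum((col_m - gm) ** 2)
    ss_tot = np.sum((X - gm) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))

    if ss_tot == 0:
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return AgreementResult(icc=np.nan, icc_ci=(np.nan, np.nan))
    if mse == 0 and msc == 0:
        warnings.warn("identical rater columns: ICC = 1 by convention",
                      stacklevel=2)
        return AgreementResult(icc=1.0, icc_ci=(1.0, 1.0))

    icc_val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # F-based interval (two-way random, absolute agreement, single measures)
    alpha = 1.0 - confidence
    fj = msc / mse if mse > 0 else np.inf
    a = (k * icc_val) / (n * (1 - icc_val)) if icc_val < 1 else np.inf
    num = ((k - 1) * (n - 1) *
           (k * icc_val * fj + n * (1 + (k - 1) * icc_val) - k * icc_val) ** 2)
    den = ((n - 1) * k ** 2 * icc_val ** 2 * fj ** 2 +
           (n * (1 + (k - 1) * icc_val) - k * icc_val) ** 2)
    with np.errstate(invalid="ignore", over="ignore"):
        v = num / den if den > 0 else np.nan
    if not np.isfinite(v) or v <= 0:
        lo = hi = np.nan
    else:
        f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msr - f_lo * mse) /
              (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr))
        hi = (n * (f_hi * msr - mse) /
              (k * msc + (k * n - k - n) * mse + n * f_hi * msr))
    return AgreementResult(icc=float(icc_val), icc_ci=(float(lo), float(hi)))


def bland_altman(pairs: Sequence[tuple[float, float]]) -> AgreementResult:
    """Mean and SD of paired differences with +-1.96 SD and +-1 SD bands."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise AnalysisError("need >= 2 (m1, m2) pairs")
    d = arr[:, 0] - arr[:, 1]
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        mean_diff=mean, sd_diff=sd,
        loa=(mean - 1.96 * sd, mean + 1.96 * sd),
        loa_1sd=(mean - sd, mean + sd),
    )


# --------------------------------------------------------------------------
# Group comparisons
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    kind: str  # "kruskal_wallis" | "anova"
    pairwise: dict[tuple[int, int], float] = field(default_factory=dict)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "statistic": round(self.statistic, 4),
            "p_value": round(self.p_value, 4),
            "pairwise": {f"{a}-{b}": round(p, 4)
                         for (a, b), p in self.pairwise.items()},
        }


def _check_groups(groups: Sequence[Sequence[float]], min_groups: int = 2) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < min_groups:
        raise AnalysisError(f"need >= {min_groups} groups")
    if any(a.size == 0 for a in arrs):
        raise AnalysisError("empty group")
    return arrs


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k - 1)."""
    arrs = _check_groups(groups)
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied: H = 0, p = 1", stacklevel=2)
        return GroupComparison(statistic=0.0, p_value=1.0,
                               kind="kruskal_wallis", degenerate=True)
    h, p = stats.kruskal(*arrs)
    return GroupComparison(statistic=float(h), p_value=float(p),
                           kind="kruskal_wallis")


def kruskal_wallis_permutation_p(groups: Sequence[Sequence[float]],
                                 n_perm: int = 100_000,
                                 seed: int = 0) -> float:
    """Permutation p-value for the Kruskal-Wallis H (Monte-Carlo oracle).

    Ranks are assigned once and shuffled; H is computed from permuted rank
    sums (with the tie correction, which is permutation-invariant), so the
    resampling is fully vectorized.
    """
    arrs = _check_groups(groups)
    sizes = np.array([a.size for a in arrs])
    pooled = np.concatenate(arrs)
    n_tot = pooled.size
    h_obs = stats.kruskal(*arrs).statistic

    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - np.sum(counts ** 3 - counts) / (n_tot ** 3 - n_tot)
    edges = np.cumsum(np.concatenate([[0], sizes]))

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(ranks, (n_perm, 1)), axis=1)
    h = np.zeros(n_perm)
    for i in range(sizes.size):
        rsum = perm[:, edges[i]:edges[i + 1]].sum(axis=1)
        h += rsum ** 2 / sizes[i]
    h = (12.0 / (n_tot * (n_tot + 1)) * h - 3.0 * (n_tot + 1)) / tie_corr
    return float(np.mean(h >= h_obs - 1e-12))


def dunn_posthoc(groups: Sequence[Sequence[float]],
                 adjust: str = "bonferroni") -> dict[tuple[int, int], float]:
    """Dunn pairwise rank tests after Kruskal-Wallis.

    z-statistics on pooled mid-ranks with the tie correction; two-sided
    normal p-values; Bonferroni adjustment min(1, p * m), m = k(k-1)/2.
    """
    if adjust != "bonferroni":
        raise AnalysisError(f"unsupported adjustment {adjust!r}")
    arrs = _check_groups(groups)
    k = len(arrs)
    sizes = np.array([a.size for a in arrs])
    pooled = np.concatenate(arrs)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    edges = np.cumsum(np.concatenate([[0], sizes]))
    mean_ranks = np.array([ranks[edges[i]:edges[i + 1]].mean()
                           for i in range(k)])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n_tot - 1))
    m = k * (k - 1) // 2
    out: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            var = (n_tot * (n_tot + 1) / 12.0 - tie_term) * \
                (1.0 / sizes[i] + 1.0 / sizes[j])
            if var <= 0:
                out[(i, j)] = 1.0
                continue
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p_raw = 2.0 * stats.norm.sf(abs(z))
            out[(i, j)] = min(1.0, p_raw * m)
    return out


def one_way_anova(groups: Sequence[Sequence[float]]) -> GroupComparison:
    """F and p from between/within mean squares."""
    arrs = _check_groups(groups)
    if any(a.size < 2 for a in arrs):
        raise AnalysisError("ANOVA needs >= 2 values per group")
    if all(np.allclose(a, a[0]) for a in arrs):
        warnings.warn("zero within-group variance everywhere", stacklevel=2)
        return GroupComparison(statistic=np.inf, p_value=0.0, kind="anova",
                               degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrs)
    return GroupComparison(statistic=float(f), p_value=float(p), kind="anova")


# --------------------------------------------------------------------------
# Normality and descriptives
# --------------------------------------------------------------------------

def ks_normality(values: Sequence[float], n_sim: int = 1000,
                 seed: int = 0) -> float:
    """Lilliefors-corrected one-sample KS p-value against a fitted Normal.

    The KS statistic is computed against N(sample mean, sample SD); the null
    distribution of the statistic (which is not the classical KS null when
    parameters are estimated) is simulated with ``n_sim`` seeded Gaussian
    replicates, each refitting its own parameters.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise AnalysisError("need >= 5 values")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise AnalysisError("zero variance: normality test degenerate")

    def lillie_d(sample: np.ndarray) -> float:
        m, s = sample.mean(), np.std(sample, ddof=1)
        return stats.kstest(sample, "norm", args=(m, s)).statistic

    d_obs = lillie_d(x)
    rng = np.random.default_rng(seed)
    d_null = np.array([lillie_d(rng.standard_normal(x.size))
                       for _ in range(n_sim)])
    return float((1 + np.sum(d_null >= d_obs)) / (n_sim + 1))


def descriptive_by_stage(df: pd.DataFrame, variable: str,
                         stage_col: str = "stage") -> pd.DataFrame:
    """Per-stage descriptives: mean, SD, min, max, median, Q1, Q3."""
    if df.empty:
        raise AnalysisError("empty table")
    rows = []
    for stage, grp in df.groupby(stage_col, sort=True):
        v = grp[variable].to_numpy(dtype=float)
        rows.append({
            "stage": stage, "n": v.size,
            "mean": np.mean(v),
            "sd": np.std(v, ddof=1) if v.size > 1 else 0.0,
            "min": np.min(v), "max": np.max(v),
            "median": np.median(v),
            "q1": np.percentile(v, 25), "q3": np.percentile(v, 75),
        })
    return pd.DataFrame(rows).set_index("stage")
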