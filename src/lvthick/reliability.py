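"""Reliability and comparison statistics.

* ICC(2,1) — two-way random effects, absolute agreement, single measurement —
  computed from the ANOVA mean squares, with the F-based 95% confidence
  interval (McGraw & Wong case 2A) and the conventional reliability bands:
  poor < 0.5 <= moderate <= 0.75 < good <= 0.9 < excellent.
* Normality-gated comparisons: Shapiro-Wilk at alpha = 0.05 selects the
  parametric branch (paired/independent t) or the nonparametric branch
  (Wilcoxon signed-rank / Mann-Whitney U).
* Table builders producing the study's four report shapes from a tidy
  two-reader cohort table: per-group method comparison, sex-stratified method
  comparison, per-method group comparison, and per-method ICC — each with 19
  rows (S1..S16 plus the three aggregate rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    IncompleteDesignError,
    InsufficientDataError,
    InvalidPairingError,
    UndefinedICCError,
)
from .segmentation import APICAL_SEGMENTS, BASAL_SEGMENTS, MID_SEGMENTS, SEGMENTS

ALPHA = 0.05

AGGREGATE_ROWS = {
    "S_AVG_BAS": BASAL_SEGMENTS,
    "S_AVG_MID": MID_SEGMENTS,
    "S_AVG_API": APICAL_SEGMENTS,
}
TABLE_ROWS = tuple(SEGMENTS) + tuple(AGGREGATE_ROWS)


def classify_reliability(icc: float) -> str:
    """Reliability band of an ICC value.

    Boundary values fall in the lower band: 0.5 and 0.75 are "moderate",
    0.9 is "good"; only values strictly above 0.9 are "excellent".
    """
    if not np.isfinite(icc):
        raise ValueError("icc must be finite")
    if icc < 0.5:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation point estimate with confidence limits."""

    icc: float
    ci_low: float
    ci_high: float
    model: str
    classification: str
    n_subjects: int
    n_raters: int


def icc_two_way_single(ratings: np.ndarray, confidence: float = 0.95,
                       model: str = "ICC(2,1)") -> ICCResult:
    """ICC for absolute agreement of single ratings, two-way random effects.

    Parameters
    ----------
    ratings : (n_subjects, k_raters) array
        Complete matrix of ratings (no missing cells).
    model : {"ICC(2,1)", "ICC(3,1)"}
        ICC(3,1) (two-way mixed, consistency) is available for sensitivity
        analysis; the default is absolute agreement.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise InsufficientDataError("ratings must be (n_subjects, k>=2 raters)")
    n, k = x.shape
    if n < 5:
        raise InsufficientDataError(f"need >= 5 subjects, got {n}")
    if not np.all(np.isfinite(x)):
        raise InsufficientDataError("ratings contain missing/non-finite cells")
    if np.ptp(x) == 0.0:
        raise UndefinedICCError("zero total variance: ICC undefined")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)              # between-subject mean square
    msc = ss_cols / (k - 1)              # between-rater mean square
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)  # residual mean square

    alpha = 1.0 - confidence
    if model == "ICC(3,1)":
        denom = msr + (k - 1) * mse
        icc = (msr - mse) / denom if denom > 0 else 1.0
        f_obs = msr / mse if mse > 0 else np.inf
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + (k - 1)) if np.isfinite(fl) else 1.0
        hi = (fu - 1) / (fu + (k - 1)) if np.isfinite(fu) else 1.0
    elif model == "ICC(2,1)":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = (msr - mse) / denom if denom > 0 else 1.0
        if mse > 0:
            # Satterthwaite df for the agreement interval (McGraw & Wong 2A)
            fj = msc / mse
            vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
            vd = ((n - 1) * k ** 2 * icc ** 2 * fj ** 2
                  + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
            v = vn / vd if vd > 0 else 1.0
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr)
        else:
            # perfect within-cell agreement: the interval degenerates
            lo = hi = icc
    else:
        raise ValueError(f"unknown ICC model {model!r}")

    icc = float(min(icc, 1.0))
    lo = float(min(lo, icc))
    hi = float(max(hi, icc))
    return ICCResult(icc=icc, ci_low=lo, ci_high=hi, model=model,
                     classification=classify_reliability(icc),
                     n_subjects=n, n_raters=k)


# ---------------------------------------------------------------------------
# Gated comparisons


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    test_used: str
    normality_p: tuple
    n: int


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk p-value; degenerate (constant) samples are treated as
    compatible with normality (the parametric branch handles them exactly)."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0.0:
        return 1.0
    return float(stats.shapiro(x).pvalue)


def compare_paired(a, b, paper_compat: bool = False) -> ComparisonResult:
    """Paired comparison with a Shapiro-Wilk gate on the differences.

    Normal differences -> paired t-test; otherwise Wilcoxon signed-rank.
    ``paper_compat=True`` substitutes a Kruskal-Wallis H-test on the two
    samples for the nonparametric branch, replicating a published procedure
    that names that (independent-groups) test for related parameters.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidPairingError(f"matched lists required, got {a.shape} vs {b.shape}")
    if a.size < 3:
        raise InvalidPairingError("need >= 3 pairs")
    d = a - b
    p_norm = _shapiro_p(d)
    if np.ptp(d) == 0.0:
        # identical pairs: zero differences, trivially non-significant
        p = 1.0 if np.all(d == 0) else np.nan
        return ComparisonResult(0.0, float(p), "paired-t", (p_norm,), a.size)
    if p_norm >= ALPHA:
        res = stats.ttest_rel(a, b)
        return ComparisonResult(float(res.statistic), float(res.pvalue),
                                "paired-t", (p_norm,), a.size)
    if paper_compat:
        res = stats.kruskal(a, b)
        return ComparisonResult(float(res.statistic), float(res.pvalue),
                                "kruskal-wallis-h", (p_norm,), a.size)
    res = stats.wilcoxon(a, b)
    return ComparisonResult(float(res.statistic), float(res.pvalue),
                            "wilcoxon-signed-rank", (p_norm,), a.size)


def compare_independent(a, b) -> ComparisonResult:
    """Independent-group comparison with a per-group Shapiro-Wilk gate.

    Both groups normal -> independent t-test; otherwise Mann-Whitney U.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 values")
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    n = int(a.size + b.size)
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return ComparisonResult(0.0, p, "independent-t", (pa, pb), n)
    if pa >= ALPHA and pb >= ALPHA:
        res = stats.ttest_ind(a, b)
        return ComparisonResult(float(res.statistic), float(res.pvalue),
                                "independent-t", (pa, pb), n)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(float(res.statistic), float(res.pvalue),
                            "mann-whitney-u", (pa, pb), n)


# ---------------------------------------------------------------------------
# Table builders


def _require(cohort: pd.DataFrame, column: str, levels) -> None:
    present = set(cohort[column].unique())
    missing = [lv for lv in levels if lv not in present]
    if missing:
        raise IncompleteDesignError(f"cohort is missing {column} level(s): {missing}")


def _subject_values(cohort: pd.DataFrame, method: str) -> pd.DataFrame:
    """Per subject x segment values for one method, averaged over readers,
    with the three aggregate rows appended."""
    sub = cohort[cohort["method"] == method]
    wide = (sub.groupby(["subject", "segment"])["value_mm"].mean()
            .unstack("segment"))
    for row, segs in AGGREGATE_ROWS.items():
        wide[row] = wide[list(segs)].mean(axis=1)
    return wide[list(TABLE_ROWS)]


def _reader_values(cohort: pd.DataFrame, method: str) -> pd.DataFrame:
    sub = cohort[cohort["method"] == method]
    wide = (sub.groupby(["subject", "reader", "segment"])["value_mm"].mean()
            .unstack("segment"))
    for row, segs in AGGREGATE_ROWS.items():
        wide[row] = wide[list(segs)].mean(axis=1)
    return wide[list(TABLE_ROWS)]


def method_comparison_table(cohort: pd.DataFrame, group: str,
                            methods: tuple = ("single_caliper", "contour_averaged"),
                            paper_compat: bool = False) -> pd.DataFrame:
    """Within-group, per-segment comparison of the two measurement methods
    (paired across subjects), with mean +/- SD columns and the gated p-value."""
    _require(cohort, "group", [group])
    _require(cohort, "method", methods)
    sub = cohort[cohort["group"] == group]
    a = _subject_values(sub, methods[0])
    b = _subject_values(sub, methods[1])
    common = a.index.intersection(b.index)
    rows = []
    for row in TABLE_ROWS:
        x, y = a.loc[common, row].to_numpy(), b.loc[common, row].to_numpy()
        cmp_ = compare_paired(x, y, paper_compat=paper_compat)
        rows.append({
            "row": row,
            f"{methods[0]}_mean_mm": x.mean(), f"{methods[0]}_sd_mm": x.std(ddof=1),
            f"{methods[1]}_mean_mm": y.mean(), f"{methods[1]}_sd_mm": y.std(ddof=1),
            "p_value": cmp_.p_value, "test_used": cmp_.test_used,
            "significant": "#" if cmp_.p_value < ALPHA else "",
        })
    return pd.DataFrame(rows).set_index("row")


def group_comparison_table(cohort: pd.DataFrame, method: str,
                           groups: tuple) -> pd.DataFrame:
    """Per-method, per-segment comparison between two subject groups."""
    _require(cohort, "group", groups)
    _require(cohort, "method", [method])
    parts = {g: _subject_values(cohort[cohort["group"] == g], method) for g in groups}
    rows = []
    for row in TABLE_ROWS:
        x = parts[groups[0]][row].to_numpy()
        y = parts[groups[1]][row].to_numpy()
        cmp_ = compare_independent(x, y)
        rows.append({
            "row": row,
            f"{groups[0]}_mean_mm": x.mean(), f"{groups[0]}_sd_mm": x.std(ddof=1),
            f"{groups[1]}_mean_mm": y.mean(), f"{groups[1]}_sd_mm": y.std(ddof=1),
            "p_value": cmp_.p_value, "test_used": cmp_.test_used,
            "significant": "#" if cmp_.p_value < ALPHA else "",
        })
    return pd.DataFrame(rows).set_index("row")


def icc_table(cohort: pd.DataFrame, method: str) -> pd.DataFrame:
    """Per-segment two-reader ICC(2,1) with confidence limits and band."""
    _require(cohort, "method", [method])
    _require(cohort, "reader", ["A", "B"])
    wide = _reader_values(cohort, method)
    rows = []
    for row in TABLE_ROWS:
        mat = wide[row].unstack("reader").to_numpy()
        try:
            res = icc_two_way_single(mat)
            rows.append({"row": row, "icc": res.icc, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "classification": res.classification})
        except UndefinedICCError:
            rows.append({"row": row, "icc": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "classification": "undefined"})
    return pd.DataFrame(rows).set_index("row")


def build_tables(cohort: pd.DataFrame,
                 groups: tuple = ("LVET-like", "HEALTHY-like"),
                 methods: tuple = ("single_caliper", "contour_averaged"),
                 paper_compat: bool = False) -> dict:
    """Build the four report-table shapes from a tidy two-reader cohort.

    Returns a dict of DataFrames: ``method_comparison`` (one per group),
    ``method_comparison_by_sex`` (one per group x sex, when a sex column with
    both levels is present), ``group_comparison`` (one per method) and
    ``icc`` (one per method).  Every table has 19 rows: S1..S16 plus
    S_AVG_BAS/MID/API.
    """
    for col in ("subject", "group", "reader", "method", "segment", "value_mm"):
        if col not in cohort.columns:
            raise IncompleteDesignError(f"cohort table is missing column {col!r}")
    out: dict = {
        "method_comparison": {
            g: method_comparison_table(cohort, g, methods, paper_compat) for g in groups},
        "group_comparison": {
            m: group_comparison_table(cohort, m, groups) for m in methods},
        "icc": {m: icc_table(cohort, m) for m in methods},
    }
    if "sex" in cohort.columns and set(cohort["sex"].unique()) >= {"M", "F"}:
        out["method_comparison_by_sex"] = {
            (g, sex): method_comparison_table(
                cohort[cohort["sex"] == sex], g, methods, paper_compat)
            for g in groups for sex in ("M", "F")}
    return out
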