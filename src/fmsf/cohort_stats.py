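"""Cohort-level statistical procedures for flowmotion parameters.

Implements the group analyses used with repeated flowmotion measurements:
within-subject coefficient of variation, repeatability correlation with a
Shapiro-Wilk normality gate (Pearson when normality is not rejected for
either variable, Spearman otherwise), the paired Wilcoxon signed-rank
comparison of FM vs FM(R), ordinary least squares with pointwise prediction
bands for outlier identification, and joint lowest-quartile flagging of
subjects with a disturbed flowmotion response to hypoxia (both FM(R) and the
myogenic share myo(R) in the lowest quartile).  All p-values are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: relative slack when testing membership of the lowest quartile, so a value
#: exactly equal to the quantile is included despite float rounding
_QUANTILE_TOL = 1e-12


@dataclass(frozen=True)
class RepeatabilityResult:
    per_subject_cv: dict[str, float]
    mean_cv: float


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    p: float
    shapiro_p_x: float
    shapiro_p_y: float


@dataclass(frozen=True)
class RegressionWithBands:
    """OLS line with pointwise prediction bounds at each observed x."""

    slope: float
    intercept: float
    level: float
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    outlier_ids: list
    residual_sd: float
    x_mean: float
    sxx: float
    n: int

    def predict_interval(self, x_new: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fitted value and prediction bounds at new x (t-based closed form)."""
        x_new = np.asarray(x_new, dtype=float)
        yhat = self.intercept + self.slope * x_new
        tcrit = stats.t.ppf(0.5 + self.level / 2.0, self.n - 2)
        se = self.residual_sd * np.sqrt(
            1.0 + 1.0 / self.n + (x_new - self.x_mean) ** 2 / self.sxx)
        return yhat, yhat - tcrit * se, yhat + tcrit * se


def within_subject_cv(repeats: Mapping[str, Sequence[float]]) -> RepeatabilityResult:
    """Within-subject CV: sample SD (n-1 denominator) over the mean, per subject.

    ``mean_cv`` is the arithmetic mean of the per-subject CVs.  Each subject
    needs >= 2 repeats and a nonzero mean.
    """
    cvs: dict[str, float] = {}
    for sid, values in repeats.items():
        arr = np.asarray(list(values), dtype=float)
        if len(arr) < 2:
            raise ValueError(f"subject {sid!r} has fewer than 2 repeats")
        mean = arr.mean()
        if mean == 0:
            raise ValueError(f"subject {sid!r} has zero mean; CV undefined")
        cvs[sid] = float(arr.std(ddof=1) / abs(mean))
    return RepeatabilityResult(per_subject_cv=cvs,
                               mean_cv=float(np.mean(list(cvs.values()))))


def correlation_with_normality_gate(x: Sequence[float], y: Sequence[float],
                                    alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation if Shapiro-Wilk rejects normality for neither
    variable at ``alpha``; Spearman otherwise.  Two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    if sw_x >= alpha and sw_y >= alpha:
        res = stats.pearsonr(x, y)
        method = "pearson"
    else:
        res = stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method=method, r=float(res.statistic),
                             p=float(res.pvalue),
                             shapiro_p_x=float(sw_x), shapiro_p_y=float(sw_y))


def paired_signed_rank(a: Sequence[float], b: Sequence[float],
                       zero_method: str = "wilcox") -> float:
    """Two-tailed paired Wilcoxon signed-rank p-value.

    Exact null distribution when there are <= 25 untied nonzero differences;
    normal approximation (mid-ranks for ties) otherwise.  Zero differences
    are dropped by default (``wilcox``); ``pratt`` keeps them in the ranking.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    d = a - b
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        raise ValueError("all paired differences are zero")
    if len(nonzero) < 5:
        raise ValueError("need at least 5 nonzero differences")
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not has_ties
                         and zero_method == "wilcox") else "approx"
    res = stats.wilcoxon(a, b, zero_method=zero_method, correction=False,
                         alternative="two-sided", method=method)
    return float(res.pvalue)


def regression_prediction_band(x: Sequence[float], y: Sequence[float],
                               level: float = 0.95,
                               ids: Sequence | None = None,
                               ) -> RegressionWithBands:
    """OLS line with pointwise prediction bands; flags points outside them.

    The prediction bound at each observation's own x is the t-based closed
    form ``yhat +- t_{1-a/2, n-2} * s * sqrt(1 + 1/n + (x-xbar)^2/Sxx)``;
    an observation above its upper bound or below its lower bound is an
    outlier (e.g. an unusually strong flowmotion response for its age).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    x_mean = float(x.mean())
    sxx = float(np.sum((x - x_mean) ** 2))
    slope = float(np.sum((x - x_mean) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x_mean)
    fitted = intercept + slope * x
    resid = y - fitted
    s = float(np.sqrt(np.sum(resid ** 2) / (n - 2)))
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 2)
    se = s * np.sqrt(1.0 + 1.0 / n + (x - x_mean) ** 2 / sxx)
    lower = fitted - tcrit * se
    upper = fitted + tcrit * se
    idx = ids if ids is not None else list(range(n))
    outliers = [idx[i] for i in range(n) if y[i] > upper[i] or y[i] < lower[i]]
    return RegressionWithBands(slope=slope, intercept=intercept, level=level,
                               x=x, y=y, fitted=fitted, lower=lower,
                               upper=upper, outlier_ids=outliers,
                               residual_sd=s, x_mean=x_mean, sxx=sxx, n=n)


def flag_disturbed_response(cohort: pd.DataFrame,
                            q: float = 0.25) -> list[str]:
    """Subjects whose FM(R) *and* myo(R) both lie in the lowest quartile.

    A healthy hypoxia response raises both the reperfusion flowmotion FM(R)
    and the myogenic share; a subject low on both is flagged as a disturbed
    responder.  Quantiles use linear interpolation between order statistics
    and boundary values are included.
    """
    for col in ("fm_r", "pie_myo_r"):
        if col not in cohort.columns or cohort[col].isna().any():
            raise ValueError(f"cohort table must provide {col!r} for every row")
    if len(cohort) < 4:
        raise ValueError("need at least 4 subjects")
    fm_r = cohort["fm_r"].to_numpy(dtype=float)
    myo_r = cohort["pie_myo_r"].to_numpy(dtype=float)
    thr_fm = float(np.quantile(fm_r, q))
    thr_myo = float(np.quantile(myo_r, q))

    def at_most(v: np.ndarray, thr: float) -> np.ndarray:
        return v <= thr + _QUANTILE_TOL * max(1.0, abs(thr))

    mask = at_most(fm_r, thr_fm) & at_most(myo_r, thr_myo)
    return [str(s) for s in cohort.loc[mask, "subject_id"]]


# ---------------------------------------------------------------------------
# orchestration


def _aggregate(table: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Collapse repeated measurements to one row per subject."""
    value_cols = [c for c in ("fm", "fm_r", "pie_myo", "pie_myo_r")
                  if c in table.columns]
    meta_cols = [c for c in ("sex", "age", "bmi", "sbp", "dbp")
                 if c in table.columns]
    agg = {c: how for c in value_cols} | {c: "first" for c in meta_cols}
    return table.groupby("subject_id", as_index=False).agg(agg)


def summarize_cohort(table: pd.DataFrame,
                     alpha: float = 0.05,
                     q: float = 0.25,
                     prediction_level: float = 0.95,
                     aggregation: str = "mean") -> dict[str, Any]:
    """Run the full cohort analysis on a (possibly repeated-measures) table.

    With a ``repeat_index`` column, computes within-subject CVs and the
    first-vs-second repeatability correlation before aggregating (mean by
    default) to one row per subject.  Then: FM-age correlation with
    prediction-band outliers, FM(R)-SBP/DBP correlations, the paired FM vs
    FM(R) comparison, and disturbed-responder flags.  Sections whose inputs
    are missing are skipped, not errored.
    """
    out: dict[str, Any] = {"n_rows": int(len(table))}
    has_repeats = ("repeat_index" in table.columns
                   and table["repeat_index"].nunique() > 1)
    if has_repeats and "fm" in table.columns:
        wide = table.pivot_table(index="subject_id", columns="repeat_index",
                                 values="fm")
        complete = wide.dropna()
        repeats = {str(sid): row.to_numpy() for sid, row in complete.iterrows()}
        rep = within_subject_cv(repeats)
        out["fm_mean_cv"] = rep.mean_cv
        first, second = complete.columns[:2]
        corr = correlation_with_normality_gate(complete[first], complete[second],
                                               alpha)
        out["fm_repeatability"] = {"method": corr.method, "r": corr.r, "p": corr.p}
    agg = _aggregate(table, aggregation)
    out["n_subjects"] = int(len(agg))

    if {"fm", "age"} <= set(agg.columns) and agg["fm"].notna().all():
        corr = correlation_with_normality_gate(agg["age"], agg["fm"], alpha)
        out["fm_vs_age"] = {"method": corr.method, "r": corr.r, "p": corr.p}
        band = regression_prediction_band(agg["age"], agg["fm"],
                                          level=prediction_level,
                                          ids=list(agg["subject_id"]))
        out["fm_vs_age_outliers"] = [str(s) for s in band.outlier_ids]

    if "fm_r" in agg.columns and agg["fm_r"].notna().all():
        for cov in ("sbp", "dbp"):
            if cov in agg.columns:
                corr = correlation_with_normality_gate(agg[cov], agg["fm_r"], alpha)
                out[f"fm_r_vs_{cov}"] = {"method": corr.method,
                                         "r": corr.r, "p": corr.p}
        if "fm" in agg.columns:
            out["fm_vs_fm_r_wilcoxon_p"] = paired_signed_rank(agg["fm_r"], agg["fm"])
            band = regression_prediction_band(agg["fm"], agg["fm_r"],
                                              level=prediction_level,
                                              ids=list(agg["subject_id"]))
            out["fm_r_vs_fm_outliers"] = [str(s) for s in band.outlier_ids]
        if "pie_myo_r" in agg.columns and agg["pie_myo_r"].notna().all():
            out["disturbed_response_ids"] = flag_disturbed_response(agg, q)
    return out
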