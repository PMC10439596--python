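"""Reliability and accuracy statistics for repeated angle measurements.

Covers the study-style analysis: per-axis cohort summaries with outlier
rates, two-way random-effects absolute-agreement ICC (single measures,
ICC(2,1)) with an F-based 95% confidence interval and the conventional
poor/good/high grading, Bland-Altman limits of agreement with an explicit
coverage criterion, and the three-axis accuracy comparison (Levene gate,
one-way ANOVA or Welch ANOVA, Fisher-LSD pairwise tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FemrotError, UnbalancedTableError

ANGLE_NAMES = ("ws", "atea", "pcl")

#: ICC grading breakpoints: below 0.4 poor, 0.4-0.75 good, above 0.75 high.
ICC_POOR_BELOW = 0.4
ICC_HIGH_ABOVE = 0.75

#: Multiplier for the limits of agreement (normal-quantile convention).
LOA_FACTOR = 1.96


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    grade: str
    n_subjects: int
    n_raters: int

    def as_dict(self) -> dict:
        return {
            "icc": self.icc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "grade": self.grade,
            "n_subjects": self.n_subjects,
            "n_raters": self.n_raters,
        }


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    coverage: float
    passed: bool
    n: int

    def as_dict(self) -> dict:
        return {
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "coverage": self.coverage,
            "passed": self.passed,
            "n": self.n,
        }


def grade_icc(icc: float) -> str:
    """Map an ICC to the conventional consistency grade."""
    if icc < ICC_POOR_BELOW:
        return "poor"
    if icc <= ICC_HIGH_ABOVE:
        return "good"
    return "high"


def icc_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows, columns, residual) for an n x k table."""
    y = np.asarray(values, dtype=float)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way(values: np.ndarray, ci: float = 0.95, form: str = "agreement") -> ICCResult:
    """Two-way single-measures ICC with an F-based confidence interval.

    ``values`` is an (n_subjects, k_raters) array of one angle's repeated
    measurements. ``form='agreement'`` gives ICC(2,1): two-way random
    effects, absolute agreement — the default used throughout the package;
    ``form='consistency'`` gives the consistency coefficient ICC(3,1).

    Raises
    ------
    UnbalancedTableError
        On missing values or fewer than 3 subjects / 2 raters.
    FemrotError
        If total variance is zero (ICC undefined).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise UnbalancedTableError("ICC needs an (n_subjects, k>=2) table")
    if not np.all(np.isfinite(y)):
        raise UnbalancedTableError("ICC table contains missing values")
    if form not in ("agreement", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")
    n, k = y.shape
    if n < 3:
        raise UnbalancedTableError("ICC needs at least 3 subjects")
    if np.ptp(y) == 0:
        raise FemrotError("ICC undefined: zero total variance")
    msr, msc, mse = icc_mean_squares(y)
    alpha = 1.0 - ci

    if form == "consistency":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0.0:
            return ICCResult(1.0, 1.0, 1.0, grade_icc(1.0), n, k)
        fobs = msr / mse
        df2 = (n - 1) * (k - 1)
        fl = fobs / sps.f.ppf(1 - alpha / 2, n - 1, df2)
        fu = fobs * sps.f.ppf(1 - alpha / 2, df2, n - 1)
        lower = (fl - 1.0) / (fl + k - 1.0)
        upper = (fu - 1.0) / (fu + k - 1.0)
        return ICCResult(float(icc), float(lower), float(upper), grade_icc(float(icc)), n, k)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        # Perfect agreement: the F-based interval degenerates.
        return ICCResult(1.0, 1.0, 1.0, grade_icc(1.0), n, k)

    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den
        fl = sps.f.ppf(1 - alpha / 2, n - 1, v)
        fu = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
    else:
        lower = upper = 1.0
    return ICCResult(float(icc), float(lower), float(upper), grade_icc(float(icc)), n, k)


def bland_altman(pairs: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement between two measurement columns.

    Bias is the mean difference (first minus second column); limits of
    agreement are bias +/- 1.96 * SD of the differences; coverage counts
    differences inside the limits inclusively; ``passed`` requires coverage
    of at least 95%.
    """
    p = np.asarray(pairs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
        raise UnbalancedTableError("Bland-Altman needs an (n>=2, 2) table")
    d = p[:, 0] - p[:, 1]
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = bias - LOA_FACTOR * sd, bias + LOA_FACTOR * sd
    coverage = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltmanResult(bias, lo, hi, coverage, coverage >= 0.95, p.shape[0])


def cohort_summary(angles: dict[str, np.ndarray], threshold_deg: float = 2.0) -> pd.DataFrame:
    """Per-axis mean, sample SD and outlier count/percent."""
    rows = []
    for name, vals in angles.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise FemrotError(f"summary for {name!r} needs at least 2 values")
        outliers = int(np.sum(np.abs(v) > threshold_deg))
        rows.append(
            {
                "angle": name,
                "n": int(v.size),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)),
                "outlier_count": outliers,
                "outlier_percent": 100.0 * outliers / v.size,
            }
        )
    return pd.DataFrame(rows)


def _lsd_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Fisher LSD: unadjusted pairwise t-tests using the pooled ANOVA MSE."""
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    ns = [a.size for a in arrays]
    N, k = sum(ns), len(arrays)
    mse = sum((a.size - 1) * np.var(a, ddof=1) for a in arrays) / (N - k)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = arrays[i].mean() - arrays[j].mean()
            if mse == 0:
                t = np.inf if diff != 0 else 0.0
            else:
                t = diff / np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
            p = 2.0 * sps.t.sf(abs(t), N - k) if np.isfinite(t) else (0.0 if t else 1.0)
            rows.append(
                {"group_a": names[i], "group_b": names[j], "mean_diff": float(diff), "t": float(t), "p": float(p)}
            )
    return pd.DataFrame(rows)


def compare_axes(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """Omnibus + pairwise comparison of the per-axis deviation angles.

    Levene's test (median-centered) gates the omnibus choice: classic
    one-way ANOVA when variances are homogeneous, Welch's ANOVA otherwise.
    Pairwise Fisher-LSD p-values are always reported; they carry inferential
    weight only when the omnibus test is significant. Groups are treated as
    independent samples.
    """
    if len(groups) < 2:
        raise FemrotError("need at least two groups to compare")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size < 2 for a in arrays):
        raise FemrotError("each group needs at least 2 values")
    constant = all(np.ptp(a) == 0 for a in arrays)
    if constant:
        levene_p = 1.0
        method = "anova"
        means = [a.mean() for a in arrays]
        stat, p = (0.0, 1.0) if np.ptp(means) == 0 else (np.inf, 0.0)
    else:
        _, levene_p = sps.levene(*arrays, center="median")
        if levene_p >= alpha:
            method = "anova"
            stat, p = sps.f_oneway(*arrays)
        else:
            method = "welch"
            long = pd.DataFrame(
                {
                    "value": np.concatenate(arrays),
                    "group": np.repeat(list(groups), [a.size for a in arrays]),
                }
            )
            import pingouin as pg

            res = pg.welch_anova(data=long, dv="value", between="group")
            stat, p = float(res["F"].iloc[0]), float(res["p_unc"].iloc[0])
    return {
        "levene_p": float(levene_p),
        "method": method,
        "statistic": float(stat),
        "p": float(p),
        "significant": bool(p < alpha),
        "pairwise": _lsd_pairwise(groups),
    }


def pivot_for_icc(
    table: pd.DataFrame, angle: str, column_key: str, column_values: tuple, fixed: dict[str, object]
) -> np.ndarray:
    """Pivot a long measurement table into an (n_subjects, 2) array.

    ``table`` has columns subject_id, observer_id, session and one column
    per angle (``ws_deg`` etc.). ``fixed`` filters (e.g. one observer);
    ``column_key``/``column_values`` select the two repeat columns (e.g.
    sessions 1 and 2). Raises UnbalancedTableError naming missing subjects.
    """
    col = f"{angle}_deg"
    sub = table
    for key, val in fixed.items():
        sub = sub[sub[key] == val]
    wide = sub.pivot_table(index="subject_id", columns=column_key, values=col, aggfunc="first")
    missing = [c for c in column_values if c not in wide.columns]
    if missing:
        raise UnbalancedTableError(f"missing {column_key} level(s) {missing} for ICC")
    wide = wide[list(column_values)]
    bad = wide.index[wide.isna().any(axis=1)].tolist()
    if bad:
        raise UnbalancedTableError(f"subjects missing repeats for ICC: {bad}")
    return wide.to_numpy(dtype=float)
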