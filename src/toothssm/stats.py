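"""Validation and inference statistics: Bland-Altman agreement, OLS
regression of measurements on PC weights, and one-way ANOVA with Tukey
HSD post-hoc comparison of PC weights across sample groups.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InvalidInputError
from .landmarks import MEASUREMENT_NAMES

__all__ = ["BlandAltmanResult", "RegressionResult", "AnovaResult",
           "bland_altman", "fit_line", "pc_measurement_regressions",
           "compare_groups", "boxplot_stats"]


@dataclass
class BlandAltmanResult:
    bias: float                  # mean of a - b
    sd: float                    # sd of differences (ddof=1)
    lower: float                 # bias - 1.96 sd
    upper: float                 # bias + 1.96 sd
    pairs: np.ndarray            # (n, 2) columns: pair mean, difference


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    t_statistic: float
    p_value: float
    n: int


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    group_means: dict
    posthoc: list = field(default_factory=list)  # rows: (ga, gb, diff, p_adj, significant)
    boxplots: dict = field(default_factory=dict)
    alpha: float = 0.05


def bland_altman(series_a, series_b) -> BlandAltmanResult:
    """Paired-agreement analysis: bias = mean(a - b), 95% limits of
    agreement at bias +/- 1.96 * sd (sd with 1/(n-1))."""
    a = np.asarray(series_a, dtype=np.float64).ravel()
    b = np.asarray(series_b, dtype=np.float64).ravel()
    if len(a) != len(b):
        raise InvalidInputError("series must be paired (equal lengths)")
    if len(a) < 2:
        raise InvalidInputError("need at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, sd=sd,
        lower=bias - 1.96 * sd, upper=bias + 1.96 * sd,
        pairs=np.column_stack([(a + b) / 2.0, diff]),
    )


def fit_line(x, y) -> RegressionResult:
    """Ordinary least squares y = slope * x + intercept with a two-sided
    t-test of slope = 0 on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(x)
    if n != len(y):
        raise InvalidInputError("x and y must have equal lengths")
    if n < 3:
        raise InvalidInputError("need n >= 3 for the regression t-test")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise InvalidInputError("x is constant; slope undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:  # constant y: define R^2 = 0, slope 0 is exact
        return RegressionResult(0.0, float(y.mean()), 0.0, 0.0, 1.0, n)
    r2 = 1.0 - ss_res / ss_tot
    df = n - 2
    mse = ss_res / df
    se = np.sqrt(mse / sxx)
    if se == 0:
        t = np.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = float(2.0 * sps.t.sf(abs(t), df))
    return RegressionResult(slope, intercept, r2, float(t), p, n)


def pc_measurement_regressions(sweep_tables: list, alpha: float = 0.01) -> list[dict]:
    """One OLS fit per (PC, measurement) with x = sigma level.

    ``sweep_tables`` is a list of per-PC row lists as produced by
    :func:`toothssm.landmarks.measure_sweep`. Rows whose landmarking
    failed propagate as missing cells. Returns tidy rows:
    ``{"pc", "measurement", "r_squared", "p_value", "significant"}``.
    """
    out = []
    for rows in sweep_tables:
        if not rows:
            continue
        pc = rows[0]["pc"]
        for name in MEASUREMENT_NAMES:
            pts = [(r["level"], r[name]) for r in rows
                   if r.get("error") is None and r.get(name) is not None]
            if len(pts) < 3:
                out.append({"pc": pc, "measurement": name, "r_squared": None,
                            "p_value": None, "significant": None})
                continue
            x, y = zip(*pts)
            res = fit_line(x, y)
            out.append({"pc": pc, "measurement": name,
                        "r_squared": res.r_squared, "p_value": res.p_value,
                        "significant": bool(res.p_value < alpha)})
    return out


def boxplot_stats(values: np.ndarray) -> dict:
    """Quartiles, 1.5*IQR whiskers/outliers and notch half-width
    (1.57 * IQR / sqrt(n))."""
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = v[(v >= lo) & (v <= hi)]
    outliers = v[(v < lo) | (v > hi)]
    notch = 1.57 * iqr / np.sqrt(len(v))
    return {
        "q1": float(q1), "median": float(med), "q3": float(q3),
        "whisker_low": float(inliers.min()), "whisker_high": float(inliers.max()),
        "outliers": outliers.tolist(),
        "notch_low": float(med - notch), "notch_high": float(med + notch),
        "n": len(v),
    }


def compare_groups(weights, groups, alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA of per-specimen PC weights across groups;
    Tukey HSD pairwise comparisons are run when the ANOVA rejects at
    ``alpha``. Boxplot summaries per group are always computed."""
    weights = np.asarray(weights, dtype=np.float64).ravel()
    groups = list(groups)
    if len(weights) != len(groups):
        raise InvalidInputError("weights and groups must have equal lengths")
    names = sorted(set(groups))
    if len(names) < 2:
        raise InvalidInputError("need at least 2 groups")
    samples = {g: weights[np.asarray(groups) == g] for g in names}
    for g, s in samples.items():
        if len(s) < 2:
            raise InvalidInputError(f"group {g!r} has n < 2")
    n_total = len(weights)
    k = len(names)
    grand = weights.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples.values())
    ss_within = sum(float(np.sum((s - s.mean()) ** 2)) for s in samples.values())
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = np.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    posthoc = []
    if p < alpha:
        for i in range(k):
            for j in range(i + 1, k):
                ga, gb = names[i], names[j]
                sa, sb = samples[ga], samples[gb]
                diff = float(sa.mean() - sb.mean())
                se = np.sqrt(ms_w / 2.0 * (1.0 / len(sa) + 1.0 / len(sb)))
                if se == 0:
                    q = np.inf if diff != 0 else 0.0
                    p_adj = 0.0 if diff != 0 else 1.0
                else:
                    q = abs(diff) / se
                    p_adj = float(sps.studentized_range.sf(q, k, df_w))
                posthoc.append({"group_a": ga, "group_b": gb, "difference": diff,
                                "p_adjusted": p_adj,
                                "significant": bool(p_adj < alpha)})
    return AnovaResult(
        f_statistic=float(f), p_value=float(p),
        group_means={g: float(s.mean()) for g, s in samples.items()},
        posthoc=posthoc,
        boxplots={g: boxplot_stats(s) for g, s in samples.items()},
        alpha=alpha,
    )
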