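"""Case-control and within-patient inference on profile metrics.

The primary analysis is an ANCOVA (OLS of metric ~ group + age + sex) per
region x contrast x metric, reported with F, p, two Cohen's d variants and
a 95% CI for the covariate-adjusted group difference (control minus
patient, so a positive patient elevation prints a negative interval).
Severity and trauma associations within patients use Kendall's tau-b with
a tie-adjusted asymptotic p and a bootstrap CI; medication and comorbidity
use the same ANCOVA machinery on within-patient subgroups.  Hemisphere
lateralization is checked with paired t-tests before profiles are averaged
across hemispheres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "CorrelationResult",
    "DesignError",
    "ancova_group_test",
    "kendall_correlation",
    "case_control_tests",
    "within_patient_analyses",
    "lateralization_test",
]

METRIC_NAMES = ("mean", "auc", "offset")


class DesignError(ValueError):
    """Singular or otherwise untestable design matrix."""


@dataclass(frozen=True)
class GroupTestResult:
    metric: str
    F: float
    df: tuple[int, int]
    p: float
    cohens_d_pooled: float
    cohens_d_adjusted: float
    ci_95: tuple[float, float]  # adjusted control-minus-case difference
    n_case: int
    n_control: int


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    tau: float
    p: float
    ci_95: tuple[float, float]
    n: int


def ancova_group_test(
    data: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    case_level: str = "MDD",
    covariates: tuple[str, ...] = ("age", "sex"),
    metric_name: str = "",
) -> GroupTestResult:
    """OLS ANCOVA of a metric on group with age/sex covariates.

    ``sex`` is coded as a male indicator; the group F statistic is the
    squared t of the case-indicator coefficient (a single-df partial F),
    with denominator df = N - 4 in the default two-covariate design.
    Both the pooled-SD Cohen's d (case minus control over pooled SD) and
    the covariate-adjusted d = t * sqrt(1/n1 + 1/n2) are reported.
    """
    df = data.dropna(subset=[value_col, group_col, *covariates])
    case = (df[group_col] == case_level).to_numpy(dtype=float)
    n1 = int(case.sum())
    n2 = len(df) - n1
    if n1 < 3 or n2 < 3:
        raise DesignError("need at least 3 subjects per group")
    cols = [case]
    for cov in covariates:
        if cov == "sex":
            cols.append((df["sex"] == "M").to_numpy(dtype=float))
        else:
            cols.append(df[cov].to_numpy(dtype=float))
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("singular design matrix (collinear covariates)")
    y = df[value_col].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    t = fit.tvalues[1]
    se = fit.bse[1]
    coef = fit.params[1]  # case minus control, adjusted
    dof = int(fit.df_resid)
    # perfect fits (e.g. a constant metric) leave only rounding noise in the
    # residuals; the group term is then null, not spuriously large
    scale = np.sqrt(max(np.mean(y**2), 1.0))
    if np.sqrt(fit.ssr / len(y)) < 1e-10 * scale and abs(coef) < 1e-10 * scale:
        t, coef, se = 0.0, 0.0, 0.0
    if not np.isfinite(t):
        t = 0.0
    F = float(t**2)
    p = float(2 * sps.t.sf(abs(t), dof))

    v1 = df.loc[df[group_col] == case_level, value_col].to_numpy(dtype=float)
    v2 = df.loc[df[group_col] != case_level, value_col].to_numpy(dtype=float)
    s_pooled = np.sqrt(
        ((n1 - 1) * v1.var(ddof=1) + (n2 - 1) * v2.var(ddof=1)) / (n1 + n2 - 2)
    )
    d_pooled = float((v1.mean() - v2.mean()) / s_pooled) if s_pooled > 0 else 0.0
    d_adj = float(t * np.sqrt(1.0 / n1 + 1.0 / n2))

    tcrit = sps.t.ppf(0.975, dof)
    ci = (float(-coef - tcrit * se), float(-coef + tcrit * se))
    return GroupTestResult(
        metric=metric_name,
        F=F,
        df=(1, dof),
        p=p,
        cohens_d_pooled=d_pooled,
        cohens_d_adjusted=d_adj,
        ci_95=ci,
        n_case=n1,
        n_control=n2,
    )


def kendall_correlation(
    x,
    y,
    n_boot: int = 2000,
    seed: int = 0,
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Kendall tau-b with tie-adjusted asymptotic p and bootstrap 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 pairwise-complete observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for all-tied input")
    tau, p = sps.kendalltau(x, y, variant="b", method="asymptotic")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.all(xb == xb[0]) or np.all(yb == yb[0]):
            boots[b] = np.nan
            continue
        boots[b] = sps.kendalltau(xb, yb, variant="b").statistic
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return CorrelationResult(
        pair=pair, tau=float(tau), p=float(p), ci_95=(float(lo), float(hi)), n=n
    )


def case_control_tests(
    metrics: pd.DataFrame,
    alpha: float = 0.05,
    rois: tuple[str, ...] | None = None,
    contrasts: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Stage-1 ANCOVAs over every (roi, contrast, metric) cell.

    ``metrics`` is long-format with columns subject_id, group, age, sex,
    roi, contrast, metric, value.  Returns a tidy results table with one
    row per test; ``significant`` flags p < alpha.
    """
    rois = rois or tuple(metrics["roi"].unique())
    contrasts = contrasts or tuple(metrics["contrast"].unique())
    rows = []
    for roi in rois:
        for contrast in contrasts:
            for metric in METRIC_NAMES:
                cell = metrics[
                    (metrics["roi"] == roi)
                    & (metrics["contrast"] == contrast)
                    & (metrics["metric"] == metric)
                ]
                if cell.empty:
                    continue
                res = ancova_group_test(cell, metric_name=metric)
                rows.append(
                    dict(
                        stage="case_control",
                        roi=roi,
                        contrast=contrast,
                        metric=metric,
                        statistic=res.F,
                        df1=res.df[0],
                        df2=res.df[1],
                        p=res.p,
                        effect_size_pooled=res.cohens_d_pooled,
                        effect_size_adjusted=res.cohens_d_adjusted,
                        ci_lo=res.ci_95[0],
                        ci_hi=res.ci_95[1],
                        n=res.n_case + res.n_control,
                        significant=res.p < alpha,
                    )
                )
    return pd.DataFrame(rows)


def within_patient_analyses(
    metrics: pd.DataFrame,
    stage1: pd.DataFrame,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Stage-2 exploratory analyses within patients, gated on stage 1.

    Runs only for (roi, contrast, metric) cells flagged significant in the
    case-control stage: severity (IDS) and childhood trauma (CTQ) via
    Kendall correlation against the metric; antidepressant use and
    comorbid anxiety via two-group ANCOVAs with age/sex covariates.  An
    empty gating set yields an empty table.
    """
    gated = stage1[stage1["significant"]]
    rows = []
    for g_idx, (_, grow) in enumerate(gated.iterrows()):
        cell = metrics[
            (metrics["roi"] == grow["roi"])
            & (metrics["contrast"] == grow["contrast"])
            & (metrics["metric"] == grow["metric"])
            & (metrics["group"] == "MDD")
        ]
        base = dict(stage="within_patients", roi=grow["roi"],
                    contrast=grow["contrast"], metric=grow["metric"])
        for var, col in (("ids", "ids_score"), ("ctq", "ctq_score")):
            res = kendall_correlation(
                cell[col], cell["value"],
                n_boot=n_boot, seed=seed + g_idx,
                pair=(col, grow["metric"]),
            )
            rows.append(
                dict(
                    **base, analysis=var, statistic=res.tau, df1=np.nan,
                    df2=np.nan, p=res.p, effect_size_pooled=np.nan,
                    effect_size_adjusted=np.nan, ci_lo=res.ci_95[0],
                    ci_hi=res.ci_95[1], n=res.n,
                )
            )
        for var, col in (
            ("antidepressants", "on_antidepressants"),
            ("anxiety", "comorbid_anxiety"),
        ):
            sub = cell.copy()
            sub["flag"] = np.where(sub[col].astype(bool), "yes", "no")
            try:
                res = ancova_group_test(
                    sub, group_col="flag", case_level="yes",
                    metric_name=grow["metric"],
                )
            except DesignError:
                continue
            rows.append(
                dict(
                    **base, analysis=var, statistic=res.F, df1=res.df[0],
                    df2=res.df[1], p=res.p,
                    effect_size_pooled=res.cohens_d_pooled,
                    effect_size_adjusted=res.cohens_d_adjusted,
                    ci_lo=res.ci_95[0], ci_hi=res.ci_95[1],
                    n=res.n_case + res.n_control,
                )
            )
    return pd.DataFrame(rows)


def lateralization_test(profiles: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired left-vs-right t-test on the profile mean per ROI and contrast.

    ``profiles`` is long-format with columns subject_id, roi, hemisphere,
    contrast, depth_bin, value.  Subjects missing a hemisphere are dropped
    from the test (their count is reported in ``n_excluded``).  When every
    test satisfies p > alpha, downstream analyses may consume
    hemisphere-averaged profiles.
    """
    means = (
        profiles[profiles["hemisphere"].isin(["left", "right"])]
        .groupby(["subject_id", "roi", "contrast", "hemisphere"], sort=True)["value"]
        .mean()
        .unstack("hemisphere")
    )
    rows = []
    for (roi, contrast), grp in means.groupby(level=["roi", "contrast"], sort=True):
        paired = grp.dropna(subset=["left", "right"])
        n_excluded = len(grp) - len(paired)
        left = paired["left"].to_numpy()
        right = paired["right"].to_numpy()
        if np.allclose(left, right):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(left, right)
        rows.append(
            dict(
                roi=roi,
                contrast=contrast,
                t=float(t),
                df=len(paired) - 1,
                p=float(p),
                n=len(paired),
                n_excluded=n_excluded,
                significant=p < alpha,
            )
        )
    return pd.DataFrame(rows)
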