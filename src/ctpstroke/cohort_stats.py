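"""Two-period cohort statistics: summaries, tests, CIs and regressions.

Implements the statistical layer of the two-period comparison: median/IQR
summaries for skewed continuous variables, Wald 95 % confidence intervals
for proportions, a normality-gated choice between the independent-samples
t test and the Mann-Whitney U test, Pearson chi-square (no continuity
correction) for 2x2 tables, univariate OLS of imaging features on the
period indicator (B, 95 % CI), and binary logistic regression of LVO on the
period indicator (OR, 95 % CI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "summarize_continuous",
    "wald_ci",
    "compare_continuous",
    "compare_categorical",
    "linear_b",
    "logistic_or",
    "build_tables",
]

_Z95 = float(stats.norm.ppf(0.975))


def summarize_continuous(values) -> tuple[float, float, float]:
    """Sample median and quartiles (linear-interpolation quantile rule)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def wald_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Normal-approximation CI for a proportion, in percent, clipped to [0, 100]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= successes <= n):
        raise ValueError("successes must lie in [0, n]")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    p = successes / n
    half = z * np.sqrt(p * (1.0 - p) / n)
    lo = max(0.0, p - half) * 100.0
    hi = min(1.0, p + half) * 100.0
    return p * 100.0, (lo, hi)


def _ks_normal(values: np.ndarray, alpha: float = 0.05) -> bool:
    """Kolmogorov-Smirnov test against a fitted normal; True = looks normal."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        return False
    return stats.kstest(values, "norm", args=(values.mean(), sd)).pvalue > alpha


def compare_continuous(group_a, group_b) -> tuple[str, float]:
    """Normality-gated two-sided comparison of two independent samples.

    Both groups passing the KS normality screen selects the independent
    t test, otherwise the Mann-Whitney U test (normal approximation with
    tie correction).  Returns ``(test_name, p_value)``; degenerate all-tied
    input yields p = 1 rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if np.concatenate([a, b]).std() == 0:
        return "mann-whitney", 1.0
    if _ks_normal(a) and _ks_normal(b):
        p = stats.ttest_ind(a, b).pvalue
        return "t-test", float(p)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = res.pvalue
    if not np.isfinite(p):
        p = 1.0
    return "mann-whitney", float(min(p, 1.0))


def compare_categorical(table) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) on a 2x2 table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) <= 0) or np.any(obs.sum(axis=1) <= 0):
        raise ValueError("all table margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def linear_b(feature, period_indicator) -> tuple[float, tuple[float, float]]:
    """Univariate OLS of a feature on the 0/1 period indicator.

    Returns ``(B, (lo, hi))``: the slope (equal to the difference in group
    means for a binary predictor) with its 95 % confidence interval.
    """
    import statsmodels.api as sm

    y = np.asarray(feature, dtype=float)
    x = np.asarray(period_indicator, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("both periods must be present")
    if np.allclose(y, y[0]):
        return 0.0, (0.0, 0.0)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = model.conf_int()[1]
    return float(model.params[1]), (float(lo), float(hi))


def logistic_or(outcome, period_indicator) -> tuple[float, tuple[float, float], bool]:
    """Binary logistic regression of an outcome on the 0/1 period indicator.

    Returns ``(OR, (lo, hi), separated)`` where OR = exp(coefficient) with
    its Wald 95 % CI.  With a single binary predictor the MLE odds ratio
    equals the 2x2 cross-product ratio.  Complete/quasi-complete separation
    (a zero cell) is flagged and the CI reported as infinite rather than
    silently diverging.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(period_indicator, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must not be constant")
    if len(np.unique(x)) < 2:
        raise ValueError("both periods must be present")
    # 2x2 cell counts to detect separation up front.
    a = float(np.sum((x == 1) & (y == 1)))
    b = float(np.sum((x == 1) & (y == 0)))
    c = float(np.sum((x == 0) & (y == 1)))
    d = float(np.sum((x == 0) & (y == 0)))
    if min(a, b, c, d) == 0:
        ratio = np.inf if (b == 0 or c == 0) else 0.0
        return ratio, (0.0, np.inf), True

    import statsmodels.api as sm

    model = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    coef = float(model.params[1])
    se = float(model.bse[1])
    return (
        float(np.exp(coef)),
        (float(np.exp(coef - _Z95 * se)), float(np.exp(coef + _Z95 * se))),
        False,
    )


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Row:
    variable: str
    kind: str  # 'continuous' | 'categorical'
    decimals: int = 0  # percent decimals for categorical rows
    regression: str | None = None  # 'linear' | 'logistic' | None


_CLINICAL_ROWS = [
    _Row("age", "continuous"),
    _Row("sex_female", "categorical"),
    _Row("suso", "categorical"),
    _Row("nihss", "continuous"),
    _Row("nihss_ge10", "categorical"),
    _Row("hypertension", "categorical"),
    _Row("diabetes", "categorical"),
    _Row("dyslipidemia", "categorical"),
    _Row("atrial_fibrillation", "categorical"),
    _Row("ischemic_cardiomyopathy", "categorical"),
]

_NEURO_ROWS = [
    _Row("lvo", "categorical", decimals=1, regression="logistic"),
    _Row("total_volume_ml", "continuous", regression="linear"),
    _Row("core_volume_ml", "continuous", regression="linear"),
    _Row("mismatch", "continuous", regression="linear"),
    _Row("infarct_volume_ml", "continuous", regression="linear"),
]

_NEURO_SOURCE = {
    "lvo": "lvo",
    "total_volume_ml": "total",
    "core_volume_ml": "core",
    "mismatch": "mismatch",
    "infarct_volume_ml": "infarct",
}


def _fmt_continuous(values, row: _Row) -> str:
    med, q1, q3 = summarize_continuous(values)
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def _fmt_categorical(flags, row: _Row) -> str:
    flags = np.asarray(flags, dtype=bool)
    k, n = int(flags.sum()), flags.size
    pct, (lo, hi) = wald_ci(k, n)
    if row.decimals == 0:
        return f"{k} ({pct:.0f}%)"
    return f"{k} ({pct:.{row.decimals}f}%; {lo:.{row.decimals}f}-{hi:.{row.decimals}f})"


def _resolve_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Derive the analysis columns from a cohort frame.

    Imaging features prefer pipeline-recovered values and fall back to
    generator ground truth when the pipeline has not run.
    """
    df = frame.copy()
    df["sex_female"] = df["sex"].astype(str).str.upper().eq("F")
    for feat in ("total", "core", "infarct"):
        rec = f"{feat}_recovered"
        true = f"{feat}_true"
        if rec in df and df[rec].notna().all():
            df[feat] = df[rec].astype(float)
        elif true in df:
            df[feat] = df[true].astype(float)
        else:
            raise KeyError(f"cohort table is missing column {true!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        df["mismatch"] = np.where(
            df["total"] > 0, 1.0 - df["core"] / df["total"], 1.0
        )
    return df


def build_tables(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical and neuroimaging comparison tables for a two-period cohort.

    ``frame`` is a cohort table (one row per patient) as produced by
    :func:`ctpstroke.phantom.cohort_to_frame`, optionally with recovered
    imaging volumes.  Returns ``(clinical, neuroimaging)`` DataFrames with a
    summary column per period, the test used, its p-value, and - for
    neuroimaging rows - the univariate regression estimate with 95 % CI.
    """
    if "period" not in frame.columns:
        raise KeyError("cohort table is missing column 'period'")
    periods = sorted(frame["period"].unique().tolist())
    if len(periods) != 2:
        raise ValueError(f"expected exactly two periods, found {periods}")
    # COVID period is the exposure (indicator 1) when present.
    exposure = next((p for p in periods if "no" not in str(p).lower()), periods[1])
    control = next(p for p in periods if p != exposure)
    df = _resolve_columns(frame)
    ga = df[df["period"] == exposure]
    gb = df[df["period"] == control]
    indicator = (df["period"] == exposure).astype(int).to_numpy()

    def assemble(rows, source_map=None) -> pd.DataFrame:
        out = []
        for row in rows:
            col = (source_map or {}).get(row.variable, row.variable)
            if col not in df.columns:
                raise KeyError(f"cohort table is missing column {col!r}")
            rec: dict = {"variable": row.variable}
            if row.kind == "continuous":
                rec[f"{exposure}"] = _fmt_continuous(ga[col], row)
                rec[f"{control}"] = _fmt_continuous(gb[col], row)
                test, p = compare_continuous(ga[col], gb[col])
            else:
                rec[f"{exposure}"] = _fmt_categorical(ga[col], row)
                rec[f"{control}"] = _fmt_categorical(gb[col], row)
                tab = [
                    [int(ga[col].sum()), int((~ga[col].astype(bool)).sum())],
                    [int(gb[col].sum()), int((~gb[col].astype(bool)).sum())],
                ]
                try:
                    _, p = compare_categorical(tab)
                    test = "chi-square"
                except ValueError:
                    test, p = "chi-square", np.nan
            rec["test"] = test
            rec["p_value"] = p
            if row.regression == "linear":
                b, (lo, hi) = linear_b(df[col].to_numpy(), indicator)
                rec["estimate"] = b
                rec["ci_low"], rec["ci_high"] = lo, hi
                rec["estimate_kind"] = "B"
            elif row.regression == "logistic":
                orat, (lo, hi), sep = logistic_or(
                    df[col].astype(bool).astype(int).to_numpy(), indicator
                )
                rec["estimate"] = orat
                rec["ci_low"], rec["ci_high"] = lo, hi
                rec["estimate_kind"] = "OR" + (" (separated)" if sep else "")
            out.append(rec)
        return pd.DataFrame(out)

    clinical = assemble(_CLINICAL_ROWS)
    neuro = assemble(_NEURO_ROWS, _NEURO_SOURCE)
    return clinical, neuro
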