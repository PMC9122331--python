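"""Statistical battery: feature correlations, paired lifetime tests,
heteroscedasticity-aware group ANOVA with the n-dependent posthoc choice,
and the log-normality check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComparisonError, DataError


# ---------------------------------------------------------------------------
# feature correlations


def feature_correlations(features: pd.DataFrame, log2fc: pd.DataFrame,
                         feature_cols: list[str] | None = None,
                         min_n: int = 3, add_bh: bool = False,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of every feature against per-dataset log2FC.

    ``features`` is indexed by protein_id; ``log2fc`` is protein x dataset.
    Missing values are excluded pairwise; a (feature, dataset) pair with
    fewer than ``min_n`` complete observations or zero variance is reported
    as missing with a warning.  Returns ``(per_dataset, summary)`` where the
    summary carries the cross-dataset mean r +/- SEM per feature.  Raw
    p-values are reported; ``add_bh`` appends a Benjamini-Hochberg column.
    """
    if feature_cols is None:
        feature_cols = [c for c in features.columns
                        if c != "protein_id" and pd.api.types.is_numeric_dtype(features[c])]
    feat = features.set_index("protein_id") if "protein_id" in features.columns else features

    rows = []
    for ds in log2fc.columns:
        fc = log2fc[ds]
        for name in feature_cols:
            joined = pd.concat({"x": feat[name], "y": fc}, axis=1).dropna()
            if len(joined) < min_n:
                rows.append({"feature": name, "dataset": ds, "r": np.nan,
                             "p": np.nan, "n": len(joined)})
                continue
            if joined["x"].std(ddof=1) == 0 or joined["y"].std(ddof=1) == 0:
                warnings.warn(f"zero variance for {name!r} in {ds}; r undefined")
                rows.append({"feature": name, "dataset": ds, "r": np.nan,
                             "p": np.nan, "n": len(joined)})
                continue
            r, p = stats.pearsonr(joined["x"], joined["y"])
            rows.append({"feature": name, "dataset": ds, "r": float(r),
                         "p": float(p), "n": len(joined)})
    per_dataset = pd.DataFrame(rows)
    if add_bh:
        mask = per_dataset["p"].notna()
        per_dataset.loc[mask, "p_bh"] = _benjamini_hochberg(per_dataset.loc[mask, "p"].to_numpy())

    grp = per_dataset.dropna(subset=["r"]).groupby("feature")["r"]
    summary = pd.DataFrame({
        "mean_r": grp.mean(),
        "sem_r": grp.sem(ddof=1),
        "n_datasets": grp.count(),
    }).reindex(feature_cols)
    return per_dataset, summary


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0, 1)
    return out


# ---------------------------------------------------------------------------
# paired lifetime test


@dataclass(frozen=True)
class PairedTestResult:
    n: int
    statistic: float
    p_value: float


def paired_lifetime_test(aged: pd.Series, young: pd.Series,
                         min_n: int = 6) -> PairedTestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test on shared proteins.

    Zero differences are dropped (Wilcoxon convention); if every difference
    is zero the test is vacuous and p = 1 is returned by convention.
    """
    shared = aged.index.intersection(young.index)
    if len(shared) < min_n:
        raise ComparisonError(f"need >= {min_n} shared proteins, got {len(shared)}")
    a = aged.loc[shared].to_numpy(dtype=float)
    y = young.loc[shared].to_numpy(dtype=float)
    if np.all(a == y):
        warnings.warn("all paired differences are zero; p = 1 by convention")
        return PairedTestResult(n=len(shared), statistic=np.nan, p_value=1.0)
    res = stats.wilcoxon(a, y, zero_method="wilcox", alternative="two-sided")
    return PairedTestResult(n=len(shared), statistic=float(res.statistic),
                            p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# group ANOVA


@dataclass(frozen=True)
class AnovaResult:
    method: str                  # "ordinary" or "welch"
    statistic: float
    p_value: float
    bf_statistic: float          # Brown-Forsythe ANOVA F*
    bf_p_value: float
    posthoc_method: str
    posthoc: pd.DataFrame        # group, n, effect (mean - reference mean), p_corrected
    excluded: list[str] = field(default_factory=list)


def _welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedasticity-robust one-way ANOVA."""
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = (w * m).sum() / w.sum()
    k = len(groups)
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = 3.0 * ((1 - w / w.sum()) ** 2 / (n - 1)).sum() / (k * k - 1)
    f_stat = num / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    df2 = 1.0 / lam
    p = stats.f.sf(f_stat, k - 1, df2)
    return float(f_stat), float(p)


def _brown_forsythe_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Brown-Forsythe F* ANOVA on means (variance-weighted, Satterthwaite df)."""
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    grand = (n * m).sum() / n.sum()
    num = (n * (m - grand) ** 2).sum()
    c = (1 - n / n.sum()) * v
    denom = c.sum()
    f_star = num / denom
    df1 = len(groups) - 1
    df2 = denom ** 2 / ((c ** 2) / (n - 1)).sum()
    return float(f_star), float(stats.f.sf(f_star, df1, df2))


def _games_howell(groups: dict[str, np.ndarray], reference: str) -> pd.DataFrame:
    """Games-Howell pairwise comparisons of each group against the reference."""
    ref = groups[reference]
    nr, mr, vr = len(ref), ref.mean(), ref.var(ddof=1)
    rows = []
    for name, g in groups.items():
        if name == reference:
            continue
        ng, mg, vg = len(g), g.mean(), g.var(ddof=1)
        se2 = vg / ng + vr / nr
        t = (mg - mr) / np.sqrt(se2)
        df = se2 ** 2 / ((vg / ng) ** 2 / (ng - 1) + (vr / nr) ** 2 / (nr - 1))
        # studentized-range correction over the full number of groups
        p = stats.studentized_range.sf(abs(t) * np.sqrt(2.0), len(groups), df)
        rows.append({"group": name, "n": ng, "effect": float(mg - mr),
                     "p_corrected": float(p)})
    return pd.DataFrame(rows)


def group_anova(values: pd.Series, labels: pd.Series, reference: str,
                posthoc_n_threshold: int = 50, min_group_n: int = 3,
                homogeneity_alpha: float = 0.05) -> AnovaResult:
    """Omnibus ANOVA across categories plus posthoc tests against a reference.

    Groups with fewer than ``min_group_n`` members are excluded with a
    warning.  When a Brown-Forsythe (median-centered Levene) test finds the
    variances homogeneous, an ordinary ANOVA with Tukey-style posthoc is
    used; otherwise Welch's ANOVA with Dunnett posthoc for small groups
    (every group n < ``posthoc_n_threshold``) or Games-Howell for large
    ones.
    """
    joined = pd.concat({"v": values, "lab": labels}, axis=1).dropna()
    groups: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, sub in joined.groupby("lab"):
        arr = sub["v"].to_numpy(dtype=float)
        if len(arr) < min_group_n:
            excluded.append(str(name))
            continue
        groups[str(name)] = arr
    if excluded:
        warnings.warn(f"excluded group(s) with < {min_group_n} members: {excluded}")
    if len(groups) < 2:
        raise ComparisonError("need >= 2 groups with enough members")
    if reference not in groups:
        raise ComparisonError(f"reference group {reference!r} missing or too small")

    arrs = list(groups.values())
    bf_stat, bf_p = _brown_forsythe_anova(arrs)
    _, levene_p = stats.levene(*arrs, center="median")

    others = {k: v for k, v in groups.items() if k != reference}
    if levene_p > homogeneity_alpha:
        method = "ordinary"
        f_stat, p = stats.f_oneway(*arrs)
        tukey = stats.tukey_hsd(*arrs)
        names = list(groups)
        i_ref = names.index(reference)
        rows = [{"group": name, "n": len(groups[name]),
                 "effect": float(groups[name].mean() - groups[reference].mean()),
                 "p_corrected": float(tukey.pvalue[names.index(name), i_ref])}
                for name in others]
        posthoc = pd.DataFrame(rows)
        posthoc_method = "tukey"
    else:
        method = "welch"
        f_stat, p = _welch_anova(arrs)
        if all(len(g) < posthoc_n_threshold for g in groups.values()):
            res = stats.dunnett(*others.values(), control=groups[reference])
            posthoc = pd.DataFrame({
                "group": list(others),
                "n": [len(g) for g in others.values()],
                "effect": [float(g.mean() - groups[reference].mean()) for g in others.values()],
                "p_corrected": [float(pv) for pv in res.pvalue],
            })
            posthoc_method = "dunnett"
        else:
            posthoc = _games_howell(groups, reference)
            posthoc_method = "games-howell"
    return AnovaResult(method=method, statistic=float(f_stat), p_value=float(p),
                       bf_statistic=bf_stat, bf_p_value=bf_p,
                       posthoc_method=posthoc_method, posthoc=posthoc,
                       excluded=excluded)


# ---------------------------------------------------------------------------
# log-normality


@dataclass(frozen=True)
class LognormalityReport:
    statistic: float
    critical_value_5pct: float
    passes: bool
    n: int
    critical_values: tuple[float, ...]
    significance_levels: tuple[float, ...]


def lognormality_check(lifetimes: pd.Series | np.ndarray, min_n: int = 20) -> LognormalityReport:
    """Anderson-Darling normality test on log10(lifetimes); pass at 5%."""
    arr = np.asarray(pd.Series(lifetimes).dropna(), dtype=float)
    if len(arr) < min_n:
        raise ComparisonError(f"need >= {min_n} lifetimes, got {len(arr)}")
    if np.any(arr <= 0):
        raise DataError("lifetimes must be positive for the log-normality check")
    with warnings.catch_warnings():
        # keep the classical critical-value interface while scipy migrates it
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(np.log10(arr), dist="norm")
    crit_5 = float(res.critical_values[list(res.significance_level).index(5.0)])
    return LognormalityReport(statistic=float(res.statistic),
                              critical_value_5pct=crit_5,
                              passes=bool(res.statistic < crit_5),
                              n=len(arr),
                              critical_values=tuple(float(c) for c in res.critical_values),
                              significance_levels=tuple(float(s) for s in res.significance_level))
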