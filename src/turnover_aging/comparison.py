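"""Aged-vs-young comparative machinery.

Median rescaling of the aged lifetimes onto the young scale, per-dataset
log2 fold changes, the "same direction in at least 3 of 4 datasets"
consistency rule, extremes (rLL / rSL lists), percentile groups, z-score
matrices, the lifetime-compression correlation with its raw-ratio
bidirectionality control, abundance quadrants, and cell-type specificity.

All operations are deterministic; ties are resolved by documented rules
(lexicographic protein id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComparisonError, DataError

DATASET_ORDER = ("cortex_hom", "cerebellum_hom", "cortex_syn", "cerebellum_syn")


@dataclass(frozen=True)
class RescaleResult:
    dataset: str
    factor: float               # 0.217 means aged lifetimes 21.7% longer
    rescaled: pd.Series         # aged lifetimes divided by (1 + factor)

    @property
    def percent(self) -> float:
        return 100.0 * self.factor


def median_rescale(aged: pd.Series, young: pd.Series, dataset: str = "",
                   min_overlap: int = 10) -> RescaleResult:
    """Linearly rescale aged lifetimes so the median aged/young ratio is 1.

    ``factor`` is the median over shared proteins of (aged/young) - 1; the
    rescaled aged lifetimes are aged / (1 + factor).
    """
    shared = aged.index.intersection(young.index)
    if len(shared) < min_overlap:
        raise ComparisonError(
            f"only {len(shared)} shared proteins (< {min_overlap}) for dataset {dataset!r}")
    ratio = aged.loc[shared] / young.loc[shared]
    factor = float(ratio.median()) - 1.0
    return RescaleResult(dataset=dataset, factor=factor,
                         rescaled=aged / (1.0 + factor))


def compute_log2fc(rescaled_aged: pd.Series, young: pd.Series) -> pd.Series:
    """log2(rescaled aged / young) on the shared index; NaN where either side
    is absent."""
    shared = rescaled_aged.index.intersection(young.index)
    a, y = rescaled_aged.loc[shared], young.loc[shared]
    if (a <= 0).any() or (y <= 0).any():
        raise DataError("non-positive lifetime in log2FC computation")
    return np.log2(a / y)


def build_log2fc_table(aged: dict[str, pd.Series], young: dict[str, pd.Series],
                       min_overlap: int = 10,
                       ) -> tuple[pd.DataFrame, dict[str, RescaleResult]]:
    """Per-dataset rescale + log2FC; returns (protein x dataset table, factors)."""
    rescales: dict[str, RescaleResult] = {}
    columns: dict[str, pd.Series] = {}
    for ds in aged:
        if ds not in young:
            continue
        res = median_rescale(aged[ds], young[ds], dataset=ds, min_overlap=min_overlap)
        rescales[ds] = res
        columns[ds] = compute_log2fc(res.rescaled, young[ds])
    table = pd.DataFrame(columns)
    table.index.name = "protein_id"
    return table, rescales


def consistency_filter(log2fc: pd.DataFrame, min_consistent: int = 3) -> pd.DataFrame:
    """Keep proteins whose log2FC has the same sign in >= ``min_consistent``
    datasets; exact zeros count toward neither direction.

    The returned frame carries n_datasets_measured, n_increase, n_decrease,
    direction (+1/-1), and mean_log2fc +/- SEM computed over all measured
    datasets (not only the consistent ones).
    """
    values = log2fc.to_numpy(dtype=float)
    measured = np.isfinite(values)
    n_measured = measured.sum(axis=1)
    n_inc = ((values > 0) & measured).sum(axis=1)
    n_dec = ((values < 0) & measured).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = np.nanmean(values, axis=1)
        sd = np.nanstd(values, axis=1, ddof=1)
    sem = sd / np.sqrt(np.maximum(n_measured, 1))

    out = pd.DataFrame({
        "n_datasets_measured": n_measured,
        "n_increase": n_inc,
        "n_decrease": n_dec,
        "mean_log2fc": mean,
        "sem_log2fc": sem,
    }, index=log2fc.index)
    keep = (n_inc >= min_consistent) | (n_dec >= min_consistent)
    out = out[keep].copy()
    out["direction"] = np.where(out["n_increase"] >= min_consistent, 1, -1)
    return out.sort_index()


def top_extremes(consistent: pd.DataFrame, k: int = 25) -> tuple[list[str], list[str]]:
    """(rLL ids, rSL ids): top / bottom ``k`` by mean_log2fc, ties broken by id."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return [], []
    if len(consistent) < k:
        warnings.warn(f"only {len(consistent)} consistent records for k={k}; returning all")
    ordered = consistent.iloc[np.lexsort((consistent.index, consistent["mean_log2fc"]))]
    rsl = list(ordered.index[:k])
    rll = list(ordered.index[-k:][::-1])
    return rll, rsl


def percentile_groups(values: pd.Series) -> pd.Series:
    """Assign rSL / middle / rLL / unassigned percentile-band labels.

    Convention (documented; the cutoffs are <25th, [37.5th, 67.5th], >75th):
    each value occupies the rank interval [#(x < v), #(x <= v)] / n.  It is
    assigned to a band only when that whole interval lies inside the band:
    rSL when #(x <= v)/n < 0.25, rLL when #(x < v)/n > 0.75, middle when
    #(x < v)/n >= 0.375 and #(x <= v)/n <= 0.675.  Ties therefore never
    straddle a cutoff, and a constant vector is entirely unassigned.
    """
    v = values.dropna()
    if len(v) < 8:
        raise ComparisonError(f"need >= 8 values for percentile groups, got {len(v)}")
    arr = v.to_numpy(dtype=float)
    n = len(arr)
    sorted_arr = np.sort(arr)
    strict = np.searchsorted(sorted_arr, arr, side="left") / n
    weak = np.searchsorted(sorted_arr, arr, side="right") / n
    labels = np.full(n, "unassigned", dtype=object)
    labels[weak < 0.25] = "rSL"
    labels[strict > 0.75] = "rLL"
    labels[(strict >= 0.375) & (weak <= 0.675)] = "middle"
    out = pd.Series("unassigned", index=values.index, dtype=object)
    out.loc[v.index] = labels
    return out


def zscore_matrix(lifetimes: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (sample SD, ddof=1); NaN cells stay NaN; rows with
    zero SD become zeros with a warning."""
    values = lifetimes.to_numpy(dtype=float)
    finite = np.isfinite(values)
    if (finite.sum(axis=1) < 2).any():
        raise ComparisonError("every row needs >= 2 finite values for z-scoring")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=1, keepdims=True)
        sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    zero_sd = (sd == 0).ravel()
    if zero_sd.any():
        warnings.warn(f"{int(zero_sd.sum())} row(s) with zero SD z-scored to 0")
        sd[zero_sd] = 1.0
    z = (values - mean) / sd
    return pd.DataFrame(z, index=lifetimes.index, columns=lifetimes.columns)


# ---------------------------------------------------------------------------
# lifetime compression and its raw-ratio control

#: below this SD the log2FC vector is treated as constant (pure rescaling)
_DEGENERATE_SD = 1e-6


@dataclass(frozen=True)
class CompressionReport:
    pearson_r: float
    p_value: float
    n: int
    tertile_mean_log2fc: dict[str, float]  # short / middle / long
    tertiles: pd.Series                    # per-protein tertile labels
    degenerate: bool = False


def lifetime_tertiles(mean_lifetime: pd.Series) -> pd.Series:
    """Equal-count short / middle / long thirds of the lifetime distribution."""
    ranks = mean_lifetime.rank(method="first")
    edges = np.ceil(np.array([1, 2]) * len(ranks) / 3)
    labels = np.where(ranks <= edges[0], "short",
                      np.where(ranks <= edges[1], "middle", "long"))
    return pd.Series(labels, index=mean_lifetime.index, dtype=object)


def lifetime_compression(mean_log2fc: pd.Series, mean_lifetime: pd.Series,
                         min_n: int = 30) -> CompressionReport:
    """Correlate lifetime change with average lifetime and summarize tertiles.

    A negative Pearson r (short-lived proteins relatively lengthened,
    long-lived relatively shortened) is the compression signature.  When the
    log2FC vector is numerically constant (pure rescaling, zero noise) the
    correlation is reported as exactly 0 rather than amplifying floating-
    point residue.
    """
    joined = pd.concat({"fc": mean_log2fc, "life": mean_lifetime}, axis=1).dropna()
    if len(joined) < min_n:
        raise ComparisonError(f"need >= {min_n} proteins, got {len(joined)}")
    if joined["life"].std(ddof=1) == 0:
        raise ComparisonError("degenerate lifetime variance")
    tert = lifetime_tertiles(joined["life"])
    tert_means = {lab: float(joined.loc[tert == lab, "fc"].mean())
                  for lab in ("short", "middle", "long")}
    if joined["fc"].std(ddof=1) < _DEGENERATE_SD:
        return CompressionReport(0.0, 1.0, len(joined), tert_means, tert, degenerate=True)
    r, p = stats.pearsonr(joined["fc"], joined["life"])
    return CompressionReport(float(r), float(p), len(joined), tert_means, tert)


@dataclass(frozen=True)
class RawRatioReport:
    """Median (aged - young) labeled-fraction differences per lifetime tertile."""

    median_diff: pd.DataFrame   # tertile x time
    p_values: pd.DataFrame      # sign-test p per tertile x time
    bidirectional: bool


def raw_ratio_check(aged_fractions: pd.DataFrame, young_fractions: pd.DataFrame,
                    tertiles: pd.Series, alpha: float = 0.05,
                    min_tertile_n: int = 10) -> RawRatioReport:
    """Bidirectionality control on raw labeled fractions.

    Inputs are protein x time tables of observed heavy fractions (replicate
    means) at common pulse times.  Flags ``bidirectional`` when, at every
    evaluated time, the short-lived tertile median difference is < 0 AND the
    long-lived tertile median difference is > 0, each supported by a
    two-sided sign test at ``alpha``.  A global slowdown moves every tertile
    the same way and therefore does not raise the flag.
    """
    times = [c for c in aged_fractions.columns if c in young_fractions.columns]
    if not times:
        raise ComparisonError("no common pulse times between cohorts")
    shared = aged_fractions.index.intersection(young_fractions.index).intersection(tertiles.index)
    diffs = aged_fractions.loc[shared, times] - young_fractions.loc[shared, times]

    med = pd.DataFrame(index=["short", "middle", "long"], columns=times, dtype=float)
    pvals = pd.DataFrame(index=["short", "middle", "long"], columns=times, dtype=float)
    for lab in med.index:
        sub = diffs[tertiles.loc[shared] == lab]
        if len(sub) < min_tertile_n:
            warnings.warn(f"tertile {lab!r} has {len(sub)} proteins; skipped")
            continue
        for t in times:
            d = sub[t].dropna()
            d = d[d != 0]
            med.at[lab, t] = float(sub[t].median())
            if len(d) == 0:
                pvals.at[lab, t] = 1.0
            else:
                pvals.at[lab, t] = stats.binomtest(int((d > 0).sum()), len(d)).pvalue

    flag = True
    for t in times:
        ok_short = (pd.notna(med.at["short", t]) and med.at["short", t] < 0
                    and pvals.at["short", t] < alpha)
        ok_long = (pd.notna(med.at["long", t]) and med.at["long", t] > 0
                   and pvals.at["long", t] < alpha)
        if not (ok_short and ok_long):
            flag = False
    return RawRatioReport(median_diff=med, p_values=pvals, bidirectional=flag)


# ---------------------------------------------------------------------------
# quadrants and cell types


def quadrant_classify(delta_lifetime: float, delta_abundance: float) -> str:
    """Joint sign classification; an exact zero on either axis is unclassified."""
    if not (np.isfinite(delta_lifetime) and np.isfinite(delta_abundance)):
        return "unclassified"
    if delta_lifetime == 0 or delta_abundance == 0:
        return "unclassified"
    if delta_lifetime > 0:
        return "up_up" if delta_abundance > 0 else "up_down"
    return "down_up" if delta_abundance > 0 else "down_down"


def quadrant_table(delta_lifetime: pd.Series, delta_abundance: pd.Series) -> pd.Series:
    joined = pd.concat({"l": delta_lifetime, "a": delta_abundance}, axis=1)
    return pd.Series([quadrant_classify(row.l, row.a) for row in joined.itertuples()],
                     index=joined.index, dtype=object)


def celltype_specificity(expression: pd.DataFrame, threshold: float = 1.0) -> pd.Series:
    """Assign each protein the cell type whose log2 expression exceeds each of
    the other three by strictly more than ``threshold``; otherwise 'none'."""
    if expression.shape[1] != 4:
        raise DataError(f"expected 4 cell-type columns, got {expression.shape[1]}")
    values = expression.to_numpy(dtype=float)
    out = np.full(len(expression), "none", dtype=object)
    complete = np.isfinite(values).all(axis=1)
    if (~complete).any():
        warnings.warn(f"{int((~complete).sum())} protein(s) with missing expression -> none")
    order = np.argsort(values, axis=1)
    best = order[:, -1]
    second_val = np.take_along_axis(values, order[:, -2:-1], axis=1).ravel()
    best_val = np.take_along_axis(values, order[:, -1:], axis=1).ravel()
    assign = complete & (best_val - second_val > threshold)
    cols = np.asarray(expression.columns, dtype=object)
    out[assign] = cols[best[assign]]
    return pd.Series(out, index=expression.index, dtype=object)
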