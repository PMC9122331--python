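"""Protein lifetime estimation from heavy/light ratio time courses.

Parses proteinGroups-dialect TSV tables, summarizes peptide-level ratios,
fits one degradation rate constant per (protein, cohort, dataset) under the
reuse-corrected labeling model, derives 95% confidence intervals from the
profile of the residual sum of squares, applies quality-control filters, and
median-normalizes LFQ abundances.

Fitting conventions (all configurable through :class:`FitOptions`):

* residuals are computed on heavy *fractions* (bounded in [0, 1)) rather
  than raw ratios, so high-ratio observations do not dominate;
* every replicate observation enters the objective individually, plus a
  single t=0 anchor with ratio 0;
* the half-life is searched on a log grid over [0.1, 1000] days and refined
  by bounded scalar minimization; solutions pinned at either bound are
  flagged censored rather than silently clipped;
* the 95% CI is the set of half-lives whose RSS stays below
  ``RSS_min * (1 + F(1, n-1; 0.95) / (n - 1))`` (profile-likelihood bounds
  for a one-parameter least-squares fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, FitError, FormatError, NormalizationError
from .kinetics import (
    DEFAULT_POOL_PARAMS,
    PrecursorPoolParams,
    heavy_fraction_grid,
    ratio_to_fraction,
)

RATIO_PREFIX = "Ratio H/L "
LFQ_H_PREFIX = "LFQ intensity H "
LFQ_L_PREFIX = "LFQ intensity L "
_MANDATORY_COLUMNS = ("Protein IDs",)
_FLAG_DROP = {
    "Reverse": "REV__",
    "Potential contaminant": "CON__",
}

LN2 = math.log(2.0)


@dataclass
class LabelTimeCourse:
    """Replicate H/L observations for one (protein, cohort, dataset)."""

    protein_id: str
    dataset: str
    cohort: str
    observations: list[tuple[float, str, float]]  # (time, replicate_id, hl_ratio)
    n_peptides: int = 0

    @property
    def positive_times(self) -> list[float]:
        return sorted({t for t, _, _ in self.observations if t > 0})


@dataclass
class LifetimeRecord:
    """Fitted half-life with CI bounds and QC flags."""

    protein_id: str
    dataset: str
    cohort: str
    halflife: float
    k: float
    ci_lower: float
    ci_upper: float
    rss: float
    n_timepoints: int
    qc_flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class FitOptions:
    halflife_bounds: tuple[float, float] = (0.1, 1000.0)
    coarse_grid_size: int = 160
    ci_level: float = 0.95
    #: relative closeness to a bound that triggers a censored flag
    censor_rel_tol: float = 1e-3

    def __post_init__(self) -> None:
        object.__setattr__(self, "halflife_bounds",
                           tuple(float(b) for b in self.halflife_bounds))
        if not 0 < self.halflife_bounds[0] < self.halflife_bounds[1]:
            raise ValueError(f"invalid halflife_bounds {self.halflife_bounds}")


@dataclass(frozen=True)
class QCRules:
    wide_ci_factor: float = 1.0      # flag when (c2 - c1) > factor * halflife
    strict_ci_factor: float = 2.0    # stricter flag when c2 > factor * halflife
    drop_decreasing: bool = True


# ---------------------------------------------------------------------------
# readers


def read_sample_map(path: str | Path) -> pd.DataFrame:
    sm = pd.read_csv(path, sep="\t")
    required = {"sample", "cohort", "dataset", "time", "replicate"}
    missing = required - set(sm.columns)
    if missing:
        raise FormatError(f"sample map missing column(s): {sorted(missing)}")
    return sm


def read_protein_groups(path: str | Path, sample_map: pd.DataFrame,
                        ) -> tuple[list[LabelTimeCourse], pd.DataFrame]:
    """Parse one proteinGroups-dialect TSV into time courses plus raw LFQ table.

    Rows flagged Reverse / Potential contaminant (also recognized by the
    ``REV__`` / ``CON__`` id prefixes) or Only identified by site are
    dropped.  For every mapped sample column present in the file, ratio
    cells become observations; observed t=0 cells are discarded and replaced
    by exactly one synthetic t=0 anchor (ratio 0) per course.  Malformed
    numeric cells are treated as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise FormatError(f"empty proteinGroups file: {path}")
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")

    keep = pd.Series(True, index=df.index)
    for col, prefix in _FLAG_DROP.items():
        if col in df.columns:
            keep &= df[col].fillna("") != "+"
        keep &= ~df["Protein IDs"].str.startswith(prefix)
    if "Only identified by site" in df.columns:
        keep &= df["Only identified by site"].fillna("") != "+"
    df = df[keep].reset_index(drop=True)

    sample_info = {row["sample"]: row for _, row in sample_map.iterrows()}
    ratio_cols = [c for c in df.columns if c.startswith(RATIO_PREFIX)
                  and c[len(RATIO_PREFIX):] in sample_info]
    if not ratio_cols:
        raise FormatError("no ratio columns match the sample map")

    peptides = pd.to_numeric(df["Peptides"], errors="coerce").fillna(0).astype(int) \
        if "Peptides" in df.columns else pd.Series(0, index=df.index)

    courses: dict[tuple[str, str, str], LabelTimeCourse] = {}
    for col in ratio_cols:
        info = sample_info[col[len(RATIO_PREFIX):]]
        t = float(info["time"])
        values = pd.to_numeric(df[col], errors="coerce")
        for i, val in values.items():
            key = (df.at[i, "Protein IDs"], str(info["cohort"]), str(info["dataset"]))
            if key not in courses:
                courses[key] = LabelTimeCourse(
                    protein_id=key[0], cohort=key[1], dataset=key[2],
                    observations=[(0.0, "anchor", 0.0)], n_peptides=int(peptides[i]))
            if t > 0 and np.isfinite(val):
                if val < 0:
                    raise DataError(f"negative H/L ratio for {key[0]} in {col}")
                courses[key].observations.append((t, str(info["replicate"]), float(val)))

    lfq_cols = [c for c in df.columns
                if (c.startswith(LFQ_H_PREFIX) and c[len(LFQ_H_PREFIX):] in sample_info)
                or (c.startswith(LFQ_L_PREFIX) and c[len(LFQ_L_PREFIX):] in sample_info)]
    lfq = df[["Protein IDs", *lfq_cols]].copy()
    lfq[lfq_cols] = lfq[lfq_cols].apply(pd.to_numeric, errors="coerce")
    lfq = lfq.rename(columns={"Protein IDs": "protein_id"})
    return list(courses.values()), lfq


def summarize_peptide_ratios(peptide_table: pd.DataFrame,
                             min_peptides: int = 4) -> pd.DataFrame:
    """Protein-level H/L per sample: median of peptide ratios, reported only
    when the peptide count reaches ``min_peptides`` (default 4, i.e. > 3).

    Input columns: protein_id, sample, hl_ratio.  Returns a protein x sample
    pivot with NaN where the count threshold is not met.
    """
    if peptide_table.empty:
        raise DataError("peptide table is empty")
    if (peptide_table["hl_ratio"].dropna() < 0).any():
        raise DataError("negative peptide H/L ratio")
    grouped = peptide_table.dropna(subset=["hl_ratio"]).groupby(["protein_id", "sample"])["hl_ratio"]
    med = grouped.median()
    med[grouped.count() < min_peptides] = np.nan
    return med.unstack("sample")


# ---------------------------------------------------------------------------
# fitting


def _course_arrays(tc: LabelTimeCourse) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([t for t, _, _ in tc.observations], dtype=float)
    ratios = np.array([r for _, _, r in tc.observations], dtype=float)
    if not np.all(np.isfinite(ratios)):
        raise DataError(f"non-finite ratio for {tc.protein_id}")
    return times, ratios


def fit_lifetime(tc: LabelTimeCourse,
                 params: PrecursorPoolParams = DEFAULT_POOL_PARAMS,
                 options: FitOptions = FitOptions()) -> LifetimeRecord:
    """Fit the degradation rate of one time course; see module docstring."""
    times, ratios = _course_arrays(tc)
    pos = times > 0
    if not np.any(pos):
        raise FitError(f"{tc.protein_id}: no observations at positive times")
    fractions = ratio_to_fraction(ratios)
    lo, hi = options.halflife_bounds

    unique_t, inverse = np.unique(times, return_inverse=True)

    def rss_of_halflife(th: float) -> float:
        h = heavy_fraction_grid(unique_t, np.array([LN2 / th]), params)[0]
        resid = fractions - h[inverse]
        return float(resid @ resid)

    # coarse vectorized log-grid search
    grid = np.geomspace(lo, hi, options.coarse_grid_size)
    h_grid = heavy_fraction_grid(unique_t, LN2 / grid, params)
    resid = fractions[None, :] - h_grid[:, inverse]
    rss_grid = np.einsum("ij,ij->i", resid, resid)
    i_best = int(np.argmin(rss_grid))

    bracket_lo = grid[max(i_best - 1, 0)]
    bracket_hi = grid[min(i_best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda x: rss_of_halflife(10.0 ** x),
                                   bounds=(math.log10(bracket_lo), math.log10(bracket_hi)),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    t_hat = 10.0 ** res.x
    rss_min = float(res.fun)
    if rss_grid[i_best] < rss_min:  # grid edge can beat the local refine
        t_hat, rss_min = float(grid[i_best]), float(rss_grid[i_best])

    flags: set[str] = set()
    if len(tc.positive_times) < 2:
        flags.add("single_timepoint")
    if t_hat >= hi * (1.0 - options.censor_rel_tol):
        flags.add("censored_slow")
        t_hat = hi
    elif t_hat <= lo * (1.0 + options.censor_rel_tol):
        flags.add("censored_fast")
        t_hat = lo

    n = len(times)
    c1, c2 = _profile_ci(rss_of_halflife, t_hat, rss_min, n, (lo, hi), options.ci_level)
    return LifetimeRecord(protein_id=tc.protein_id, dataset=tc.dataset,
                          cohort=tc.cohort, halflife=t_hat, k=LN2 / t_hat,
                          ci_lower=c1, ci_upper=c2, rss=rss_min,
                          n_timepoints=len(tc.positive_times), qc_flags=flags)


def _profile_ci(rss_fn, t_hat: float, rss_min: float, n: int,
                bounds: tuple[float, float], level: float) -> tuple[float, float]:
    """Profile-likelihood CI: RSS threshold via the F(1, n-1) statistic."""
    dof = max(n - 1, 1)
    f_crit = stats.f.ppf(level, 1, dof)
    threshold = rss_min * (1.0 + f_crit / dof)
    if rss_min == 0.0 or threshold <= rss_min:
        return t_hat, t_hat

    lo, hi = bounds

    def g(log_th: float) -> float:
        return rss_fn(10.0 ** log_th) - threshold

    def side(a: float, b: float, fallback: float) -> float:
        ga, gb = g(a), g(b)
        if ga <= 0:  # RSS never crosses the threshold before the bound
            return fallback
        return 10.0 ** optimize.brentq(g, a, b, xtol=1e-10)

    log_hat = math.log10(t_hat)
    c1 = side(math.log10(lo), log_hat, lo) if t_hat > lo else lo
    c2 = side(math.log10(hi), log_hat, hi) if t_hat < hi else hi
    return min(c1, t_hat), max(c2, t_hat)


def fit_many(courses: Iterable[LabelTimeCourse],
             params: PrecursorPoolParams = DEFAULT_POOL_PARAMS,
             options: FitOptions = FitOptions()) -> list[LifetimeRecord]:
    """Fit every course that has at least one positive-time observation."""
    records = []
    for tc in courses:
        if not any(t > 0 for t, _, _ in tc.observations):
            continue
        records.append(fit_lifetime(tc, params, options))
    return records


# ---------------------------------------------------------------------------
# QC


def mean_fraction_by_time(tc: LabelTimeCourse) -> dict[float, float]:
    by_time: dict[float, list[float]] = {}
    for t, _, r in tc.observations:
        if t > 0:
            by_time.setdefault(t, []).append(ratio_to_fraction(r))
    return {t: float(np.mean(v)) for t, v in sorted(by_time.items())}


def qc_filter(records: Iterable[LifetimeRecord],
              courses: Iterable[LabelTimeCourse],
              rules: QCRules = QCRules()) -> list[LifetimeRecord]:
    """Apply the exclusion and annotation rules.

    Removes records whose course has data at only one positive time, and
    records whose replicate-mean fraction decreases between consecutive
    positive times.  Annotates ``wide_ci`` when the CI width exceeds the
    half-life, and ``wide_ci_strict`` when the upper bound exceeds twice the
    half-life (both factors configurable).
    """
    course_of = {(tc.protein_id, tc.cohort, tc.dataset): tc for tc in courses}
    kept: list[LifetimeRecord] = []
    for rec in records:
        tc = course_of.get((rec.protein_id, rec.cohort, rec.dataset))
        if tc is None or len(tc.positive_times) < 2:
            rec.qc_flags.add("single_timepoint")
            continue
        if rules.drop_decreasing:
            means = list(mean_fraction_by_time(tc).values())
            if any(b < a for a, b in zip(means, means[1:])):
                rec.qc_flags.add("decreasing_labeling")
                continue
        if rec.ci_upper - rec.ci_lower > rules.wide_ci_factor * rec.halflife:
            rec.qc_flags.add("wide_ci")
        if rec.ci_upper > rules.strict_ci_factor * rec.halflife:
            rec.qc_flags.add("wide_ci_strict")
        kept.append(rec)
    return kept


def records_to_frame(records: Iterable[LifetimeRecord]) -> pd.DataFrame:
    rows = [{
        "protein_id": r.protein_id, "dataset": r.dataset, "cohort": r.cohort,
        "halflife_days": r.halflife, "k_per_day": r.k,
        "c1": r.ci_lower, "c2": r.ci_upper, "rss": r.rss,
        "n_timepoints": r.n_timepoints, "flags": ";".join(sorted(r.qc_flags)),
    } for r in records]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LFQ abundance


def summarize_lfq_levels(lfq: pd.DataFrame, sample_map: pd.DataFrame) -> pd.DataFrame:
    """Median-normalized, averaged protein abundances.

    Per sample, H and L intensities are summed into one value; each sample
    column is divided by its median and multiplied by the grand median; the
    normalized values are then averaged across replicates and pulse lengths
    within each (cohort, dataset).  Returns columns protein_id, dataset,
    cohort, lfq.
    """
    info = {row["sample"]: row for _, row in sample_map.iterrows()}
    samples = sorted({c[len(LFQ_H_PREFIX):] for c in lfq.columns if c.startswith(LFQ_H_PREFIX)}
                     & set(info))
    if not samples:
        raise FormatError("no LFQ intensity columns match the sample map")
    summed = pd.DataFrame({"protein_id": lfq["protein_id"]})
    for s in samples:
        h = lfq.get(LFQ_H_PREFIX + s)
        l = lfq.get(LFQ_L_PREFIX + s)
        total = (h.fillna(0.0) if h is not None else 0.0) + (l.fillna(0.0) if l is not None else 0.0)
        summed[s] = total

    medians = {s: float(summed[s].median()) for s in samples}
    if any(m == 0 or not np.isfinite(m) for m in medians.values()):
        bad = [s for s, m in medians.items() if m == 0 or not np.isfinite(m)]
        raise NormalizationError(f"cannot median-normalize all-zero sample column(s): {bad}")
    grand = float(np.median(summed[samples].to_numpy().ravel()))
    for s in samples:
        summed[s] = summed[s] / medians[s] * grand

    long = summed.melt(id_vars="protein_id", var_name="sample", value_name="value")
    long["cohort"] = long["sample"].map(lambda s: info[s]["cohort"])
    long["dataset"] = long["sample"].map(lambda s: info[s]["dataset"])
    out = (long.groupby(["protein_id", "cohort", "dataset"], as_index=False)["value"]
           .mean().rename(columns={"value": "lfq"}))
    return out
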