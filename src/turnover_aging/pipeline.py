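"""End-to-end orchestration: simulate -> fit -> QC -> compare -> features ->
correlations -> report.

Every stage writes its intermediate table as TSV under the output directory,
and the headline numbers (rescale factors, extremes, compression, tests) go
into a machine-readable ``summary.yaml``.  Reruns with the same config are
bit-identical: nothing time- or host-dependent is written to the report
files (the log goes to stderr).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison as cmp
from . import estimation as est
from . import statistics as stat
from .errors import ConfigError
from .features import build_feature_table
from .kinetics import PrecursorPoolParams, DEFAULT_POOL_PARAMS, ratio_to_fraction
from .synthetic import COHORTS, DATASETS, CohortConfig, write_cohort

log = logging.getLogger("turnover_aging")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; every threshold defaults to the value
    used throughout the analysis (documented per field)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    pool: PrecursorPoolParams = field(default_factory=lambda: DEFAULT_POOL_PARAMS)
    fit: est.FitOptions = field(default_factory=est.FitOptions)
    qc: est.QCRules = field(default_factory=est.QCRules)
    min_consistent: int = 3        # same-sign datasets required (3 of 4)
    k_extremes: int = 25           # rLL / rSL list size per side
    celltype_threshold: float = 1.0  # log2 margin for cell-type specificity
    min_overlap: int = 10          # shared proteins required for rescaling
    enrich_residues: tuple[str, ...] = ()
    enrich_factor: float = 2.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name, cls in (("cohort", CohortConfig), ("pool", PrecursorPoolParams),
                          ("fit", est.FitOptions), ("qc", est.QCRules)):
            value = getattr(self, name)
            if isinstance(value, dict):
                try:
                    object.__setattr__(self, name, cls(**value))
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"invalid {name} block: {exc}") from exc
        if self.min_consistent < 1 or self.min_consistent > 4:
            raise ConfigError("min_consistent must be in 1..4")
        if self.k_extremes < 0:
            raise ConfigError("k_extremes must be non-negative")
        object.__setattr__(self, "enrich_residues", tuple(self.enrich_residues))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["enrich_residues"] = list(self.enrich_residues)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _pyify(obj):
    """Convert numpy scalars/containers to plain Python for YAML output."""
    if isinstance(obj, dict):
        return {str(k): _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def fit_stage(tables_dir: Path, sample_map: pd.DataFrame, config: RunConfig,
              ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Fit + QC every (cohort, dataset) table; returns (lifetimes frame,
    abundance frame, observed replicate-mean fractions per cohort)."""
    all_records = []
    abundance_frames = []
    fractions: dict[str, dict[str, dict[float, list[float]]]] = {c: {} for c in COHORTS}
    for cohort in COHORTS:
        for dataset in DATASETS:
            path = tables_dir / f"proteinGroups_{cohort}_{dataset}.tsv"
            courses, lfq = est.read_protein_groups(path, sample_map)
            records = est.fit_many(courses, config.pool, config.fit)
            kept = est.qc_filter(records, courses, config.qc)
            all_records.extend(kept)
            abundance_frames.append(est.summarize_lfq_levels(lfq, sample_map))
            for tc in courses:
                per_time = est.mean_fraction_by_time(tc)
                store = fractions[cohort].setdefault(tc.protein_id, {})
                for t, f in per_time.items():
                    store.setdefault(t, []).append(f)
            log.info("fit %s/%s: %d courses, %d retained after QC",
                     cohort, dataset, len(records), len(kept))
    lifetimes = est.records_to_frame(all_records)
    abundance = pd.concat(abundance_frames, ignore_index=True)
    return lifetimes, abundance, fractions


def _lifetime_series(lifetimes: pd.DataFrame, cohort: str) -> dict[str, pd.Series]:
    out = {}
    sub = lifetimes[lifetimes["cohort"] == cohort]
    for ds, g in sub.groupby("dataset"):
        out[ds] = g.set_index("protein_id")["halflife_days"]
    return out


def _fraction_frame(fractions: dict, cohort: str) -> pd.DataFrame:
    """Protein x pulse-time table of observed fractions, dataset-averaged."""
    rows = {pid: {t: float(np.mean(v)) for t, v in per_time.items()}
            for pid, per_time in fractions[cohort].items()}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "protein_id"
    return df[sorted(df.columns)]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline on a synthetic cohort; returns the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=config.log_level,
                        format="%(asctime)s %(levelname)s %(message)s")
    config.to_yaml(outdir / "run_config.yaml")

    # --- simulate -----------------------------------------------------------
    sim_dir = outdir / "simulated"
    paths = write_cohort(config.cohort, sim_dir, config.pool,
                         enrich_residues=config.enrich_residues,
                         enrich_factor=config.enrich_factor)
    sample_map = est.read_sample_map(paths["sample_map"])
    log.info("simulated cohort written to %s", sim_dir)

    # --- fit + QC -----------------------------------------------------------
    lifetimes, abundance, fractions = fit_stage(sim_dir, sample_map, config)
    _write(lifetimes, outdir / "lifetimes.tsv")
    _write(abundance, outdir / "abundance.tsv")

    # --- compare ------------------------------------------------------------
    aged = _lifetime_series(lifetimes, "aged")
    young = _lifetime_series(lifetimes, "young")
    log2fc, rescales = cmp.build_log2fc_table(aged, young, min_overlap=config.min_overlap)
    _write(log2fc.reset_index(), outdir / "log2fc.tsv")
    factors_pct = {ds: res.percent for ds, res in rescales.items()}

    consistent = cmp.consistency_filter(log2fc, min_consistent=config.min_consistent)
    rll, rsl = cmp.top_extremes(consistent, k=config.k_extremes)
    groups = cmp.percentile_groups(consistent["mean_log2fc"])

    # mean lifetime per protein: aged/young average per dataset, then across datasets
    mean_life_parts = []
    for ds in log2fc.columns:
        shared = aged[ds].index.intersection(young[ds].index)
        mean_life_parts.append(((aged[ds].loc[shared] + young[ds].loc[shared]) / 2).rename(ds))
    mean_lifetime = pd.concat(mean_life_parts, axis=1).mean(axis=1)

    compression = cmp.lifetime_compression(consistent["mean_log2fc"],
                                           mean_lifetime.loc[consistent.index])
    tertiles_all = cmp.lifetime_tertiles(mean_lifetime)
    raw_check = cmp.raw_ratio_check(_fraction_frame(fractions, "aged"),
                                    _fraction_frame(fractions, "young"),
                                    tertiles_all)

    # abundance change + quadrants
    ab = abundance.pivot_table(index="protein_id", columns="cohort", values="lfq",
                               aggfunc="mean")
    delta_ab = np.log2(ab["aged"] / ab["young"]).replace([np.inf, -np.inf], np.nan)
    quadrants = cmp.quadrant_table(consistent["mean_log2fc"], delta_ab)

    # cell-type specificity from the annotation table
    annotations = pd.read_csv(paths["annotations"], sep="\t").set_index("protein_id")
    expr_cols = [c for c in annotations.columns if c.startswith("expr_")]
    celltype = cmp.celltype_specificity(annotations[expr_cols], config.celltype_threshold)
    celltype = celltype.rename("cell_type")

    report = consistent.copy()
    report["percentile_group"] = groups
    report["lifetime_tertile"] = tertiles_all.reindex(report.index)
    report["quadrant"] = quadrants.reindex(report.index)
    report["cell_type"] = celltype.reindex(report.index).map(
        lambda v: v.removeprefix("expr_") if isinstance(v, str) else v)
    _write(report.reset_index(), outdir / "comparison.tsv")

    zmat = cmp.zscore_matrix(log2fc.loc[[p for p in rll + rsl if p in log2fc.index]].dropna(
        thresh=2))
    _write(zmat.reset_index(), outdir / "extremes_zscores.tsv")
    _write(pd.DataFrame({"protein_id": rll + rsl,
                         "group": ["rLL"] * len(rll) + ["rSL"] * len(rsl)}),
           outdir / "extremes.tsv")

    # --- statistics on lifetimes -------------------------------------------
    paired = {}
    lognorm = {}
    for ds in log2fc.columns:
        paired[ds] = asdict(stat.paired_lifetime_test(aged[ds], young[ds]))
        lognorm[ds] = stat.lognormality_check(young[ds]).passes

    # --- features + correlations -------------------------------------------
    feature_table = build_feature_table(paths["fasta"], paths["annotations"])
    _write(feature_table, outdir / "features.tsv")
    core_features = ["length", "molecular_weight", "pI", "gravy", "avECPA",
                     "frac_expensive", "frac_affordable", "n_glyco",
                     "disorder_fraction", "aggregation_score"]
    per_ds, summary_corr = stat.feature_correlations(
        feature_table, log2fc,
        feature_cols=core_features + [f"frac_{aa}" for aa in "ACDEFGHIKLMNPQRSTVWY"])
    _write(per_ds, outdir / "correlations.tsv")
    _write(summary_corr.reset_index(), outdir / "correlations_summary.tsv")

    summary = _pyify({
        "n_proteins_simulated": config.cohort.n_proteins,
        "rescale_factors_percent": factors_pct,
        "n_consistent": int(len(consistent)),
        "rll": rll,
        "rsl": rsl,
        "compression": {
            "pearson_r": compression.pearson_r,
            "p_value": compression.p_value,
            "n": compression.n,
            "tertile_mean_log2fc": compression.tertile_mean_log2fc,
            "degenerate": compression.degenerate,
        },
        "raw_ratio_bidirectional": raw_check.bidirectional,
        "paired_lifetime_tests": paired,
        "young_lognormality_pass": lognorm,
        "seed": config.cohort.seed,
        "thresholds": {
            "min_consistent": config.min_consistent,
            "k_extremes": config.k_extremes,
            "celltype_log2_margin": config.celltype_threshold,
            "min_peptides": 4,
            "wide_ci_factor": config.qc.wide_ci_factor,
            "strict_ci_factor": config.qc.strict_ci_factor,
        },
    })
    (outdir / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    log.info("pipeline complete; summary at %s", outdir / "summary.yaml")
    return summary
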