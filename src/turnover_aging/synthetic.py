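"""Synthetic pulse-labeling cohort generator.

Produces ground-truth lifetimes, observation tables in the MaxQuant
``proteinGroups`` dialect, FASTA sequences, and annotation tables with the
statistical structure the downstream analysis assumes: log-normal lifetime
distributions, four datasets (cortex/cerebellum homogenate + synaptic
fraction), two cohorts (young, aged), replicated pulse time points,
multiplicative ratio noise, random missingness, and injected aging effects
(global lengthening, targeted rLL/rSL subsets, lifetime compression).

Everything is a pure function of (config, seed): per-table random streams
are derived from the master seed by stable hashing of (cohort, dataset), so
adding a dataset does not perturb the others.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .kinetics import (
    DEFAULT_POOL_PARAMS,
    KineticRate,
    PrecursorPoolParams,
    fraction_to_ratio,
    protein_heavy_fraction,
)

DATASETS = ("cortex_hom", "cerebellum_hom", "cortex_syn", "cerebellum_syn")
HOMOGENATE_OF = {
    "cortex_hom": "cortex_hom", "cortex_syn": "cortex_hom",
    "cerebellum_hom": "cerebellum_hom", "cerebellum_syn": "cerebellum_hom",
}
COHORTS = ("young", "aged")
CELL_TYPES = ("neuron", "astrocyte", "microglia", "oligodendrocyte")


@dataclass(frozen=True)
class EffectSpec:
    """Targeted aging effects injected on top of the global factor."""

    n_rll: int = 0          # proteins given extra lifetime lengthening in aged
    n_rsl: int = 0          # proteins given extra shortening
    extra_factor: float = 1.5
    compression_slope: float = 0.0  # power-law pivot exponent; 0 = none

    def validate(self, n_proteins: int) -> None:
        if self.n_rll < 0 or self.n_rsl < 0:
            raise ConfigError("n_rll and n_rsl must be non-negative")
        if self.n_rll + self.n_rsl > n_proteins:
            raise ConfigError("n_rll + n_rsl exceeds n_proteins")
        if self.extra_factor <= 0:
            raise ConfigError("extra_factor must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic two-cohort labeling experiment."""

    n_proteins: int = 1000
    young_median_halflife: float = 9.4   # days; aged median ~ 9.4 * 1.217 = 11.4
    lognormal_sigma: float = 0.35        # sd of log10(lifetime)
    global_aging_factor: float = 1.217   # aged lifetimes ~20% longer overall
    synaptic_factor: float = 1.20        # synaptic fraction lifetimes ~20% longer
    pulse_times: tuple[float, ...] = (0.0, 14.0, 21.0)
    replicates_per_time: int = 3
    ratio_noise_cv: float = 0.10
    missing_rate: float = 0.0
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be a positive integer")
        for name in ("young_median_halflife", "lognormal_sigma",
                     "global_aging_factor", "synaptic_factor"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        times = tuple(float(t) for t in self.pulse_times)
        if 0.0 not in times or not any(t > 0 for t in times):
            raise ConfigError("pulse_times must contain 0 and at least one positive time")
        if any(t < 0 for t in times):
            raise ConfigError("pulse_times must be non-negative")
        object.__setattr__(self, "pulse_times", times)
        if self.replicates_per_time < 1:
            raise ConfigError("replicates_per_time must be a positive integer")
        if self.ratio_noise_cv < 0:
            raise ConfigError("ratio_noise_cv must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if isinstance(self.effect_spec, dict):
            object.__setattr__(self, "effect_spec", EffectSpec(**self.effect_spec))
        self.effect_spec.validate(self.n_proteins)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pulse_times"] = list(self.pulse_times)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "effect_spec" in d and isinstance(d["effect_spec"], dict):
            d["effect_spec"] = EffectSpec(**d["effect_spec"])
        if "pulse_times" in d:
            d["pulse_times"] = tuple(float(t) for t in d["pulse_times"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _child_rng(seed: int, *tokens: str) -> np.random.Generator:
    """Stable per-stream RNG: master seed + sha256 of the token path."""
    digest = hashlib.sha256("/".join(tokens).encode()).digest()
    return np.random.default_rng([seed & 0xFFFFFFFF, int.from_bytes(digest[:8], "big")])


def sample_name(cohort: str, dataset: str, time: float, replicate: int) -> str:
    return f"{cohort}_{dataset}_d{time:g}_r{replicate}"


# ---------------------------------------------------------------------------
# ground truth


def generate_truth(config: CohortConfig) -> pd.DataFrame:
    """Draw ground-truth lifetimes, abundances, effect labels and cell types.

    Young homogenate lifetimes are log-normal with the configured median and
    log10 sigma (cortex and cerebellum drawn independently).  Aged = young x
    global factor, then rLL/rSL proteins multiplied/divided by the extra
    factor, then compression applied as a power-law pivot around the aged
    median; synaptic datasets are the homogenate times the synaptic factor.
    """
    n = config.n_proteins
    eff = config.effect_spec
    rng = _child_rng(config.seed, "truth")

    protein_ids = [f"SYN{i:05d}" for i in range(n)]
    labels = np.array(["none"] * n, dtype=object)
    picked = rng.choice(n, size=eff.n_rll + eff.n_rsl, replace=False)
    labels[picked[:eff.n_rll]] = "rll"
    labels[picked[eff.n_rll:]] = "rsl"

    cell_type = rng.choice(list(CELL_TYPES) + ["none"], size=n,
                           p=[0.2, 0.1, 0.1, 0.1, 0.5])

    out = pd.DataFrame({"protein_id": protein_ids, "effect_label": labels,
                        "cell_type": cell_type})

    log10_med = math.log10(config.young_median_halflife)
    for region in ("cortex_hom", "cerebellum_hom"):
        young = 10.0 ** rng.normal(log10_med, config.lognormal_sigma, size=n)
        aged = young * config.global_aging_factor
        aged = np.where(labels == "rll", aged * eff.extra_factor, aged)
        aged = np.where(labels == "rsl", aged / eff.extra_factor, aged)
        if eff.compression_slope != 0.0:
            med = float(np.median(aged))
            aged = med * (aged / med) ** (1.0 - eff.compression_slope)
        syn = region.replace("_hom", "_syn")
        out[f"halflife_young_{region}"] = young
        out[f"halflife_aged_{region}"] = aged
        out[f"halflife_young_{syn}"] = young * config.synaptic_factor
        out[f"halflife_aged_{syn}"] = aged * config.synaptic_factor

    abundance = 10.0 ** rng.normal(7.0, 0.6, size=n)
    out["abundance_young"] = abundance
    out["abundance_aged"] = abundance
    return out


def truth_halflives(truth: pd.DataFrame, cohort: str, dataset: str) -> pd.Series:
    """Lifetimes for one (cohort, dataset), indexed by protein_id."""
    return truth.set_index("protein_id")[f"halflife_{cohort}_{dataset}"]


# ---------------------------------------------------------------------------
# observation tables (proteinGroups dialect)

_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Median-1 multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


def simulate_observations(truth: pd.DataFrame, config: CohortConfig,
                          params: PrecursorPoolParams = DEFAULT_POOL_PARAMS,
                          ) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Forward-simulate one proteinGroups-dialect table per (cohort, dataset).

    Returns ``(tables, sample_map)`` where ``sample_map`` maps each sample
    name to its (cohort, dataset, time, replicate).  Observed H/L ratios are
    the forward-model ratio times multiplicative log-normal noise; t=0
    columns are exactly 0; positive-time cells go missing independently with
    ``missing_rate``.  Decoy rows carrying the Reverse / Potential
    contaminant / Only identified by site flags are appended for parser
    tests.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    pos_times = [t for t in config.pulse_times if t > 0]
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    map_rows = []

    for cohort in COHORTS:
        for dataset in DATASETS:
            rng = _child_rng(config.seed, "obs", cohort, dataset)
            half = truth[f"halflife_{cohort}_{dataset}"].to_numpy()
            n = len(half)
            frac = {t: np.array([protein_heavy_fraction(t, KineticRate(math.log(2.0) / h), params)
                                 for h in half]) for t in pos_times}
            for t, f in frac.items():
                if np.any(f >= 1.0):
                    raise RuntimeError(f"model heavy fraction >= 1 at t={t}")

            df = pd.DataFrame({
                "Protein IDs": truth["protein_id"].to_numpy(),
                "Gene names": [f"Gene{pid[-5:]}" for pid in truth["protein_id"]],
                "Peptides": rng.integers(4, 40, size=n),
            })
            abundance = truth[f"abundance_{cohort}"].to_numpy()
            for t in config.pulse_times:
                for rep in range(1, config.replicates_per_time + 1):
                    name = sample_name(cohort, dataset, t, rep)
                    map_rows.append({"sample": name, "cohort": cohort,
                                     "dataset": dataset, "time": t, "replicate": rep})
                    if t == 0:
                        ratio = np.zeros(n)
                        f_exp = np.zeros(n)
                    else:
                        ratio = fraction_to_ratio(frac[t]) * _lognormal_noise(rng, config.ratio_noise_cv, n)
                        if config.missing_rate > 0:
                            ratio = np.where(rng.random(n) < config.missing_rate, np.nan, ratio)
                        f_exp = frac[t]
                    total = abundance * _lognormal_noise(rng, config.ratio_noise_cv, n)
                    df[f"Ratio H/L {name}"] = ratio
                    df[f"LFQ intensity H {name}"] = total * f_exp
                    df[f"LFQ intensity L {name}"] = total * (1.0 - f_exp)
            for col in _FLAG_COLUMNS:
                df[col] = ""
            tables[(cohort, dataset)] = _append_decoys(df)

    sample_map = pd.DataFrame(map_rows).drop_duplicates("sample").reset_index(drop=True)
    return tables, sample_map


def _append_decoys(df: pd.DataFrame) -> pd.DataFrame:
    """Append REV__ / CON__ / only-identified-by-site rows the parser must drop."""
    decoys = []
    for pid, gene, flag in (("REV__DECOY00001", "RevGene", "Reverse"),
                            ("CON__KRT00001", "Krt1", "Potential contaminant"),
                            ("SITEONLY00001", "SiteGene", "Only identified by site")):
        row = {c: 1.0 for c in df.columns if c.startswith(("Ratio", "LFQ"))}
        row.update({"Protein IDs": pid, "Gene names": gene, "Peptides": 5})
        for col in _FLAG_COLUMNS:
            row[col] = "+" if col == flag else ""
        decoys.append(row)
    return pd.concat([df, pd.DataFrame(decoys)], ignore_index=True)


# ---------------------------------------------------------------------------
# sequences + annotations

# rough mammalian background amino-acid frequencies
_AA_BACKGROUND = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "E": 0.071, "Q": 0.048, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.022, "F": 0.036, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.027, "V": 0.060,
}


def generate_sequences(truth: pd.DataFrame, seed: int,
                       length_range: tuple[int, int] = (80, 600),
                       enrich_residues: Sequence[str] = (),
                       enrich_factor: float = 2.0,
                       ) -> tuple[dict[str, str], pd.DataFrame]:
    """Fabricate one sequence per protein plus an annotation table.

    When ``enrich_residues`` is non-empty, rLL proteins draw those residues
    with probability multiplied by ``enrich_factor`` (renormalized), which
    creates a detectable composition/log2FC correlation downstream.  The
    annotation table carries fabricated glycosylation counts, disorder
    fractions, aggregation scores, and a 4-column log2 cell-type expression
    matrix consistent with ``truth.cell_type`` (the labeled type exceeds the
    best other column by > 1 log2 unit).
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    rng = _child_rng(seed, "sequences")
    aas = list(_AA_BACKGROUND)
    base_p = np.array([_AA_BACKGROUND[a] for a in aas])
    base_p = base_p / base_p.sum()
    rich_p = base_p.copy()
    for res in enrich_residues:
        rich_p[aas.index(res)] *= enrich_factor
    rich_p = rich_p / rich_p.sum()

    sequences: dict[str, str] = {}
    ann_rows = []
    for pid, label, ctype in zip(truth["protein_id"], truth["effect_label"], truth["cell_type"]):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        p = rich_p if (label == "rll" and len(enrich_residues) > 0) else base_p
        sequences[pid] = "".join(rng.choice(aas, size=length, p=p))

        expr = dict(zip(CELL_TYPES, rng.normal(8.0, 1.0, size=4)))
        if ctype in expr:
            expr[ctype] = max(v for t, v in expr.items() if t != ctype) \
                + 1.0 + abs(rng.normal(0.5, 0.25)) + 0.01
        row = {"protein_id": pid,
               "n_glyco": int(rng.poisson(2.0)),
               "disorder_fraction": float(rng.beta(2.0, 5.0)),
               "aggregation_score": float(rng.normal(0.0, 1.0))}
        row.update({f"expr_{t}": expr[t] for t in CELL_TYPES})
        ann_rows.append(row)
    return sequences, pd.DataFrame(ann_rows)


# ---------------------------------------------------------------------------
# writers


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_cohort(config: CohortConfig, outdir: str | Path,
                 params: PrecursorPoolParams = DEFAULT_POOL_PARAMS,
                 enrich_residues: Sequence[str] = (),
                 enrich_factor: float = 2.0) -> dict[str, Path]:
    """Generate and write the full synthetic cohort to ``outdir``.

    Writes truth.tsv, one proteinGroups_<cohort>_<dataset>.tsv per table,
    sample_map.tsv, sequences.fasta, annotations.tsv and config.yaml;
    returns the paths keyed by logical name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)
    tables, sample_map = simulate_observations(truth, config, params)
    sequences, annotations = generate_sequences(truth, config.seed,
                                                enrich_residues=enrich_residues,
                                                enrich_factor=enrich_factor)
    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path

    _write("truth", truth)
    _write("sample_map", sample_map)
    _write("annotations", annotations)
    for (cohort, dataset), df in tables.items():
        _write(f"proteinGroups_{cohort}_{dataset}", df)
    fasta = outdir / "sequences.fasta"
    write_fasta(sequences, fasta)
    paths["fasta"] = fasta
    config.to_yaml(outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return paths
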