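"""Per-protein biochemical features computed from sequence.

Length, average molecular weight, isoelectric point (bisection on the
Henderson-Hasselbalch net-charge function), GRAVY (Kyte-Doolittle), the 20
amino-acid composition fractions, and the average biosynthetic cost per
residue (avECPA) together with the fraction of metabolically expensive /
affordable residues.  The hydropathy, pKa, and cost tables are shipped as
editable TSV files under ``turnover_aging/data`` and are the single source
of truth for those constants.

All features are pure functions of sequence plus tables; optional
annotations (glycosylation counts, disorder fraction, aggregation score,
cell-type expression) are external inputs joined by protein id, never
computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# average residue (monomer) masses in Da; +H2O for the full chain
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_MASS = 18.01524


def _data_path(name: str) -> Path:
    return Path(resources.files("turnover_aging") / "data" / name)


def _read_table(name: str) -> pd.DataFrame:
    return pd.read_csv(_data_path(name), sep="\t", comment="#")


def load_hydropathy() -> dict[str, float]:
    df = _read_table("hydropathy.tsv")
    return dict(zip(df["residue"], df["hydropathy"].astype(float)))


def load_pka_table() -> pd.DataFrame:
    return _read_table("pka.tsv")


@dataclass(frozen=True)
class CostTable:
    """Per-residue biosynthetic energy cost and decay-normalized metric."""

    energy_cost: dict[str, float]
    decay_normalized_metric: dict[str, float]

    def __post_init__(self) -> None:
        for table in (self.energy_cost, self.decay_normalized_metric):
            if set(table) != set(STANDARD_AA):
                missing = set(STANDARD_AA) - set(table)
                raise ValueError(f"cost table must cover the 20 standard residues; missing {sorted(missing)}")
            if any(v <= 0 for v in table.values()):
                raise ValueError("cost table values must be positive")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CostTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            energy_cost=dict(zip(df["residue"], df["energy_cost"].astype(float))),
            decay_normalized_metric=dict(zip(df["residue"], df["decay_normalized_metric"].astype(float))),
        )


def load_cost_table() -> CostTable:
    return CostTable.from_tsv(_data_path("aa_costs.tsv"))


def _clean_sequence(sequence: str) -> str:
    """Uppercase and drop non-standard residues (X, U, B, Z, ...) with a warning."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    kept = [c for c in seq if c in _RESIDUE_MASS]
    if len(kept) != len(seq):
        dropped = sorted({c for c in seq if c not in _RESIDUE_MASS})
        warnings.warn(f"skipping {len(seq) - len(kept)} non-standard residue(s) {dropped}")
    if not kept:
        raise ValueError("sequence contains no standard residues")
    return "".join(kept)


def aa_composition(sequence: str) -> tuple[dict[str, float], int]:
    """Return ({residue: fraction}, length) over standard residues only."""
    seq = _clean_sequence(sequence)
    n = len(seq)
    return {aa: seq.count(aa) / n for aa in STANDARD_AA}, n


def molecular_weight(sequence: str) -> float:
    """Average (not monoisotopic) molecular weight in Da."""
    seq = _clean_sequence(sequence)
    return sum(_RESIDUE_MASS[c] for c in seq) + _WATER_MASS


def compute_gravy(sequence: str, scale: dict[str, float] | None = None) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    seq = _clean_sequence(sequence)
    scale = scale if scale is not None else load_hydropathy()
    return float(np.mean([scale[c] for c in seq]))


def net_charge(sequence: str, ph: float, pka: pd.DataFrame | None = None) -> float:
    """Henderson-Hasselbalch net charge at ``ph`` over ionizable groups.

    Positive groups (N-terminus, H, K, R) contribute ``+1/(1+10^(pH-pKa))``,
    negative groups (C-terminus, C, D, E, Y) ``-1/(1+10^(pKa-pH))``.
    """
    seq = _clean_sequence(sequence)
    pka = pka if pka is not None else load_pka_table()
    counts = {"Nterm": 1, "Cterm": 1}
    for aa in "CDEHKRY":
        counts[aa] = seq.count(aa)
    charge = 0.0
    for _, row in pka.iterrows():
        n = counts.get(row["group"], 0)
        if n == 0:
            continue
        if row["sign"] > 0:
            charge += n / (1.0 + 10.0 ** (ph - row["pka"]))
        else:
            charge -= n / (1.0 + 10.0 ** (row["pka"] - ph))
    return charge


def compute_pI(sequence: str, pka: pd.DataFrame | None = None, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on (0, 14).

    Net charge is strictly decreasing in pH, so the root is unique.
    """
    pka = pka if pka is not None else load_pka_table()
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_avECPA(sequence: str, costs: CostTable | None = None) -> float:
    """Mean biosynthetic energy cost per residue over the sequence."""
    seq = _clean_sequence(sequence)
    costs = costs if costs is not None else load_cost_table()
    return float(np.mean([costs.energy_cost[c] for c in seq]))


def classify_amino_acids(costs: CostTable | None = None, hi: float = 60.0,
                         lo: float = 20.0) -> tuple[set[str], set[str]]:
    """Split residues into (expensive, affordable) sets by the decay-normalized
    cost metric: strictly > ``hi`` is expensive, strictly < ``lo`` affordable."""
    if hi <= lo:
        raise ValueError(f"hi must exceed lo (got hi={hi}, lo={lo})")
    costs = costs if costs is not None else load_cost_table()
    expensive = {aa for aa, v in costs.decay_normalized_metric.items() if v > hi}
    affordable = {aa for aa, v in costs.decay_normalized_metric.items() if v < lo}
    return expensive, affordable


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {id: sequence}; duplicate ids are an error."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        records[rec.id] = str(rec.seq)
    return records


def build_feature_table(fasta: str | Path | dict[str, str],
                        annotations: pd.DataFrame | str | Path | None = None,
                        costs: CostTable | None = None,
                        hi: float = 60.0, lo: float = 20.0) -> pd.DataFrame:
    """Assemble the per-protein feature table.

    One row per FASTA record: length, molecular_weight, pI, gravy, the 20
    ``frac_<residue>`` composition columns, avECPA, frac_expensive and
    frac_affordable; optional annotation columns are left-joined on
    ``protein_id`` (missing ids keep NaN).
    """
    sequences = fasta if isinstance(fasta, dict) else read_fasta(fasta)
    if not sequences:
        raise ValueError("no sequences provided")
    costs = costs if costs is not None else load_cost_table()
    expensive, affordable = classify_amino_acids(costs, hi=hi, lo=lo)
    hydropathy = load_hydropathy()
    pka = load_pka_table()

    rows = []
    for pid, seq in sequences.items():
        comp, length = aa_composition(seq)
        row = {
            "protein_id": pid,
            "length": length,
            "molecular_weight": molecular_weight(seq),
            "pI": compute_pI(seq, pka),
            "gravy": compute_gravy(seq, hydropathy),
            "avECPA": compute_avECPA(seq, costs),
            "frac_expensive": sum(comp[aa] for aa in expensive),
            "frac_affordable": sum(comp[aa] for aa in affordable),
        }
        row.update({f"frac_{aa}": comp[aa] for aa in STANDARD_AA})
        rows.append(row)
    table = pd.DataFrame(rows)

    if annotations is not None:
        if not isinstance(annotations, pd.DataFrame):
            annotations = pd.read_csv(annotations, sep="\t")
        if "protein_id" not in annotations.columns:
            raise ValueError("annotation table must have a protein_id column")
        if annotations["protein_id"].duplicated().any():
            raise ValueError("duplicate protein_id in annotation table")
        table = table.merge(annotations, on="protein_id", how="left")
    return table
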