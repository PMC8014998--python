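"""Peptide evidence tables, labeling QC, and Lys-only protein ratios.

The evidence dialect is a TSV derived from a search engine's
modification-specific peptide output. Required columns::

    peptide  protein  nterm_mod  lys_mods  cleaved_after_dimethyl_lys
    ratio_hl_rep1..repK  spectral_count_rep1..repK

``nterm_mod`` is one of ``dimethyl, acetyl, pyroglu_E, pyroglu_Q, free``;
``lys_mods`` is a semicolon-separated list with one token per Lys in the
peptide, each of ``dimethyl_light, dimethyl_heavy, unmodified`` (empty for
Lys-less peptides). Ratios are log2(heavy/light); empty cells and the
string ``NaN`` are missing, never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NTERM_MODS = ("dimethyl", "acetyl", "pyroglu_E", "pyroglu_Q", "free")
LYS_MODS = ("dimethyl_light", "dimethyl_heavy", "unmodified")

# native MaxQuant modificationSpecificPeptides column names -> dialect names
MAXQUANT_COLUMN_MAP = {
    "Sequence": "peptide",
    "Proteins": "protein",
    "Leading razor protein": "protein",
    "N-term mod": "nterm_mod",
    "Modifications": "nterm_mod",
    "K mods": "lys_mods",
}


@dataclass
class PeptideEvidence:
    """One identified N-terminal peptide with per-replicate quantification."""

    peptide_seq: str
    protein_acc: str
    nterm_mod: str
    lys_mods: tuple[str, ...]
    ratio_hl: tuple[float | None, ...]
    spectral_count: tuple[int, ...]
    cleaved_after_dimethyl_lys: bool = False

    def __post_init__(self):
        if self.nterm_mod not in NTERM_MODS:
            raise ValueError(f"unknown modification {self.nterm_mod!r}")
        for m in self.lys_mods:
            if m not in LYS_MODS:
                raise ValueError(f"unknown modification {m!r}")
        for r in self.ratio_hl:
            if r is not None and not math.isfinite(r):
                raise ValueError("non-finite ratio")
        if any(c < 0 for c in self.spectral_count):
            raise ValueError("negative spectral count")

    @property
    def cterm_residue(self) -> str:
        return self.peptide_seq[-1]

    @property
    def n_lys(self) -> int:
        return self.peptide_seq.count("K")

    @property
    def total_spectral_count(self) -> int:
        return int(sum(self.spectral_count))

    def quantified_ratios(self) -> list[float]:
        return [r for r in self.ratio_hl if r is not None]


@dataclass
class QCReport:
    """Labeling-efficiency QC against the >=0.98 / <0.06 thresholds."""

    frac_lys_dimethylated: float
    frac_cleaved_after_dimethyl_lys: float
    n_peptides: int
    n_lys: int
    lys_threshold: float = 0.98
    cleavage_threshold: float = 0.06
    pass_lys_labeling: bool = field(init=False)
    pass_cleavage: bool = field(init=False)

    def __post_init__(self):
        self.pass_lys_labeling = (
            self.frac_lys_dimethylated >= self.lys_threshold)
        self.pass_cleavage = (
            self.frac_cleaved_after_dimethyl_lys < self.cleavage_threshold)


def _parse_ratio(cell) -> float | None:
    if cell is None:
        return None
    s = str(cell).strip()
    if s == "" or s.lower() == "nan":
        return None
    return float(s)


def read_evidence_table(path: str | Path,
                        n_replicates: int = 3) -> list[PeptideEvidence]:
    """Read the evidence TSV into :class:`PeptideEvidence` records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    ratio_cols = [f"ratio_hl_rep{i}" for i in range(1, n_replicates + 1)]
    count_cols = [f"spectral_count_rep{i}" for i in range(1, n_replicates + 1)]
    required = {"peptide", "protein", "nterm_mod", "lys_mods",
                *ratio_cols, *count_cols}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"evidence table missing columns {sorted(missing)} "
            f"(design expects {n_replicates} replicates)")

    records = []
    for idx, row in df.iterrows():
        lys_mods = tuple(t for t in row["lys_mods"].split(";") if t)
        try:
            rec = PeptideEvidence(
                peptide_seq=row["peptide"],
                protein_acc=row["protein"],
                nterm_mod=row["nterm_mod"],
                lys_mods=lys_mods,
                ratio_hl=tuple(_parse_ratio(row[c]) for c in ratio_cols),
                spectral_count=tuple(
                    int(row[c] or 0) for c in count_cols),
                cleaved_after_dimethyl_lys=(
                    str(row.get("cleaved_after_dimethyl_lys", "False"))
                    .lower() in ("true", "1")),
            )
        except ValueError as exc:
            raise ValueError(f"evidence row {idx}: {exc}") from exc
        records.append(rec)
    return records


def write_evidence_table(records: list[PeptideEvidence],
                         path: str | Path) -> None:
    n_reps = len(records[0].ratio_hl) if records else 3
    rows = []
    for rec in records:
        row = {
            "peptide": rec.peptide_seq,
            "protein": rec.protein_acc,
            "nterm_mod": rec.nterm_mod,
            "lys_mods": ";".join(rec.lys_mods),
            "cleaved_after_dimethyl_lys": rec.cleaved_after_dimethyl_lys,
        }
        for i in range(n_reps):
            r = rec.ratio_hl[i]
            row[f"ratio_hl_rep{i + 1}"] = "" if r is None else f"{r:.6f}"
            row[f"spectral_count_rep{i + 1}"] = rec.spectral_count[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def convert_maxquant_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Rename native MaxQuant modificationSpecificPeptides columns.

    Converter stub: maps known native headers onto the internal dialect;
    replicate ratio/count columns must still be supplied by the caller's
    experiment design since MaxQuant names them per raw file.
    """
    return df.rename(columns={k: v for k, v in MAXQUANT_COLUMN_MAP.items()
                              if k in df.columns})


def labeling_qc(evidence: list[PeptideEvidence]) -> QCReport:
    """Fraction of Lys residues dimethylated, and of peptides produced by
    cleavage after a dimethylated Lys (both should be near-complete /
    near-zero for efficient duplex dimethyl labeling)."""
    if not evidence:
        raise ValueError("empty evidence list")
    n_lys = sum(len(rec.lys_mods) for rec in evidence)
    n_dimethyl = sum(
        sum(m in ("dimethyl_light", "dimethyl_heavy") for m in rec.lys_mods)
        for rec in evidence)
    n_cleaved = sum(rec.cleaved_after_dimethyl_lys for rec in evidence)
    return QCReport(
        frac_lys_dimethylated=n_dimethyl / n_lys if n_lys else 1.0,
        frac_cleaved_after_dimethyl_lys=n_cleaved / len(evidence),
        n_peptides=len(evidence),
        n_lys=n_lys,
    )


def recalc_protein_ratios_lys_only(
        evidence: list[PeptideEvidence]) -> dict[str, float | None]:
    """Protein-level log2 ratios from Lys-containing quantified peptides.

    For each protein, the ratio is the median over the per-peptide median
    log2 ratios of peptides that contain at least one Lys and carry a
    quantified ratio; proteins with no qualifying peptide map to ``None``
    (unquantified), never to zero.
    """
    by_protein: dict[str, list[float]] = {}
    for rec in evidence:
        by_protein.setdefault(rec.protein_acc, [])
        ratios = rec.quantified_ratios()
        if rec.n_lys >= 1 and ratios:
            by_protein[rec.protein_acc].append(float(np.median(ratios)))
    return {acc: (float(np.median(vals)) if vals else None)
            for acc, vals in by_protein.items()}
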