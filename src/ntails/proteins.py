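"""Protein sequences and positional feature annotation.

Coordinates are 1-based and inclusive throughout, following the UniProt
feature convention. A cleavage "before position p" lies between residues
p-1 (P1) and p (P1'); the mature protein produced by removal of a signal
peptide (SP), mitochondrial targeting signal (MTS) or propeptide (PP)
starts at feature end + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")
FEATURE_TYPES = ("SP", "MTS", "PP")
EVIDENCE_LEVELS = ("annotated", "predicted")

FEATURE_COLUMNS = ["accession", "feature_type", "start", "end",
                   "evidence", "is_mitochondrial"]


@dataclass(frozen=True)
class FeatureAnnotation:
    """One positional feature; mature protein starts at ``end + 1``."""

    feature_type: str
    start: int
    end: int
    evidence: str = "annotated"

    def __post_init__(self):
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(f"unknown evidence level {self.evidence!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid feature coordinates {self.start}..{self.end}")

    @property
    def mature_start(self) -> int:
        return self.end + 1


@dataclass
class ProteinRecord:
    accession: str
    sequence: str
    is_mitochondrial: bool = False
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residues {sorted(bad)}")
        for ft in FEATURE_TYPES[:2]:  # at most one SP and one MTS
            if sum(f.feature_type == ft for f in self.features) > 1:
                raise ValueError(f"{self.accession}: multiple {ft} features")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"{self.accession}: feature {f.feature_type} "
                    f"{f.start}..{f.end} coordinate out of range "
                    f"(length {len(self.sequence)})")

    def __len__(self) -> int:
        return len(self.sequence)


class ProteinDB:
    """Accession-keyed protein records with an expected-start index."""

    def __init__(self, records: Iterable[ProteinRecord] = ()):
        self._records: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.accession in self._records:
            raise ValueError(f"duplicate accession {record.accession!r}")
        self._records[record.accession] = record

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._records[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def accessions(self) -> list[str]:
        return list(self._records)

    def expected_index(self, window: int = 5) -> dict[str, dict[int, str]]:
        """Expected start positions with category tags, per accession."""
        return {acc: expected_start_positions(rec, window)
                for acc, rec in self._records.items()}


def expected_start_positions(protein: ProteinRecord,
                             window: int = 5) -> dict[int, str]:
    """Map of 1-based positions at which a peptide start is "expected".

    Positions 1 and 2 are tagged ``P1_2`` (translational start, with or
    without initiator-Met removal). For every SP/MTS/PP feature, positions
    within ``window`` residues of the mature start are tagged with the
    feature type. Tag precedence on collision: P1_2 > SP > MTS > PP.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    tags: dict[int, str] = {}
    # lowest precedence first; higher precedence overwrites
    for ftype in ("PP", "MTS", "SP"):
        for feat in protein.features:
            if feat.feature_type != ftype:
                continue
            ms = feat.mature_start
            lo = max(1, ms - window)
            hi = min(len(protein), ms + window)
            for pos in range(lo, hi + 1):
                tags[pos] = ftype
    tags[1] = "P1_2"
    if len(protein) >= 2:
        tags[2] = "P1_2"
    return tags


def get_window(protein: ProteinRecord, cleavage_before: int,
               n_left: int = 5, n_right: int = 5) -> str:
    """Cleavage window around a peptide start.

    Returns ``n_left`` residues N-terminal to the cleavage (P_n..P1) and
    ``n_right`` residues starting at the observed peptide start
    (P1'..P_n'), padded with ``-`` beyond the protein ends.
    """
    p = cleavage_before
    if not 1 <= p <= len(protein):
        raise ValueError(
            f"{protein.accession}: position {p} out of range")
    seq = protein.sequence
    left = "".join(
        seq[i - 1] if i >= 1 else "-" for i in range(p - n_left, p))
    right = "".join(
        seq[i - 1] if i <= len(seq) else "-" for i in range(p, p + n_right))
    return left + right


def load_protein_db(fasta_path: str | Path,
                    features_path: str | Path) -> ProteinDB:
    """Load a :class:`ProteinDB` from FASTA plus a feature TSV.

    The feature table must have columns ``accession, feature_type, start,
    end, evidence, is_mitochondrial``. Rows referencing unknown accessions
    or out-of-range coordinates are hard errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate accession {rec.id!r} in FASTA")
        sequences[rec.id] = str(rec.seq).upper()

    feats = pd.read_csv(features_path, sep="\t", dtype={"accession": str})
    missing_cols = set(FEATURE_COLUMNS) - set(feats.columns)
    if missing_cols:
        raise ValueError(f"feature table missing columns {sorted(missing_cols)}")

    per_acc: dict[str, list[FeatureAnnotation]] = {a: [] for a in sequences}
    mito: dict[str, bool] = {a: False for a in sequences}
    for idx, row in feats.iterrows():
        acc = row["accession"]
        if acc not in sequences:
            raise ValueError(
                f"feature row {idx}: unknown accession {acc!r}")
        mito[acc] = mito[acc] or bool(row["is_mitochondrial"])
        ftype = str(row["feature_type"])
        if ftype in ("", "nan", "none"):
            continue
        feat = FeatureAnnotation(ftype, int(row["start"]), int(row["end"]),
                                 str(row["evidence"]))
        if feat.end > len(sequences[acc]):
            raise ValueError(
                f"feature row {idx} ({acc} {ftype} {feat.start}..{feat.end}): "
                f"coordinate out of range")
        per_acc[acc].append(feat)

    return ProteinDB(
        ProteinRecord(acc, seq, mito[acc], per_acc[acc])
        for acc, seq in sequences.items())


def write_protein_db(db: ProteinDB, fasta_path: str | Path,
                     features_path: str | Path) -> None:
    """Round-trippable inverse of :func:`load_protein_db`."""
    records = [SeqRecord(Seq(rec.sequence), id=rec.accession, description="")
               for rec in db]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = []
    for rec in db:
        if not rec.features:
            # keep the mitochondrial flag even for feature-less proteins
            rows.append((rec.accession, "none", 0, 0, "annotated",
                         rec.is_mitochondrial))
        for f in rec.features:
            rows.append((rec.accession, f.feature_type, f.start, f.end,
                         f.evidence, rec.is_mitochondrial))
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(
        features_path, sep="\t", index=False)
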