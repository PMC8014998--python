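"""Terminome annotation: evidence filtering, peptide-to-position mapping,
five-category classification, collapse to unique termini, ragging detection.

Filters implement ArgC-consistency rules for negative-selection N-terminome
data: pyro-Glu peptides (sample-preparation artifacts after tryptic digest),
peptides without a C-terminal Arg, and dimethyl reported on an N-terminal
Pro (chemically implausible) are excluded before positional annotation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .evidence import PeptideEvidence
from .proteins import ProteinDB, expected_start_positions

CATEGORIES = ("P1_2", "SP", "MTS", "PP", "unexpected")
_PRECEDENCE = {"P1_2": 0, "SP": 1, "MTS": 2, "PP": 3}

REJECT_PYROGLU = "pyroglu"
REJECT_NO_CTERM_ARG = "no_cterm_arg"
REJECT_PRO_DIMETHYL = "pro_dimethyl"


@dataclass
class TerminusRecord:
    """A unique (protein, start) N terminus with positional category."""

    protein_acc: str
    start: int
    category: str
    is_mitochondrial: bool
    nterm_mod: str
    supporting_peptides: list[PeptideEvidence] = field(default_factory=list)
    ambiguous_mapping: bool = False

    @property
    def total_spectral_count(self) -> int:
        return sum(p.total_spectral_count for p in self.supporting_peptides)

    @property
    def peptide_count(self) -> int:
        return len(self.supporting_peptides)

    @property
    def is_expected(self) -> bool:
        return self.category != "unexpected"


@dataclass
class RaggingCluster:
    """A ladder of N termini at successive positions of one protein."""

    protein_acc: str
    member_positions: list[int]
    prevalence_counts: list[int]

    @property
    def most_prevalent_position(self) -> int:
        # ties break to the smallest (most N-terminal) position
        best = max(self.prevalence_counts)
        for pos, cnt in zip(self.member_positions, self.prevalence_counts):
            if cnt == best:
                return pos
        raise AssertionError("empty cluster")


def filter_evidence(evidence: list[PeptideEvidence],
                    allow_protein_cterm: bool = True,
                    db: ProteinDB | None = None
                    ) -> tuple[list[PeptideEvidence],
                               list[tuple[PeptideEvidence, str]]]:
    """Split evidence into kept peptides and (peptide, reason) rejections.

    A peptide whose C terminus coincides with its protein's C terminus is
    exempt from the C-terminal-Arg requirement when ``allow_protein_cterm``
    (ArgC digestion cannot produce Arg there); this exemption requires a
    ``db`` to locate the protein end.
    """
    kept, rejected = [], []
    for rec in evidence:
        if rec.nterm_mod in ("pyroglu_E", "pyroglu_Q"):
            rejected.append((rec, REJECT_PYROGLU))
            continue
        if rec.nterm_mod == "dimethyl" and rec.peptide_seq.startswith("P"):
            rejected.append((rec, REJECT_PRO_DIMETHYL))
            continue
        if rec.cterm_residue != "R":
            at_cterm = False
            if allow_protein_cterm and db is not None \
                    and rec.protein_acc in db:
                seq = db[rec.protein_acc].sequence
                at_cterm = seq.endswith(rec.peptide_seq)
            if not at_cterm:
                rejected.append((rec, REJECT_NO_CTERM_ARG))
                continue
        kept.append(rec)
    return kept, rejected


@dataclass(frozen=True)
class MappedPeptide:
    """A peptide placed on its protein with a positional category."""

    peptide: PeptideEvidence
    protein_acc: str
    start: int
    category: str
    ambiguous: bool


def map_and_classify(peptide: PeptideEvidence, db: ProteinDB,
                     window: int = 5) -> MappedPeptide:
    """Locate the peptide on its stated protein and classify the start.

    The start is the first 1-based occurrence of the peptide sequence;
    multiple occurrences set the ambiguity flag. Category precedence:
    P1_2 > SP > MTS > PP > unexpected (Met1-removed starts at position 2
    are P1_2).
    """
    if peptide.protein_acc not in db:
        raise ValueError(f"unknown protein {peptide.protein_acc!r}")
    protein = db[peptide.protein_acc]
    pos0 = protein.sequence.find(peptide.peptide_seq)
    if pos0 < 0:
        raise ValueError(
            f"peptide {peptide.peptide_seq!r} does not match protein "
            f"{peptide.protein_acc} (stale database?)")
    ambiguous = protein.sequence.find(peptide.peptide_seq, pos0 + 1) >= 0
    start = pos0 + 1
    tags = expected_start_positions(protein, window)
    category = tags.get(start, "unexpected")
    return MappedPeptide(peptide, peptide.protein_acc, start, category,
                         ambiguous)


def classify_terminus(db: ProteinDB, protein_acc: str, start: int,
                      window: int = 5) -> str:
    tags = expected_start_positions(db[protein_acc], window)
    return tags.get(start, "unexpected")


def collapse_to_unique(mapped: list[MappedPeptide],
                       db: ProteinDB) -> list[TerminusRecord]:
    """Collapse mapped peptides to unique (protein, start) termini.

    Peptides differing only in C terminus, Lys label state or N-terminal
    modification merge into one record; spectral counts sum over members
    and the record's ``nterm_mod`` is the modal observed modification.
    """
    groups: dict[tuple[str, int], list[MappedPeptide]] = {}
    for mp in mapped:
        groups.setdefault((mp.protein_acc, mp.start), []).append(mp)

    records = []
    for (acc, start), members in sorted(groups.items()):
        mods = Counter(m.peptide.nterm_mod for m in members)
        records.append(TerminusRecord(
            protein_acc=acc,
            start=start,
            category=members[0].category,
            is_mitochondrial=db[acc].is_mitochondrial,
            nterm_mod=mods.most_common(1)[0][0],
            supporting_peptides=[m.peptide for m in members],
            ambiguous_mapping=any(m.ambiguous for m in members),
        ))
    return records


def detect_ragging(termini: list[TerminusRecord],
                   gap_max: int = 2) -> list[RaggingCluster]:
    """Find ladders of >=2 termini with successive gaps <= ``gap_max``
    within one protein (progressive aminopeptidase trimming)."""
    by_protein: dict[str, list[TerminusRecord]] = {}
    for t in termini:
        by_protein.setdefault(t.protein_acc, []).append(t)

    clusters = []
    for acc in sorted(by_protein):
        recs = sorted(by_protein[acc], key=lambda t: t.start)
        run: list[TerminusRecord] = []
        for rec in recs + [None]:  # sentinel flushes the final run
            if run and (rec is None
                        or rec.start - run[-1].start > gap_max):
                if len(run) >= 2:
                    clusters.append(RaggingCluster(
                        protein_acc=acc,
                        member_positions=[t.start for t in run],
                        prevalence_counts=[t.total_spectral_count
                                           for t in run]))
                run = []
            if rec is not None:
                run.append(rec)
    return clusters


def annotate_terminome(evidence: list[PeptideEvidence], db: ProteinDB,
                       window: int = 5,
                       allow_protein_cterm: bool = True
                       ) -> tuple[list[TerminusRecord],
                                  list[tuple[PeptideEvidence, str]]]:
    """filter -> map/classify -> collapse, returning termini + rejections."""
    kept, rejected = filter_evidence(evidence, allow_protein_cterm, db)
    mapped = [map_and_classify(p, db, window) for p in kept]
    return collapse_to_unique(mapped, db), rejected


def category_counts(termini: list[TerminusRecord]) -> pd.DataFrame:
    """Per-category terminus counts split by mitochondrial annotation."""
    rows = [(t.category, t.is_mitochondrial) for t in termini]
    df = pd.DataFrame(rows, columns=["category", "is_mitochondrial"])
    out = (df.groupby(["category", "is_mitochondrial"], observed=True)
             .size().rename("n_termini").reset_index())
    return out


def termini_to_frame(termini: list[TerminusRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "accession": t.protein_acc,
        "start": t.start,
        "category": t.category,
        "is_mitochondrial": t.is_mitochondrial,
        "nterm_mod": t.nterm_mod,
        "spectral_count": t.total_spectral_count,
        "peptide_count": t.peptide_count,
        "ambiguity_flag": t.ambiguous_mapping,
    } for t in termini])
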