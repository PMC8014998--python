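"""Synthetic ground-truth data for every pipeline stage.

The generator emulates the statistical structure a duplex-dimethyl TAILS
experiment on mitochondria is assumed to have:

* mitochondrial proteins carry an N-terminal targeting signal (MTS) whose
  removal leaves Arg at P2 ("twin Arg") or, after one-residue
  aminopeptidase (ICP55-style) trimming of a Phe/Tyr/Leu, Arg at P3;
* mature N termini start mostly with stabilizing residues (Ser/Ala/Thr/
  Gly/Met) and show ragged +1/+2 satellites;
* unexpected (neo-) termini sit at uniform internal positions and carry a
  small global log2 shift between genotypes;
* a few substrate proteins contribute strongly accumulating termini and
  strongly depleted wild-type-specific cleavages whose P1 is enriched
  for Arg;
* observed replicate ratios are the truth plus log-normal noise with
  spectral-count-dependent missingness;
* the trapping screen is a 3-condition LFQ matrix with intensity-
  dependent (MNAR) missingness and spiked TRAP/interactor enrichment.

Randomness comes from seeded NumPy Generator substreams (one per
generated artifact, derived as ``default_rng([seed, k])``) with a fixed
draw order, so identical seeds give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

from ._constants import AMINO_ACIDS
from .evidence import PeptideEvidence, write_evidence_table
from .proteins import (FeatureAnnotation, ProteinDB, ProteinRecord,
                       write_protein_db)

_START_RESIDUES = ("S", "A", "T", "G", "M")
_START_PROBS = (0.30, 0.25, 0.15, 0.10, 0.10)  # remaining 0.10 uniform other
_ICP55_P1 = ("F", "Y", "L")


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the standard study conditions."""

    seed: int = 0
    n_proteins: int = 300
    frac_mitochondrial: float = 0.7
    mature_len_range: tuple[int, int] = (100, 400)
    mts_len_mean: float = 35.0
    mts_len_sd: float = 10.0
    mts_len_bounds: tuple[int, int] = (15, 80)
    # MTS cleavage motif mix: Arg at P2, Arg at P3 (ICP55-trimmed), none
    p_r_at_p2: float = 0.6
    p_r_at_p3: float = 0.3
    icp55_trim_prob: float = 0.8
    ragging_prob: float = 0.5
    neo_termini_rate: float = 2.0
    frac_changed_proteins: float = 0.15
    changed_effect_sd: float = 0.8
    global_shift_delta: float = 0.32
    n_substrates: int = 10
    n_accum_termini_per_substrate: int = 2
    n_depleted_termini_per_substrate: int = 2
    substrate_accumulation: tuple[float, float] = (2.0, 0.3)
    wt_specific_cleavage: tuple[float, float] = (-2.0, 0.3)
    p1_arg_prob: float = 0.7
    terminus_sd: float = 0.25
    ratio_noise_sd: float = 0.3
    n_replicates: int = 3
    sc_lambda: dict = field(default_factory=lambda: {
        "expected": 6.0, "substrate": 4.0, "neo": 2.0})
    n_artifact_peptides: int = 15
    # trapping screen
    trap_n_null: int = 185
    trap_n_substrates: int = 10
    trap_substrate_shift: float = 3.0
    trap_n_interactors: int = 5
    trap_interactor_shift: float = 2.5
    trap_baseline: tuple[float, float] = (25.0, 2.0)
    trap_rep_sd: float = 0.4
    trap_mnar_quantile: float = 0.15
    trap_mnar_prob: float = 0.8


def _draw_mts_len(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.mts_len_bounds
    a = (lo - cfg.mts_len_mean) / cfg.mts_len_sd
    b = (hi - cfg.mts_len_mean) / cfg.mts_len_sd
    val = _sps.truncnorm.rvs(a, b, loc=cfg.mts_len_mean,
                             scale=cfg.mts_len_sd, random_state=rng)
    return int(round(val))


def _draw_start_residue(rng: np.random.Generator) -> str:
    u = rng.random()
    acc = 0.0
    for aa, p in zip(_START_RESIDUES, _START_PROBS):
        acc += p
        if u < acc:
            return aa
    others = [aa for aa in AMINO_ACIDS if aa not in _START_RESIDUES]
    return others[rng.integers(len(others))]


def generate_protein_db(cfg: SyntheticConfig
                        ) -> tuple[ProteinDB, pd.DataFrame]:
    """Synthetic proteome with planted MTS cleavage motifs.

    Sequences are i.i.d. uniform over the 20 residues except at planted
    positions: the mature start residue follows the stabilizing-residue
    mix, and Arg is planted at P2 or P3 of the annotated mature start
    (with an ICP55-style Phe/Tyr/Leu at P1 for the P3 case).

    Returns the in-memory DB and a per-protein ground-truth table.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    aas = np.array(list(AMINO_ACIDS))
    n_mito = int(round(cfg.n_proteins * cfg.frac_mitochondrial))
    records, truth = [], []
    for i in range(cfg.n_proteins):
        acc = f"SYN{i:04d}"
        is_mito = i < n_mito
        mature_len = int(rng.integers(*cfg.mature_len_range))
        if is_mito:
            mts_len = _draw_mts_len(cfg, rng)
            seq = list(rng.choice(aas, size=mts_len + mature_len))
            ms = mts_len + 1  # mature start, 1-based
            seq[ms - 1] = _draw_start_residue(rng)
            u = rng.random()
            if u < cfg.p_r_at_p2:
                motif = "R_at_P2"
                seq[ms - 3] = "R"  # P2 = ms - 2 (1-based)
            elif u < cfg.p_r_at_p2 + cfg.p_r_at_p3:
                motif = "R_at_P3"
                seq[ms - 4] = "R"
                if rng.random() < cfg.icp55_trim_prob:
                    seq[ms - 2] = _ICP55_P1[rng.integers(len(_ICP55_P1))]
            else:
                motif = "none"
            features = [FeatureAnnotation("MTS", 1, mts_len, "annotated")]
        else:
            mts_len, ms, motif = 0, 1, "none"
            seq = list(rng.choice(aas, size=mature_len))
            features = []
        records.append(ProteinRecord(acc, "".join(seq), is_mito, features))
        truth.append({"accession": acc, "is_mitochondrial": is_mito,
                      "mts_len": mts_len, "mature_start": ms,
                      "motif": motif})
    return ProteinDB(records), pd.DataFrame(truth)


@dataclass
class TailsDataset:
    evidence: list[PeptideEvidence]
    protein_lfq: pd.DataFrame
    terminus_truth: pd.DataFrame
    protein_truth: pd.DataFrame


def _peptide_from(seq: str, start: int, min_len: int = 6) -> str:
    """ArgC-style peptide: runs to the first Arg at length >= min_len, or
    to the protein C terminus when no Arg follows."""
    sub = seq[start - 1:]
    for j in range(min_len - 1, len(sub)):
        if sub[j] == "R":
            return sub[:j + 1]
    return sub


def generate_tails_experiment(cfg: SyntheticConfig, db: ProteinDB,
                              db_truth: pd.DataFrame) -> TailsDataset:
    """Evidence table + protein LFQ table with per-terminus ground truth.

    Draw order (fixed): protein effects -> substrate assignment -> termini
    (expected, ragging, neo, substrate) -> replicate noise -> missingness
    -> spectral counts -> artifact peptides.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    info = db_truth.set_index("accession")
    mito_accs = [a for a in db.accessions if info.loc[a, "is_mitochondrial"]]
    other_accs = [a for a in db.accessions
                  if not info.loc[a, "is_mitochondrial"]]

    # protein effects and change flags
    effects: dict[str, float] = {}
    changed: dict[str, bool] = {}
    for acc in db.accessions:
        is_changed = rng.random() < cfg.frac_changed_proteins
        effects[acc] = (float(rng.normal(0.0, cfg.changed_effect_sd))
                        if is_changed else 0.0)
        changed[acc] = is_changed
    unchanged_mito = [a for a in mito_accs if not changed[a]]
    subs_idx = rng.choice(len(unchanged_mito),
                          size=min(cfg.n_substrates, len(unchanged_mito)),
                          replace=False)
    substrates = [unchanged_mito[i] for i in sorted(subs_idx)]

    termini: list[dict] = []  # planned termini before noise

    def plan(acc, start, true_log2, category, tier, role,
             p1_is_arg=False, nterm_mod="dimethyl"):
        termini.append(dict(accession=acc, start=start,
                            true_log2=true_log2, true_category=category,
                            tier=tier, role=role, p1_is_arg=p1_is_arg,
                            nterm_mod=nterm_mod))

    for acc in mito_accs:
        seq = db[acc].sequence
        ms = int(info.loc[acc, "mature_start"])
        eff = effects[acc]
        plan(acc, ms, eff + rng.normal(0.0, cfg.terminus_sd),
             "MTS", "expected", "expected")
        if rng.random() < cfg.ragging_prob:
            extra = min(int(rng.geometric(0.5)), 3)
            for d in range(1, extra + 1):
                plan(acc, ms + d, eff + rng.normal(0.0, cfg.terminus_sd),
                     "MTS", "expected", "ragging")
        n_neo = rng.poisson(cfg.neo_termini_rate)
        lo, hi = ms + 6, len(seq) - 10
        for _ in range(int(n_neo)):
            if hi <= lo:
                break
            pos = int(rng.integers(lo, hi))
            plan(acc, pos,
                 eff + cfg.global_shift_delta
                 + rng.normal(0.0, cfg.terminus_sd),
                 "unexpected", "neo", "neo")

    for acc in substrates:
        seq = db[acc].sequence
        ms = int(info.loc[acc, "mature_start"])
        lo, hi = ms + 6, len(seq) - 10
        if hi <= lo:
            continue
        for _ in range(cfg.n_accum_termini_per_substrate):
            pos = int(rng.integers(lo, hi))
            mu, sd = cfg.substrate_accumulation
            plan(acc, pos, float(rng.normal(mu, sd)),
                 "unexpected", "substrate", "substrate_accumulating")
        arg_positions = [p for p in range(lo, hi)
                         if seq[p - 2] == "R"]  # P1 residue is seq[p-2]
        for _ in range(cfg.n_depleted_termini_per_substrate):
            use_arg = arg_positions and rng.random() < cfg.p1_arg_prob
            pos = (int(arg_positions[rng.integers(len(arg_positions))])
                   if use_arg else int(rng.integers(lo, hi)))
            mu, sd = cfg.wt_specific_cleavage
            plan(acc, pos, float(rng.normal(mu, sd)),
                 "unexpected", "substrate", "substrate_depleted",
                 p1_is_arg=db[acc].sequence[pos - 2] == "R")

    # contaminant translational starts on non-mitochondrial proteins
    for acc in other_accs:
        if rng.random() < 0.3:
            mod = "acetyl" if rng.random() < 0.4 else "dimethyl"
            plan(acc, 1, effects[acc] + rng.normal(0.0, 0.5),
                 "P1_2", "expected", "contaminant", nterm_mod=mod)

    # de-duplicate planned positions within a protein
    seen: set[tuple[str, int]] = set()
    unique_termini = []
    for t in termini:
        key = (t["accession"], t["start"])
        if key in seen:
            continue
        seen.add(key)
        unique_termini.append(t)

    evidence: list[PeptideEvidence] = []
    truth_rows = []
    for t in unique_termini:
        seq = db[t["accession"]].sequence
        pep = _peptide_from(seq, t["start"])
        lam = cfg.sc_lambda[t["tier"]]
        counts = tuple(int(max(1, rng.poisson(lam)))
                       for _ in range(cfg.n_replicates))
        ratios = []
        for r in range(cfg.n_replicates):
            val = t["true_log2"] + rng.normal(0.0, cfg.ratio_noise_sd)
            p_miss = 0.35 * np.exp(-counts[r] / 4.0) + 0.05
            ratios.append(None if rng.random() < p_miss else float(val))
        lys_mods = tuple(
            ("dimethyl_heavy" if rng.random() < 0.5 else "dimethyl_light")
            if rng.random() < 0.99 else "unmodified"
            for _ in range(pep.count("K")))
        mod = t["nterm_mod"]
        if pep.startswith("P") and mod == "dimethyl":
            mod = "free"  # dimethylation does not occur on N-terminal Pro
        evidence.append(PeptideEvidence(
            peptide_seq=pep, protein_acc=t["accession"],
            nterm_mod=mod, lys_mods=lys_mods,
            ratio_hl=tuple(ratios), spectral_count=counts,
            cleaved_after_dimethyl_lys=bool(rng.random() < 0.03)))
        truth_rows.append({
            "accession": t["accession"], "start": t["start"],
            "peptide": pep, "true_category": t["true_category"],
            "true_log2": t["true_log2"], "role": t["role"],
            "p1_is_arg": t["p1_is_arg"]})

    # artifact peptides exercising the exclusion filters
    artifact_kinds = ["pyroglu", "no_cterm_arg", "pro_dimethyl"]
    for i in range(cfg.n_artifact_peptides):
        acc = mito_accs[int(rng.integers(len(mito_accs)))]
        seq = db[acc].sequence
        pos = int(rng.integers(5, len(seq) - 25))
        kind = artifact_kinds[i % 3]
        pep = _peptide_from(seq, pos)
        mod = "dimethyl"
        if kind == "pyroglu":
            mod = "pyroglu_Q"
        elif kind == "no_cterm_arg":
            pep = pep.rstrip("R") or pep[:-1]
            if pep.endswith("R"):
                pep = pep[:-1]
            if not pep or seq.endswith(pep):
                continue
        else:
            idx = seq.find("P", 5, len(seq) - 25)
            if idx < 0:
                continue
            pep = _peptide_from(seq, idx + 1)
        evidence.append(PeptideEvidence(
            peptide_seq=pep, protein_acc=acc, nterm_mod=mod,
            lys_mods=tuple("dimethyl_light" for _ in range(pep.count("K"))),
            ratio_hl=tuple([None] * cfg.n_replicates),
            spectral_count=tuple([1] * cfg.n_replicates)))

    lfq_rows = []
    for acc in db.accessions:
        lfq_rows.append({
            "accession": acc,
            "log2_ratio": effects[acc] + float(rng.normal(0.0, 0.15)),
            "significant_flag": bool(changed[acc] or acc in substrates)})

    protein_truth = db_truth.copy()
    protein_truth["effect"] = [effects[a] for a in protein_truth["accession"]]
    protein_truth["changed"] = [changed[a] for a in protein_truth["accession"]]
    protein_truth["substrate"] = [a in substrates
                                  for a in protein_truth["accession"]]
    return TailsDataset(evidence, pd.DataFrame(lfq_rows),
                        pd.DataFrame(truth_rows), protein_truth)


def generate_trap_experiment(cfg: SyntheticConfig
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3-condition x 3-replicate LFQ matrix with spiked enrichment.

    Substrate proteins are shifted in TRAP only, interactors in both WT
    and TRAP; cells in the lowest ``trap_mnar_quantile`` of the full
    intensity distribution go missing with probability ``trap_mnar_prob``.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    n = cfg.trap_n_null + cfg.trap_n_substrates + cfg.trap_n_interactors
    classes = (["null"] * cfg.trap_n_null
               + ["substrate"] * cfg.trap_n_substrates
               + ["interactor"] * cfg.trap_n_interactors)
    mu0, sd0 = cfg.trap_baseline
    conds = ("NEG", "WT", "TRAP")
    rows, truth = [], []
    values = np.empty((n, 9))
    for i in range(n):
        base = rng.normal(mu0, sd0)
        shift = {"NEG": 0.0, "WT": 0.0, "TRAP": 0.0}
        if classes[i] == "substrate":
            shift["TRAP"] = cfg.trap_substrate_shift
        elif classes[i] == "interactor":
            shift["WT"] = cfg.trap_interactor_shift
            shift["TRAP"] = cfg.trap_interactor_shift
        vals = [base + shift[c] + rng.normal(0.0, cfg.trap_rep_sd)
                for c in conds for _ in range(cfg.n_replicates)]
        values[i] = vals
        is_mito = classes[i] != "null" or rng.random() < 0.8
        rows.append({"accession": f"TRP{i:04d}",
                     "is_mitochondrial": is_mito})
        truth.append({"accession": f"TRP{i:04d}", "class": classes[i]})
    threshold = np.quantile(values, cfg.trap_mnar_quantile)
    cols = [f"{c}_{r}" for c in conds for r in range(1, cfg.n_replicates + 1)]
    for i, row in enumerate(rows):
        for j, col in enumerate(cols):
            v = values[i, j]
            if v < threshold and rng.random() < cfg.trap_mnar_prob:
                row[col] = np.nan
            else:
                row[col] = round(v, 6)
    matrix = pd.DataFrame(rows).set_index("accession")
    return matrix, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# presets and file emission

PRESETS = ("tails-default", "trap-default", "null")


def preset_config(preset: str, seed: int = 0) -> SyntheticConfig:
    cfg = SyntheticConfig(seed=seed)
    if preset == "null":
        cfg = replace(cfg, global_shift_delta=0.0, n_substrates=0,
                      trap_n_substrates=0, trap_n_interactors=0)
    elif preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    return cfg


def write_tails_files(db: ProteinDB, dataset: TailsDataset,
                      outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "features": outdir / "features.tsv",
        "evidence": outdir / "evidence.tsv",
        "protein_lfq": outdir / "protein_lfq.tsv",
        "terminus_truth": outdir / "ground_truth_termini.tsv",
        "protein_truth": outdir / "ground_truth_proteins.tsv",
    }
    write_protein_db(db, paths["fasta"], paths["features"])
    write_evidence_table(dataset.evidence, paths["evidence"])
    dataset.protein_lfq.to_csv(paths["protein_lfq"], sep="\t", index=False,
                               float_format="%.6f")
    dataset.terminus_truth.to_csv(paths["terminus_truth"], sep="\t",
                                  index=False, float_format="%.6f")
    dataset.protein_truth.to_csv(paths["protein_truth"], sep="\t",
                                 index=False, float_format="%.6f")
    return paths


def write_trap_files(matrix: pd.DataFrame, truth: pd.DataFrame,
                     outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_groups": outdir / "protein_groups.tsv",
        "trap_truth": outdir / "ground_truth_trap.tsv",
    }
    matrix.to_csv(paths["protein_groups"], sep="\t", float_format="%.6f")
    truth.to_csv(paths["trap_truth"], sep="\t", index=False)
    return paths


def generate_preset(preset: str, seed: int,
                    outdir: str | Path) -> dict[str, Path]:
    """Emit all files of a preset into ``outdir``; byte-stable per seed."""
    cfg = preset_config(preset, seed)
    paths: dict[str, Path] = {}
    if preset in ("tails-default", "null"):
        db, db_truth = generate_protein_db(cfg)
        dataset = generate_tails_experiment(cfg, db, db_truth)
        paths.update(write_tails_files(db, dataset, outdir))
    if preset in ("trap-default", "null"):
        matrix, truth = generate_trap_experiment(cfg)
        paths.update(write_trap_files(matrix, truth, outdir))
    return paths
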