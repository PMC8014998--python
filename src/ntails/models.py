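"""Analysis objects tying the pipeline stages together.

Two model classes follow the familiar model/results pattern:
:class:`TailsAnalysis` (terminome annotation + quantification + cleavage
logos) and :class:`TrapScreen` (impute / ANOVA / Tukey / classify). Each
is constructed from data, ``fit()`` runs the analysis and returns a
results object carrying the tables, statistics and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import logo as logo_mod
from . import quant, terminome, trap
from .evidence import PeptideEvidence, labeling_qc, read_evidence_table
from .proteins import ProteinDB, load_protein_db


@dataclass
class TailsConfig:
    window: int = 5
    min_reps: int = 2
    n_replicates: int = 3
    cutoff_k: float = 1.5
    fixed_cutoff: float | None = None  # overrides the IQR-derived bounds
    logo_n_left: int = 5
    logo_n_right: int = 5
    logo_alpha: float = 0.05
    logo_scope: str = "mitochondrial_only"
    gap_max: int = 2
    allow_protein_cterm: bool = True
    mitochondrial_only: bool = True


class TailsAnalysis:
    """Differential N-terminome analysis of a duplex-labeled experiment.

    Parameters
    ----------
    evidence : list of PeptideEvidence
    db : ProteinDB
    protein_lfq : DataFrame with columns accession, log2_ratio,
        significant_flag — the independent protein-level quantification
        used for the cutoff reference set and the correlation analysis.
    """

    def __init__(self, evidence: list[PeptideEvidence], db: ProteinDB,
                 protein_lfq: pd.DataFrame | None = None,
                 config: TailsConfig | None = None):
        self.evidence = evidence
        self.db = db
        self.protein_lfq = protein_lfq
        self.config = config or TailsConfig()

    @classmethod
    def from_paths(cls, fasta, features, evidence_path, lfq_path=None,
                   config: TailsConfig | None = None) -> "TailsAnalysis":
        config = config or TailsConfig()
        db = load_protein_db(fasta, features)
        evidence = read_evidence_table(evidence_path, config.n_replicates)
        lfq = pd.read_csv(lfq_path, sep="\t") if lfq_path else None
        return cls(evidence, db, lfq, config)

    def fit(self) -> "TailsResults":
        cfg = self.config
        qc = labeling_qc(self.evidence)
        termini, rejected = terminome.annotate_terminome(
            self.evidence, self.db, cfg.window, cfg.allow_protein_cterm)
        all_termini = termini
        if cfg.mitochondrial_only:
            termini = [t for t in termini if t.is_mitochondrial]

        quantified = quant.quantify_termini(termini, cfg.n_replicates)
        quant.normalize_ratios(quantified, cfg.n_replicates)
        quant.aggregate_replicates(quantified, cfg.min_reps,
                                   cfg.n_replicates)
        usable = [qt for qt in quantified
                  if qt.diff_call != "not_quantified"]

        expected_vals = [qt.mean_norm_log2 for qt in usable
                         if qt.terminus.is_expected]
        unexpected_vals = [qt.mean_norm_log2 for qt in usable
                           if not qt.terminus.is_expected]
        comparison = None
        if expected_vals and unexpected_vals:
            comparison = quant.compare_class_distributions(
                expected_vals, unexpected_vals)

        bounds = self._derive_bounds(usable)
        _, call_table = quant.call_differential_termini(quantified, bounds)

        correlations = None
        if self.protein_lfq is not None:
            correlations = quant.correlate_with_protein_abundance(
                quantified, self.protein_lfq)

        ragging = terminome.detect_ragging(termini, cfg.gap_max)
        reference = logo_mod.reference_frequencies(self.db, cfg.logo_scope)
        windows = logo_mod.extract_cleavage_windows(
            termini, self.db, cfg.logo_n_left, cfg.logo_n_right)
        logos = self._logos(quantified, bounds, reference)

        return TailsResults(
            model=self, qc=qc, termini=all_termini,
            mito_termini=termini, rejected=rejected,
            quantified=quantified, comparison=comparison, bounds=bounds,
            call_table=call_table, correlations=correlations,
            ragging=ragging, windows=windows,
            reference_frequencies=reference, logos=logos)

    def _derive_bounds(self, usable) -> quant.CutoffBounds:
        cfg = self.config
        if cfg.fixed_cutoff is not None:
            return quant.fixed_cutoff(cfg.fixed_cutoff)
        reference = self._reference_values(usable)
        if len(reference) >= 4:
            return quant.derive_cutoff(reference, cfg.cutoff_k)
        return quant.fixed_cutoff(0.9)

    def _reference_values(self, usable) -> list[float]:
        """Normalized ratios of termini on abundance-unchanged proteins."""
        if self.protein_lfq is None:
            return []
        unchanged = set(
            self.protein_lfq.loc[~self.protein_lfq["significant_flag"]
                                 .astype(bool), "accession"])
        return [qt.mean_norm_log2 for qt in usable
                if qt.terminus.protein_acc in unchanged]

    def _logos(self, quantified, bounds, reference) -> dict[str, pd.DataFrame]:
        cfg = self.config
        out: dict[str, pd.DataFrame] = {}
        groups = {
            "expected_mts": [qt.terminus for qt in quantified
                             if qt.terminus.category == "MTS"],
            "accumulating_neo": [qt.terminus for qt in quantified
                                 if qt.diff_call == "accumulating"
                                 and not qt.terminus.is_expected],
            "depleted_neo": [qt.terminus for qt in quantified
                             if qt.diff_call == "depleted"
                             and not qt.terminus.is_expected],
        }
        for name, group in groups.items():
            if not group:
                continue
            windows = logo_mod.extract_cleavage_windows(
                group, self.db, cfg.logo_n_left, cfg.logo_n_right)
            out[name] = logo_mod.position_enrichment(
                windows, reference, cfg.logo_alpha)
        return out


class TailsResults:
    """Results of :meth:`TailsAnalysis.fit`."""

    def __init__(self, model, qc, termini, mito_termini, rejected,
                 quantified, comparison, bounds, call_table, correlations,
                 ragging, windows, reference_frequencies, logos):
        self.model = model
        self.qc = qc
        self.termini = termini
        self.mito_termini = mito_termini
        self.rejected = rejected
        self.quantified = quantified
        self.comparison = comparison
        self.bounds = bounds
        self.call_table = call_table
        self.correlations = correlations
        self.ragging = ragging
        self.windows = windows
        self.reference_frequencies = reference_frequencies
        self.logos = logos

    @property
    def n_unique_termini(self) -> int:
        return len(self.termini)

    def termini_frame(self) -> pd.DataFrame:
        df = terminome.termini_to_frame(self.termini)
        quantmap = {(qt.terminus.protein_acc, qt.terminus.start): qt
                    for qt in self.quantified}
        df["mean_norm_log2"] = [
            (quantmap[k].mean_norm_log2
             if (k := (row.accession, row.start)) in quantmap else None)
            for row in df.itertuples()]
        df["n_quantified"] = [
            (quantmap[k].n_quantified
             if (k := (row.accession, row.start)) in quantmap else 0)
            for row in df.itertuples()]
        df["diff_call"] = [
            (quantmap[k].diff_call
             if (k := (row.accession, row.start)) in quantmap
             else "not_quantified")
            for row in df.itertuples()]
        return df

    def summary_dict(self) -> dict:
        d = {
            "n_peptides": len(self.model.evidence),
            "n_rejected": len(self.rejected),
            "n_unique_termini": len(self.termini),
            "n_mitochondrial_termini": len(self.mito_termini),
            "n_quantified": sum(qt.diff_call != "not_quantified"
                                for qt in self.quantified),
            "qc": {"frac_lys_dimethylated": self.qc.frac_lys_dimethylated,
                   "frac_cleaved_after_dimethyl_lys":
                       self.qc.frac_cleaved_after_dimethyl_lys,
                   "pass_lys_labeling": self.qc.pass_lys_labeling,
                   "pass_cleavage": self.qc.pass_cleavage},
            "cutoff": {"lower": self.bounds.lower,
                       "upper": self.bounds.upper,
                       "method": self.bounds.method,
                       "reference_n": self.bounds.reference_n},
            "call_table": {cls: {call: int(self.call_table.loc[cls, call])
                                 for call in self.call_table.columns}
                           for cls in self.call_table.index},
            "n_ragging_clusters": len(self.ragging),
        }
        if self.comparison is not None:
            d["class_comparison"] = {
                "n_expected": self.comparison.n_expected,
                "n_unexpected": self.comparison.n_unexpected,
                "delta_median": self.comparison.delta_median,
                "mw_u": self.comparison.mw_u,
                "p_two_sided": self.comparison.p_two_sided,
            }
        if self.correlations is not None:
            d["correlations"] = self.correlations
        return d

    def summary(self) -> str:
        d = self.summary_dict()
        lines = [
            "TAILS terminome analysis",
            "=" * 56,
            f"peptides in               {d['n_peptides']:>6}",
            f"rejected by filters       {d['n_rejected']:>6}",
            f"unique termini            {d['n_unique_termini']:>6}",
            f"  mitochondrial           {d['n_mitochondrial_termini']:>6}",
            f"quantified (>= {self.model.config.min_reps}/"
            f"{self.model.config.n_replicates} reps)   {d['n_quantified']:>6}",
            f"Lys labeling efficiency   {self.qc.frac_lys_dimethylated:>9.3f}"
            f"  (pass: {self.qc.pass_lys_labeling})",
            f"cutoff bounds             [{self.bounds.lower:+.3f}, "
            f"{self.bounds.upper:+.3f}]  ({self.bounds.method})",
        ]
        if self.comparison is not None:
            lines += [
                f"delta median (unexp-exp)  "
                f"{self.comparison.delta_median:>9.3f}",
                f"Mann-Whitney p            "
                f"{self.comparison.p_two_sided:>12.3g}",
            ]
        lines.append("differential calls (class x call):")
        lines.append(self.call_table.to_string())
        if self.correlations:
            for cls, cor in self.correlations.items():
                r = cor["pearson_r"]
                rtxt = "n/a" if r is None else f"{r:.3f}"
                lines.append(
                    f"Pearson r vs protein LFQ ({cls}, n={cor['n']}): {rtxt}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.termini_frame().to_csv(outdir / "termini.tsv", sep="\t",
                                    index=False, float_format="%.6f")
        terminome.category_counts(self.termini).to_csv(
            outdir / "category_counts.tsv", sep="\t", index=False)
        for name, df in self.logos.items():
            df.to_csv(outdir / f"logo_{name}.tsv", sep="\t", index=False,
                      float_format="%.6g")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)


@dataclass
class TrapConfig:
    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0
    q_thresh: float = 0.05
    p_thresh: float = 0.05
    n_replicates: int = 3


class TrapScreen:
    """Substrate-trapping enrichment screen over NEG/WT/TRAP LFQ data."""

    def __init__(self, matrix: pd.DataFrame,
                 config: TrapConfig | None = None):
        self.config = config or TrapConfig()
        trap.validate_matrix(matrix, self.config.n_replicates)
        self.matrix = matrix

    @classmethod
    def from_path(cls, path, config: TrapConfig | None = None) -> "TrapScreen":
        df = pd.read_csv(path, sep="\t").set_index("accession")
        return cls(df, config)

    def fit(self, seed: int | None = None) -> "TrapResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        imputed, mask = trap.impute_missing(
            self.matrix, cfg.width, cfg.downshift, seed, cfg.n_replicates)
        anova = trap.anova_bh(imputed, cfg.n_replicates)
        significant = anova.index[anova["q"] < cfg.q_thresh]
        tukey = trap.tukey_posthoc(imputed, significant, cfg.n_replicates)
        means_obs = trap.group_means(self.matrix, None, cfg.n_replicates)
        means_imp = trap.group_means(imputed, None, cfg.n_replicates)
        # observed-only means where available, imputed means as fallback
        means = means_obs.where(means_obs.notna(), means_imp)
        hits = trap.classify_hits(anova, tukey, means,
                                  cfg.q_thresh, cfg.p_thresh)
        pa = trap.presence_absence(self.matrix,
                                   n_replicates=cfg.n_replicates)
        return TrapResults(self, imputed, mask, anova, tukey, hits, pa)

    def classification_stability(self, seeds) -> pd.DataFrame:
        """Multi-imputation sensitivity: hit class per protein per seed."""
        frames = {}
        for s in seeds:
            frames[s] = self.fit(seed=s).hits["hit_class"]
        return pd.DataFrame(frames)


class TrapResults:
    """Results of :meth:`TrapScreen.fit`."""

    def __init__(self, model, imputed, mask, anova, tukey, hits,
                 presence_absence):
        self.model = model
        self.imputed = imputed
        self.imputation_mask = mask
        self.anova = anova
        self.tukey = tukey
        self.hits = hits
        self.presence_absence = presence_absence

    def class_counts(self) -> dict[str, int]:
        counts = self.hits["hit_class"].value_counts().to_dict()
        return {cls: int(counts.get(cls, 0)) for cls in trap.HIT_CLASSES}

    def scatter_frame(self) -> pd.DataFrame:
        """log2(TRAP/NEG) vs log2(WT/NEG) with hit classes, for plotting."""
        return self.hits[["log2_TRAP_NEG", "log2_WT_NEG",
                          "hit_class"]].copy()

    def summary(self) -> str:
        counts = self.class_counts()
        lines = [
            "Substrate-trapping screen",
            "=" * 44,
            f"proteins tested           {len(self.anova):>6}",
            f"ANOVA q < {self.model.config.q_thresh:<4}          "
            f"{int((self.anova['q'] < self.model.config.q_thresh).sum()):>6}",
        ]
        for cls in trap.HIT_CLASSES:
            lines.append(f"{cls:<25} {counts[cls]:>6}")
        lines.append(
            f"presence/absence flagged  {len(self.presence_absence):>6}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.hits.to_csv(outdir / "trap_hits.tsv", sep="\t",
                         float_format="%.6g")
        self.presence_absence.to_csv(outdir / "presence_absence.tsv",
                                     sep="\t")
        self.scatter_frame().to_csv(outdir / "trap_scatter.tsv", sep="\t",
                                    float_format="%.6g")
        with open(outdir / "trap_summary.json", "w") as fh:
            json.dump({"class_counts": self.class_counts(),
                       "n_tested": len(self.anova)}, fh, indent=2,
                      sort_keys=True)
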