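"""Cleavage-window sequence analysis.

Windows follow Schechter-Berger nomenclature: P1 is the residue
immediately N-terminal to the scissile bond, P1' the first residue of the
observed N-terminal peptide. Positional enrichment is percent difference
of the observed residue frequency against a reference frequency model
(whole-proteome composition by default), with an exact two-sided binomial
test per (position, residue) cell — deterministic, unlike logo tools that
test against sampled reference sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._constants import AMINO_ACIDS, NEND_RULE_CLASS
from .proteins import ProteinDB, get_window
from .terminome import TerminusRecord


@dataclass(frozen=True)
class CleavageWindow:
    protein_acc: str
    cleavage_before: int
    residues: str  # P_n..P1 then P1'..P_n', '-' padded
    n_left: int
    n_right: int

    def at(self, label: str) -> str:
        return self.residues[position_index(label, self.n_left, self.n_right)]


def position_labels(n_left: int, n_right: int) -> list[str]:
    """P<n>..P1, P1'..P<n>' labels for a window."""
    return ([f"P{i}" for i in range(n_left, 0, -1)]
            + [f"P{i}'" for i in range(1, n_right + 1)])


def position_index(label: str, n_left: int, n_right: int) -> int:
    labels = position_labels(n_left, n_right)
    if label not in labels:
        raise ValueError(f"invalid position label {label!r} for a "
                         f"{n_left}+{n_right} window")
    return labels.index(label)


def extract_cleavage_windows(termini: list[TerminusRecord], db: ProteinDB,
                             n_left: int = 5, n_right: int = 5,
                             dedupe: bool = True) -> list[CleavageWindow]:
    """One cleavage window per (protein, start), via the annotated DB."""
    seen: set[tuple[str, int]] = set()
    out = []
    for t in termini:
        key = (t.protein_acc, t.start)
        if dedupe and key in seen:
            continue
        seen.add(key)
        out.append(CleavageWindow(
            t.protein_acc, t.start,
            get_window(db[t.protein_acc], t.start, n_left, n_right),
            n_left, n_right))
    return out


def reference_frequencies(db: ProteinDB,
                          scope: str = "mitochondrial_only"
                          ) -> dict[str, float]:
    """Residue frequencies over all residues of the in-scope proteome."""
    if scope not in ("all_proteins", "mitochondrial_only"):
        raise ValueError(f"unknown scope {scope!r}")
    counts: Counter[str] = Counter()
    for rec in db:
        if scope == "mitochondrial_only" and not rec.is_mitochondrial:
            continue
        counts.update(rec.sequence)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no residues in scope {scope!r}")
    return {aa: counts.get(aa, 0) / total for aa in sorted(set(counts) | set(AMINO_ACIDS))}


def binomial_two_sided(k: int, n: int, p: float) -> float:
    """Exact two-sided binomial p by doubling the smaller tail, capped at 1."""
    lo = stats.binom.cdf(k, n, p)
    hi = stats.binom.sf(k - 1, n, p)
    return float(min(1.0, 2 * min(lo, hi)))


def position_enrichment(windows: list[CleavageWindow],
                        reference: dict[str, float],
                        alpha: float = 0.05,
                        bh_correct: bool = False) -> pd.DataFrame:
    """Per (position, residue) enrichment vs the reference model.

    Returns a long-format frame with observed/reference frequencies,
    percent difference (100 x (obs - ref)) and exact binomial two-sided
    p-values; ``significant`` marks p < alpha. Padding characters are
    excluded from the per-position totals. BH correction across cells is
    available but off by default.
    """
    if not windows:
        raise ValueError("need at least one window")
    n_left, n_right = windows[0].n_left, windows[0].n_right
    labels = position_labels(n_left, n_right)
    rows = []
    for j, label in enumerate(labels):
        residues = [w.residues[j] for w in windows if w.residues[j] != "-"]
        n = len(residues)
        counts = Counter(residues)
        for aa in sorted(reference):
            k = counts.get(aa, 0)
            ref = reference[aa]
            obs = k / n if n else 0.0
            p = binomial_two_sided(k, n, ref) if n else 1.0
            rows.append((label, aa, n, k, obs, ref,
                         100.0 * (obs - ref), p))
    df = pd.DataFrame(rows, columns=[
        "position", "residue", "n", "count", "observed_freq",
        "reference_freq", "percent_difference", "p_value"])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        df["p_adjusted"] = multipletests(df["p_value"],
                                         method="fdr_bh")[1]
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["significant"] = df["p_value"] < alpha
    return df


def subset_by_residue(windows: list[CleavageWindow], position_label: str,
                      residue: str) -> list[CleavageWindow]:
    """Windows carrying ``residue`` at the labelled position (e.g. the
    Arg-at-P2 / Arg-at-P3 subsets that separate direct processing-peptidase
    cleavage from subsequent aminopeptidase trimming)."""
    if not windows:
        return []
    idx = position_index(position_label, windows[0].n_left,
                         windows[0].n_right)
    return [w for w in windows if w.residues[idx] == residue]


def nterm_residue_profile(termini_by_group: dict[str, list[TerminusRecord]],
                          db: ProteinDB) -> dict[str, dict]:
    """Fraction of each residue at P1' per group, with the bacterial
    N-end-rule class split (stabilizing / secondary destabilizing /
    primary destabilizing)."""
    out: dict[str, dict] = {}
    for group, termini in termini_by_group.items():
        if not termini:
            raise ValueError(f"group {group!r} is empty")
        first = [db[t.protein_acc].sequence[t.start - 1] for t in termini]
        counts = Counter(first)
        n = len(first)
        fractions = {aa: c / n for aa, c in sorted(counts.items())}
        classes = Counter(NEND_RULE_CLASS.get(aa, "other") for aa in first)
        out[group] = {
            "fractions": fractions,
            "nend_rule": {cls: classes.get(cls, 0) / n
                          for cls in ("stabilizing", "destabilizing",
                                      "secondary_destabilizing", "other")},
            "n": n,
        }
    return out


def plot_logo(enrichment: pd.DataFrame, path: str,
              significant_only: bool = True) -> None:
    """Render a minimal letter plot (height = percent difference) of the
    significant cells; cosmetic output only."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = enrichment[enrichment["significant"]] if significant_only \
        else enrichment
    positions = list(dict.fromkeys(enrichment["position"]))
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(positions)), 3))
    for x, pos in enumerate(positions):
        sub = df[df["position"] == pos]
        up = sub[sub["percent_difference"] > 0].sort_values(
            "percent_difference", ascending=False)
        base = 0.0
        for _, row in up.iterrows():
            ax.text(x, base, row["residue"],
                    fontsize=6 + min(20, abs(row["percent_difference"])),
                    ha="center", va="bottom", color="tab:green")
            base += max(2.0, row["percent_difference"])
        down = sub[sub["percent_difference"] < 0]
        base = 0.0
        for _, row in down.iterrows():
            ax.text(x, base, row["residue"],
                    fontsize=6 + min(20, abs(row["percent_difference"])),
                    ha="center", va="top", color="tab:red")
            base -= max(2.0, abs(row["percent_difference"]))
    ax.set_xticks(range(len(positions)), positions)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("% difference vs reference")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
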