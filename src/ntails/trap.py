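"""Substrate-trapping screen statistics.

An affinity-purification LFQ matrix over three conditions (NEG empty
vector, WT active protease, TRAP catalytically dead protease) x three
replicates is imputed with a per-column downshifted normal (missing
LFQ values are low-abundance biased), tested per protein by one-way
ANOVA with Benjamini-Hochberg correction, resolved pairwise by Tukey's
HSD, and classified into substrate / interactor confidence classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("NEG", "WT", "TRAP")
PAIRS = (("TRAP", "WT"), ("TRAP", "NEG"), ("WT", "NEG"))
HIT_CLASSES = ("high_confidence", "putative", "wt_interactor",
               "not_significant")


def lfq_columns(n_replicates: int = 3) -> list[str]:
    return [f"{cond}_{r}" for cond in CONDITIONS
            for r in range(1, n_replicates + 1)]


def validate_matrix(matrix: pd.DataFrame, n_replicates: int = 3) -> None:
    missing = set(lfq_columns(n_replicates)) - set(matrix.columns)
    if missing:
        raise ValueError(f"LFQ matrix missing columns {sorted(missing)}")


def impute_missing(matrix: pd.DataFrame, width: float = 0.3,
                   downshift: float = 1.8, seed: int = 0,
                   n_replicates: int = 3
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-column downshifted-normal imputation of missing intensities.

    Missing cells in each LFQ column are drawn from
    Normal(mean - downshift*sd, (width*sd)^2) of that column's observed
    values — the conventional model for intensity-dependent (MNAR)
    missingness. Returns the imputed matrix and a boolean mask of the
    imputed cells; deterministic for a fixed seed.
    """
    validate_matrix(matrix, n_replicates)
    rng = np.random.default_rng(seed)
    imputed = matrix.copy()
    cols = lfq_columns(n_replicates)
    mask = pd.DataFrame(False, index=matrix.index, columns=cols)
    for col in cols:
        vals = matrix[col].astype(float)
        observed = vals.dropna()
        if len(observed) < 2:
            raise ValueError(f"column {col}: fewer than 2 observed values")
        miss = vals.isna()
        if miss.any():
            mu = observed.mean() - downshift * observed.std(ddof=1)
            sd = width * observed.std(ddof=1)
            imputed.loc[miss, col] = rng.normal(mu, sd, int(miss.sum()))
        mask[col] = miss
    return imputed, mask


def _group_values(row: pd.Series, cond: str,
                  n_replicates: int = 3) -> np.ndarray:
    return np.array([row[f"{cond}_{r}"]
                     for r in range(1, n_replicates + 1)], dtype=float)


def anova_bh(imputed: pd.DataFrame,
             n_replicates: int = 3) -> pd.DataFrame:
    """One-way ANOVA across NEG/WT/TRAP per protein, BH-corrected.

    Degenerate proteins (zero variance everywhere and equal means) get
    p = 1 by convention.
    """
    validate_matrix(imputed, n_replicates)
    records = []
    for idx, row in imputed.iterrows():
        groups = [_group_values(row, c, n_replicates) for c in CONDITIONS]
        flat = np.concatenate(groups)
        if np.allclose(flat, flat[0]):
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*groups)
            if not np.isfinite(p):
                f, p = np.inf, 0.0
        records.append((idx, float(f), float(p)))
    out = pd.DataFrame(records, columns=["protein", "F", "p"]
                       ).set_index("protein")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def tukey_posthoc(imputed: pd.DataFrame, proteins,
                  n_replicates: int = 3) -> pd.DataFrame:
    """Tukey HSD p-values for the three condition pairs.

    Uses the pooled within-group mean square from the same one-way ANOVA
    and the studentized range distribution with k = 3 groups.
    """
    validate_matrix(imputed, n_replicates)
    k = len(CONDITIONS)
    rows = []
    for idx in proteins:
        row = imputed.loc[idx]
        groups = [_group_values(row, c, n_replicates) for c in CONDITIONS]
        ns = [len(g) for g in groups]
        df_within = sum(ns) - k
        mse = sum(np.sum((g - g.mean()) ** 2) for g in groups) / df_within
        rec = {"protein": idx}
        for a, b in PAIRS:
            ga = groups[CONDITIONS.index(a)]
            gb = groups[CONDITIONS.index(b)]
            if mse <= 0:
                p = 1.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / len(ga) + 1.0 / len(gb)))
                q = abs(ga.mean() - gb.mean()) / se
                p = float(stats.studentized_range.sf(q, k, df_within))
            rec[f"tukey_p_{a}_{b}"] = p
        rows.append(rec)
    cols = ["protein"] + [f"tukey_p_{a}_{b}" for a, b in PAIRS]
    return pd.DataFrame(rows, columns=cols).set_index("protein")


def group_means(matrix: pd.DataFrame,
                mask: pd.DataFrame | None = None,
                n_replicates: int = 3) -> pd.DataFrame:
    """Per-condition means; when ``mask`` is given, imputed cells are
    excluded so reported enrichments reflect measured intensities only."""
    out = pd.DataFrame(index=matrix.index)
    for cond in CONDITIONS:
        cols = [f"{cond}_{r}" for r in range(1, n_replicates + 1)]
        vals = matrix[cols].astype(float)
        if mask is not None:
            vals = vals.where(~mask[cols])
        out[cond] = vals.mean(axis=1)
    return out


def classify_hits(anova: pd.DataFrame, tukey: pd.DataFrame,
                  means: pd.DataFrame, q_thresh: float = 0.05,
                  p_thresh: float = 0.05) -> pd.DataFrame:
    """Three-way hit classification.

    high_confidence: q < q_thresh, Tukey TRAP-WT p < p_thresh and TRAP
    mean above WT (substrate retained by the dead protease beyond the
    active one). putative: otherwise significant with TRAP over NEG.
    wt_interactor: otherwise significant with WT over NEG.
    """
    rows = []
    for protein, arow in anova.iterrows():
        trow = tukey.loc[protein] if protein in tukey.index else None
        m = means.loc[protein]
        cls = "not_significant"
        if arow["q"] < q_thresh and trow is not None:
            if (trow["tukey_p_TRAP_WT"] < p_thresh
                    and m["TRAP"] > m["WT"]):
                cls = "high_confidence"
            elif (trow["tukey_p_TRAP_NEG"] < p_thresh
                    and m["TRAP"] > m["NEG"]):
                cls = "putative"
            elif (trow["tukey_p_WT_NEG"] < p_thresh
                    and m["WT"] > m["NEG"]):
                cls = "wt_interactor"
        rec = {"protein": protein, "anova_q": arow["q"],
               "hit_class": cls,
               "log2_TRAP_WT": m["TRAP"] - m["WT"],
               "log2_TRAP_NEG": m["TRAP"] - m["NEG"],
               "log2_WT_NEG": m["WT"] - m["NEG"]}
        if trow is not None:
            for a, b in PAIRS:
                rec[f"tukey_p_{a}_{b}"] = trow[f"tukey_p_{a}_{b}"]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("protein")


def presence_absence(matrix: pd.DataFrame, min_detected: int = 2,
                     n_replicates: int = 3) -> pd.DataFrame:
    """Companion table of proteins detected in >= ``min_detected``
    replicates of one condition but never in another — candidates the
    impute-then-ANOVA route can miss."""
    validate_matrix(matrix, n_replicates)
    counts = pd.DataFrame(index=matrix.index)
    for cond in CONDITIONS:
        cols = [f"{cond}_{r}" for r in range(1, n_replicates + 1)]
        counts[f"n_{cond}"] = matrix[cols].notna().sum(axis=1)
    keep = ((counts.max(axis=1) >= min_detected)
            & (counts.min(axis=1) == 0))
    return counts[keep]
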