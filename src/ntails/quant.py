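"""Quantitative terminome analysis.

Per-replicate log2(KO/WT) ratios are median-centred on the expected
termini of mitochondrial proteins (which should sit at 1:1), replicates
are averaged under a >=2-of-3 quantification rule, expected and unexpected
terminus distributions are compared by Mann-Whitney U, a Tukey-fence
(1.5 x IQR) cutoff is derived from termini of abundance-unchanged
proteins, and strong accumulation/depletion calls are made against it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .terminome import TerminusRecord

DIFF_CALLS = ("accumulating", "depleted", "unchanged", "not_quantified")


@dataclass
class QuantifiedTerminus:
    terminus: TerminusRecord
    raw_log2_ratio: list[float | None]
    norm_log2_ratio: list[float | None] = field(default_factory=list)
    diff_call: str = "not_quantified"

    @property
    def n_quantified(self) -> int:
        vals = self.norm_log2_ratio or self.raw_log2_ratio
        return sum(v is not None for v in vals)

    @property
    def mean_norm_log2(self) -> float | None:
        vals = [v for v in self.norm_log2_ratio if v is not None]
        return float(np.mean(vals)) if vals else None


@dataclass
class CutoffBounds:
    lower: float
    upper: float
    method: str
    reference_n: int

    @property
    def degenerate(self) -> bool:
        return not self.lower < self.upper


@dataclass
class ClassComparison:
    n_expected: int
    n_unexpected: int
    median_expected: float
    median_unexpected: float
    mw_u: float
    p_two_sided: float

    @property
    def delta_median(self) -> float:
        return self.median_unexpected - self.median_expected


def replicate_ratios(terminus: TerminusRecord,
                     n_replicates: int = 3) -> list[float | None]:
    """Per-replicate log2 ratio of a unique terminus: median over its
    supporting peptides quantified in that replicate."""
    out: list[float | None] = []
    for r in range(n_replicates):
        vals = [p.ratio_hl[r] for p in terminus.supporting_peptides
                if p.ratio_hl[r] is not None]
        out.append(float(np.median(vals)) if vals else None)
    return out


def quantify_termini(termini: list[TerminusRecord],
                     n_replicates: int = 3) -> list[QuantifiedTerminus]:
    return [QuantifiedTerminus(t, replicate_ratios(t, n_replicates))
            for t in termini]


def normalize_ratios(quantified: list[QuantifiedTerminus],
                     n_replicates: int = 3) -> list[QuantifiedTerminus]:
    """Centre each replicate on the median ratio of expected-category
    termini of mitochondrial proteins, in place.

    After normalization that reference median is exactly 0 in every
    replicate, removing run-to-run differences in the amount of
    co-purified non-mitochondrial material.
    """
    for r in range(n_replicates):
        ref = [qt.raw_log2_ratio[r] for qt in quantified
               if qt.terminus.is_mitochondrial and qt.terminus.is_expected
               and qt.raw_log2_ratio[r] is not None]
        if not ref:
            raise ValueError(
                f"no expected mitochondrial reference termini quantified "
                f"in replicate {r + 1}")
        offset = float(np.median(ref))
        for qt in quantified:
            if len(qt.norm_log2_ratio) != n_replicates:
                qt.norm_log2_ratio = [None] * n_replicates
            raw = qt.raw_log2_ratio[r]
            qt.norm_log2_ratio[r] = None if raw is None else raw - offset
    return quantified


def aggregate_replicates(quantified: list[QuantifiedTerminus],
                         min_reps: int = 2,
                         total_reps: int = 3) -> list[QuantifiedTerminus]:
    """Keep termini quantified in >= ``min_reps`` of ``total_reps``
    replicates; the rest are marked ``not_quantified``."""
    for qt in quantified:
        if not qt.norm_log2_ratio:
            qt.norm_log2_ratio = list(qt.raw_log2_ratio)
        if qt.n_quantified >= min_reps:
            qt.diff_call = "unchanged"
        else:
            qt.diff_call = "not_quantified"
    return quantified


def mann_whitney_u(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, returning (U of ``y``, p).

    When min(n) <= ``exact_max_n`` the null distribution of U is
    enumerated over all group labelings of the pooled sample (valid under
    ties); otherwise the normal approximation with tie and continuity
    correction is used.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)

    def u_stat(a, b):
        # U counting pairs where b > a, ties as 1/2
        return sum((bi > ai) + 0.5 * (bi == ai) for ai in a for bi in b)

    u_obs = u_stat(x, y)
    if min(n1, n2) <= exact_max_n:
        pooled = x + y
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            mask = set(idx)
            a = [pooled[i] for i in idx]
            b = [pooled[i] for i in range(n1 + n2) if i not in mask]
            total += 1
            if abs(u_stat(a, b) - mu) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(y, x, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return u_obs, float(res.pvalue)


def compare_class_distributions(expected, unexpected) -> ClassComparison:
    """Shift of the unexpected (neo-terminus) distribution relative to the
    expected termini, with a two-sided Mann-Whitney U test."""
    expected = list(expected)
    unexpected = list(unexpected)
    if not expected or not unexpected:
        raise ValueError("both classes must be non-empty")
    u, p = mann_whitney_u(expected, unexpected)
    return ClassComparison(
        n_expected=len(expected),
        n_unexpected=len(unexpected),
        median_expected=float(np.median(expected)),
        median_unexpected=float(np.median(unexpected)),
        mw_u=u,
        p_two_sided=p,
    )


def derive_cutoff(reference_values, k: float = 1.5) -> CutoffBounds:
    """Tukey-fence cutoff (Q1 - k*IQR, Q3 + k*IQR) from the normalized
    ratios of termini on abundance-unchanged proteins.

    Quartiles use linear interpolation (quantile type 7), recorded in
    ``method`` since boxplot conventions differ.
    """
    vals = np.asarray(list(reference_values), dtype=float)
    if vals.size < 4:
        raise ValueError("need >= 4 reference values for a cutoff")
    q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
    iqr = q3 - q1
    return CutoffBounds(
        lower=float(q1 - k * iqr),
        upper=float(q3 + k * iqr),
        method=f"tukey_fence(k={k}, quantile=linear/type7)",
        reference_n=int(vals.size),
    )


def fixed_cutoff(bound: float = 0.9) -> CutoffBounds:
    """Symmetric fixed cutoff (config override when no reference set)."""
    return CutoffBounds(-abs(bound), abs(bound), "fixed", 0)


def call_differential_termini(
        quantified: list[QuantifiedTerminus],
        bounds: CutoffBounds) -> tuple[list[QuantifiedTerminus],
                                       pd.DataFrame]:
    """Set diff calls by strict comparison against the cutoff bounds and
    return the (expected/unexpected) x (call) summary table."""
    for qt in quantified:
        if qt.diff_call == "not_quantified":
            continue
        m = qt.mean_norm_log2
        if m is None:
            qt.diff_call = "not_quantified"
        elif m > bounds.upper:
            qt.diff_call = "accumulating"
        elif m < bounds.lower:
            qt.diff_call = "depleted"
        else:
            qt.diff_call = "unchanged"

    classes = ["expected", "unexpected"]
    calls = ["accumulating", "depleted", "unchanged"]
    table = pd.DataFrame(0, index=classes, columns=calls)
    for qt in quantified:
        if qt.diff_call == "not_quantified":
            continue
        cls = "expected" if qt.terminus.is_expected else "unexpected"
        table.loc[cls, qt.diff_call] += 1
    return quantified, table


def correlate_with_protein_abundance(
        quantified: list[QuantifiedTerminus],
        protein_lfq: pd.DataFrame) -> dict[str, dict]:
    """Pearson correlation of terminus vs protein-level log2 ratios, per
    positional class (joined on accession).

    ``protein_lfq`` needs columns ``accession`` and ``log2_ratio``.
    Classes with < 3 matched pairs are reported as not computable.
    """
    lfq = dict(zip(protein_lfq["accession"], protein_lfq["log2_ratio"]))
    out: dict[str, dict] = {}
    for cls in ("expected", "unexpected"):
        xs, ys, unmatched = [], [], 0
        for qt in quantified:
            if qt.diff_call == "not_quantified":
                continue
            if ("expected" if qt.terminus.is_expected else "unexpected") != cls:
                continue
            ratio = lfq.get(qt.terminus.protein_acc)
            if ratio is None or not math.isfinite(ratio):
                unmatched += 1
                continue
            xs.append(ratio)
            ys.append(qt.mean_norm_log2)
        if len(xs) < 3:
            out[cls] = {"n": len(xs), "unmatched": unmatched,
                        "pearson_r": None, "p_value": None}
            continue
        r, p = stats.pearsonr(xs, ys)
        out[cls] = {"n": len(xs), "unmatched": unmatched,
                    "pearson_r": float(r), "p_value": float(p)}
    return out
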