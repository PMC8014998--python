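"""Normalization, replicate aggregation, Mann-Whitney, IQR cutoff,
differential calls, protein-abundance correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ntails.evidence import PeptideEvidence
from ntails.quant import (CutoffBounds, QuantifiedTerminus,
                          aggregate_replicates, call_differential_termini,
                          compare_class_distributions,
                          correlate_with_protein_abundance, derive_cutoff,
                          fixed_cutoff, mann_whitney_u, normalize_ratios,
                          quantify_termini)
from ntails.simulate import (SyntheticConfig, generate_protein_db,
                             generate_tails_experiment)
from ntails.terminome import TerminusRecord


def _qt(raw, category="MTS", mito=True, acc="P1", start=11):
    term = TerminusRecord(acc, start, category, mito, "dimethyl",
                          [PeptideEvidence("AAAAR", acc, "dimethyl", (),
                                           (None,) * len(raw),
                                           (1,) * len(raw))])
    return QuantifiedTerminus(term, list(raw))


class TestNormalize:
    def test_median_offset(self):
        ref = [_qt([0.4]), _qt([0.6]), _qt([0.8])]
        other = _qt([1.5], category="unexpected")
        normalize_ratios(ref + [other], n_replicates=1)
        assert other.norm_log2_ratio[0] == pytest.approx(0.9)
        assert sorted(q.norm_log2_ratio[0] for q in ref) \
            == pytest.approx([-0.2, 0.0, 0.2])

    def test_identity_when_centred(self):
        ref = [_qt([-0.3]), _qt([0.0]), _qt([0.3])]
        normalize_ratios(ref, n_replicates=1)
        assert [q.norm_log2_ratio[0] for q in ref] == [-0.3, 0.0, 0.3]

    def test_single_reference_terminus(self):
        ref = [_qt([1.0])]
        other = _qt([2.5], category="unexpected")
        normalize_ratios(ref + [other], n_replicates=1)
        assert other.norm_log2_ratio[0] == pytest.approx(1.5)

    def test_missing_reference_errors(self):
        qts = [_qt([0.5], category="unexpected")]
        with pytest.raises(ValueError, match="replicate 1"):
            normalize_ratios(qts, n_replicates=1)

    def test_idempotence(self):
        qts = [_qt([0.4, 0.1]), _qt([0.6, None]),
               _qt([1.5, 0.2], category="unexpected")]
        normalize_ratios(qts, n_replicates=2)
        once = [list(q.norm_log2_ratio) for q in qts]
        normalize_ratios(qts, n_replicates=2)
        assert [list(q.norm_log2_ratio) for q in qts] == once


class TestAggregate:
    @pytest.mark.parametrize("values,mean,call", [
        ((0.5, 0.7, None), 0.6, "unchanged"),
        ((0.5, None, None), None, "not_quantified"),
        ((1.0, 2.0, 3.0), 2.0, "unchanged"),
    ])
    def test_min_reps_rule(self, values, mean, call):
        qt = _qt(list(values))
        qt.norm_log2_ratio = list(values)
        aggregate_replicates([qt])
        assert qt.diff_call == call
        if mean is None:
            assert qt.n_quantified < 2
        else:
            assert qt.mean_norm_log2 == pytest.approx(mean)


def mw_permutation_oracle(x, y):
    """Brute force: pairwise-count U over every labeling of the pool."""
    n1 = len(x)
    pooled = list(x) + list(y)
    mu = n1 * len(y) / 2

    def u(a, b):
        return sum((bi > ai) + 0.5 * (bi == ai) for ai in a for bi in b)

    obs = abs(u(x, y) - mu)
    stats = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        stats.append(abs(u(a, b) - mu))
    return sum(s >= obs - 1e-12 for s in stats) / len(stats)


class TestMannWhitney:
    def test_three_vs_three_separated(self):
        comp = compare_class_distributions([0, 0, 0], [1, 1, 1])
        assert comp.delta_median == 1
        assert comp.p_two_sided == pytest.approx(0.1)

    def test_identical_groups(self):
        comp = compare_class_distributions([1, 2, 3], [1, 2, 3])
        assert comp.delta_median == 0
        assert comp.p_two_sided == 1.0

    def test_two_vs_two(self):
        comp = compare_class_distributions([0, 1], [2, 3])
        assert comp.p_two_sided == pytest.approx(1 / 3)

    def test_exact_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(0)
        for n1 in range(1, 6):
            for n2 in range(n1, 11 - n1):
                x = list(rng.integers(0, 4, n1))  # ties likely
                y = list(rng.integers(0, 4, n2))
                _, p = mann_whitney_u(x, y)
                assert p == pytest.approx(mw_permutation_oracle(x, y))

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.8, 1, 40)
        _, p = mann_whitney_u(x, y)
        from scipy.stats import mannwhitneyu
        ref = mannwhitneyu(y, x, alternative="two-sided",
                           method="asymptotic").pvalue
        assert p == pytest.approx(float(ref))


class TestDeriveCutoff:
    def test_hand_computed_quartiles(self):
        b = derive_cutoff([-0.4, -0.2, 0, 0.2, 0.4])
        assert (b.lower, b.upper) == pytest.approx((-0.8, 0.8))
        assert "k=1.5" in b.method

    def test_degenerate_all_zero(self):
        b = derive_cutoff([0.0] * 10)
        assert b.lower == b.upper == 0.0
        assert b.degenerate

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            derive_cutoff([0.0, 0.1, 0.2])

    def test_matches_quantile_oracle_on_normal_sample(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(0, 0.3, 120)
        b = derive_cutoff(vals)
        q1, q3 = np.percentile(vals, [25, 75])
        assert b.lower == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert b.upper == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_sanity_envelope_for_reference_style_sample(self):
        """Termini of unchanged proteins (n about 100, sd about 0.3)
        give fences of roughly +/-0.9 magnitude."""
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 0.3, 100)
        b = derive_cutoff(vals)
        assert 0.5 <= abs(b.lower) <= 1.3
        assert 0.5 <= abs(b.upper) <= 1.3


class TestDifferentialCalls:
    def test_boundary_is_strict(self):
        bounds = fixed_cutoff(0.9)
        qts = [_qt([1.2, 1.2]), _qt([0.9, 0.9]), _qt([-1.0, -1.0])]
        for qt in qts:
            qt.norm_log2_ratio = list(qt.raw_log2_ratio)
        aggregate_replicates(qts)
        _, table = call_differential_termini(qts, bounds)
        assert [q.diff_call for q in qts] \
            == ["accumulating", "unchanged", "depleted"]
        assert table.loc["expected", "accumulating"] == 1

    def test_planted_shift_recovery(self):
        rng = np.random.default_rng(3)
        shifted = [_qt(list(rng.normal(2.0, 0.1, 2)),
                       category="unexpected") for _ in range(20)]
        nulls = [_qt(list(rng.normal(0, 0.3, 2)), category="unexpected")
                 for _ in range(200)]
        qts = shifted + nulls
        for qt in qts:
            qt.norm_log2_ratio = list(qt.raw_log2_ratio)
        aggregate_replicates(qts)
        bounds = derive_cutoff([qt.mean_norm_log2 for qt in nulls])
        call_differential_termini(qts, bounds)
        n_called = sum(q.diff_call == "accumulating" for q in shifted)
        false = sum(q.diff_call != "unchanged" for q in nulls)
        assert n_called >= 19
        assert false <= 10  # <= 5% of 200 nulls


class TestCorrelation:
    def _qts_with_lfq(self, pairs, category="MTS"):
        qts, rows = [], []
        for i, (prot_ratio, term_ratio) in enumerate(pairs):
            qt = _qt([term_ratio, term_ratio], category=category,
                     acc=f"P{i}")
            qt.norm_log2_ratio = list(qt.raw_log2_ratio)
            qts.append(qt)
            rows.append({"accession": f"P{i}", "log2_ratio": prot_ratio,
                         "significant_flag": False})
        aggregate_replicates(qts)
        return qts, pd.DataFrame(rows)

    def test_perfect_positive(self):
        qts, lfq = self._qts_with_lfq([(1, 1), (2, 2), (3, 3)])
        out = correlate_with_protein_abundance(qts, lfq)
        assert out["expected"]["pearson_r"] == pytest.approx(1.0)

    def test_perfect_negative(self):
        qts, lfq = self._qts_with_lfq([(1, 3), (2, 2), (3, 1)])
        out = correlate_with_protein_abundance(qts, lfq)
        assert out["expected"]["pearson_r"] == pytest.approx(-1.0)

    def test_too_few_pairs_not_computable(self):
        qts, lfq = self._qts_with_lfq([(1, 1), (2, 2)])
        out = correlate_with_protein_abundance(qts, lfq)
        assert out["expected"]["pearson_r"] is None

    def test_noisy_synthetic_correlation(self):
        rng = np.random.default_rng(5)
        prot = rng.normal(0, 0.5, 120)
        pairs = [(p, p + rng.normal(0, 0.2)) for p in prot]
        qts, lfq = self._qts_with_lfq(pairs)
        out = correlate_with_protein_abundance(qts, lfq)
        assert 0.7 <= out["expected"]["pearson_r"] <= 0.95


class TestParameterRecovery:
    def test_delta_median_recovery_over_seeds(self):
        """The planted global neo-terminus shift is recovered to 0.05
        (seed-averaged) by the full normalize/aggregate/compare chain."""
        from ntails.models import TailsAnalysis, TailsConfig
        deltas = []
        for seed in range(20):
            cfg = SyntheticConfig(seed=seed)
            db, db_truth = generate_protein_db(cfg)
            ds = generate_tails_experiment(cfg, db, db_truth)
            res = TailsAnalysis(ds.evidence, db, ds.protein_lfq).fit()
            assert res.comparison.n_unexpected >= 300
            deltas.append(res.comparison.delta_median)
        assert np.mean(deltas) == pytest.approx(0.32, abs=0.05)
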