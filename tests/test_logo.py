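"""Cleavage windows, iceLogo-style enrichment, residue profiling."""

import numpy as np
import pytest
from scipy import stats

from ntails.evidence import PeptideEvidence
from ntails.logo import (CleavageWindow, binomial_two_sided,
                         extract_cleavage_windows, nterm_residue_profile,
                         position_enrichment, position_labels,
                         reference_frequencies, subset_by_residue)
from ntails.proteins import ProteinDB, ProteinRecord
from ntails.terminome import TerminusRecord


def _terminus(acc, start, mito=True):
    return TerminusRecord(acc, start, "unexpected", mito, "dimethyl",
                          [PeptideEvidence("AAAAR", acc, "dimethyl", (),
                                           (None,), (1,))])


def _window(residues, n_left=5, n_right=5):
    return CleavageWindow("X", 1, residues, n_left, n_right)


class TestWindows:
    def test_extraction(self, prot1_db):
        wins = extract_cleavage_windows([_terminus("PROT1", 21)], prot1_db)
        assert wins[0].residues == "VRAGKWTEYF"

    def test_dedupe(self, prot1_db):
        wins = extract_cleavage_windows(
            [_terminus("PROT1", 21), _terminus("PROT1", 21)], prot1_db)
        assert len(wins) == 1

    def test_position_one_padded(self, prot1_db):
        wins = extract_cleavage_windows([_terminus("PROT1", 1)], prot1_db)
        assert wins[0].residues == "-----MLSRR"

    def test_labels(self):
        assert position_labels(2, 2) == ["P2", "P1", "P1'", "P2'"]


class TestReferenceFrequencies:
    def test_single_residue(self):
        db = ProteinDB([ProteinRecord("X", "AAAA", True)])
        freqs = reference_frequencies(db)
        assert freqs["A"] == 1.0

    def test_two_residue_toy(self):
        db = ProteinDB([ProteinRecord("X", "AAGG", True)])
        freqs = reference_frequencies(db, "all_proteins")
        assert freqs["A"] == freqs["G"] == 0.5

    def test_empty_scope_errors(self):
        db = ProteinDB([ProteinRecord("X", "AAAA", False)])
        with pytest.raises(ValueError):
            reference_frequencies(db, "mitochondrial_only")

    def test_matches_counting_oracle(self, tails_default):
        _, db, _, _ = tails_default
        freqs = reference_frequencies(db, "mitochondrial_only")
        from collections import Counter
        counts = Counter()
        for rec in db:
            if rec.is_mitochondrial:
                counts.update(rec.sequence)
        total = sum(counts.values())
        for aa, c in counts.items():
            assert freqs[aa] == pytest.approx(c / total)


class TestPositionEnrichment:
    def test_all_arg_at_p1(self):
        wins = [_window("AAAAR" + "WTEYF") for _ in range(10)]
        ref = {aa: 0.05 for aa in "ARWTEYF"}
        df = position_enrichment(wins, ref)
        cell = df[(df.position == "P1") & (df.residue == "R")].iloc[0]
        assert cell.percent_difference == pytest.approx(95.0)
        assert cell.p_value < 1e-12
        assert cell.significant

    def test_matching_reference_not_significant(self):
        wins = [_window("A" * 10) for _ in range(3)] \
            + [_window("G" * 10) for _ in range(3)]
        df = position_enrichment(wins, {"A": 0.5, "G": 0.5})
        assert (df.percent_difference == 0).all()
        assert not df.significant.any()

    def test_padding_excluded_from_n(self):
        wins = [_window("-----MLSRR"), _window("AAAAAMLSRR")]
        df = position_enrichment(wins, {aa: 0.05 for aa in "AMLSR"})
        p5 = df[df.position == "P5"]
        assert (p5.n == 1).all()

    def test_binomial_oracle_small_n(self):
        """Exact doubled-tail p agrees with direct binomial sums."""
        for n in (1, 5, 12, 20):
            for k in range(n + 1):
                for p0 in (0.05, 0.3, 0.5):
                    direct = min(1.0, 2 * min(
                        sum(stats.binom.pmf(i, n, p0)
                            for i in range(k + 1)),
                        sum(stats.binom.pmf(i, n, p0)
                            for i in range(k, n + 1))))
                    assert binomial_two_sided(k, n, p0) \
                        == pytest.approx(direct, abs=1e-10)

    def test_type_i_error_control(self):
        """Windows drawn i.i.d. from the reference give <= 7% significant
        cells at alpha 0.05 (averaged over seeds)."""
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        ref = {aa: 0.05 for aa in aas}
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            wins = [_window("".join(rng.choice(aas, 10)))
                    for _ in range(500)]
            df = position_enrichment(wins, ref)
            fracs.append(df.significant.mean())
        assert np.mean(fracs) <= 0.07


class TestLogoPlot:
    def test_writes_image(self, tmp_path):
        from ntails.logo import plot_logo
        wins = [_window("AAAAR" + "WTEYF") for _ in range(10)]
        ref = {aa: 0.05 for aa in "ARWTEYF"}
        df = position_enrichment(wins, ref)
        out = tmp_path / "logo.svg"
        plot_logo(df, str(out))
        assert out.stat().st_size > 0


class TestSubsetByResidue:
    def test_p2_convention(self):
        w1, w2 = _window("VRAGKWTEYF"), _window("AAAAASSSSS")
        assert subset_by_residue([w1, w2], "P2", "G") == [w1]
        assert subset_by_residue([w1, w2], "P1", "K") == [w1]

    def test_absent_residue(self):
        assert subset_by_residue([_window("VRAGKWTEYF")], "P2", "W") == []

    def test_p1_prime(self):
        w = _window("VRAGKWTEYF")
        assert subset_by_residue([w], "P1'", "W") == [w]

    def test_bad_label(self):
        with pytest.raises(ValueError):
            subset_by_residue([_window("VRAGKWTEYF")], "P9", "A")

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        wins = [_window("".join(rng.choice(aas + ["-"], 10)))
                for _ in range(50)]
        for label in ("P3", "P1", "P2'"):
            total = sum(len(subset_by_residue(wins, label, aa))
                        for aa in aas)
            idx = position_labels(5, 5).index(label)
            assert total == sum(w.residues[idx] != "-" for w in wins)


class TestNtermResidueProfile:
    def _db(self, seqs):
        return ProteinDB([ProteinRecord(f"P{i}", s, True)
                          for i, s in enumerate(seqs)])

    def test_all_ala(self):
        db = self._db(["AAAAAA"])
        prof = nterm_residue_profile(
            {"g": [_terminus("P0", 1)]}, db)
        assert prof["g"]["fractions"]["A"] == 1.0
        assert prof["g"]["nend_rule"]["stabilizing"] == 1.0

    def test_half_secondary_destabilizing(self):
        db = self._db(["AAAAAA", "DAAAAA"])
        prof = nterm_residue_profile(
            {"g": [_terminus("P0", 1), _terminus("P1", 1)]}, db)
        assert prof["g"]["nend_rule"]["stabilizing"] == 0.5
        assert prof["g"]["nend_rule"]["secondary_destabilizing"] == 0.5

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            nterm_residue_profile({"g": []}, self._db(["AA"]))

    def test_synthetic_expected_starts_are_stabilizing_biased(
            self, tails_default):
        _, db, dataset, results = tails_default
        expected = [t for t in results.termini if t.category == "MTS"]
        prof = nterm_residue_profile({"expected": expected}, db)
        assert prof["expected"]["nend_rule"]["stabilizing"] >= 0.7
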