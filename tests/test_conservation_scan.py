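"""Codon-alignment construction and synonymous-site conservation scanning."""

import numpy as np
import pytest

from riboshift import (
    CodonAlignment,
    SimConfig,
    back_translate_alignment,
    classify_columns,
    simulate_codon_alignment,
    window_synonymy_scan,
)
from riboshift.conservation_scan import (
    CODON_TO_AA,
    GAP,
    IDENTICAL,
    NON_SYNONYMOUS,
    SYNONYMOUS,
    classify_codon_pair,
    read_codon_alignment_fasta,
    write_codon_alignment_fasta,
)
from riboshift.synthetic_data import SENSE_CODONS, random_cds


class TestBackTranslation:
    def test_single_gap_case(self):
        aln = back_translate_alignment(["a", "b"], ["MQK", "M-K"],
                                       {"a": "ATGCAAAAA", "b": "ATGAAG"})
        assert aln.rows[0] == ["ATG", "CAA", "AAA"]
        assert aln.rows[1] == ["ATG", "---", "AAG"]

    def test_round_trip_degap_equals_cds(self, rng):
        names, prots, cds = self._random_protein_alignment(rng, n=6, ncol=40)
        aln = back_translate_alignment(names, prots, cds)
        for name, row in zip(aln.names, aln.rows):
            rebuilt = "".join(c for c in row if c != "---")
            stripped = cds[name][: len(rebuilt)]
            assert rebuilt == stripped

    def test_matches_position_map_oracle(self, rng):
        """Each aligned codon equals the CDS codon at the residue's ungapped index."""
        names, prots, cds = self._random_protein_alignment(rng, n=5, ncol=30)
        aln = back_translate_alignment(names, prots, cds)
        for name, prot, row in zip(names, prots, aln.rows):
            resi = 0
            for col, aa in enumerate(prot):
                if aa == "-":
                    assert row[col] == "---"
                else:
                    assert row[col] == cds[name][3 * resi : 3 * resi + 3]
                    resi += 1

    def test_translation_mismatch_reported_with_row_and_position(self):
        with pytest.raises(ValueError, match="residue 1"):
            back_translate_alignment(["a"], ["MK"], {"a": "ATGCAA"})  # MQ, not MK

    @staticmethod
    def _random_protein_alignment(rng, n, ncol):
        names, prots, cds = [], [], {}
        for k in range(n):
            codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=ncol)]
            gaps = rng.random(ncol) < 0.15
            prot = "".join(
                "-" if g else CODON_TO_AA[c] for g, c in zip(gaps, codons)
            )
            names.append(f"sp{k}")
            prots.append(prot)
            cds[f"sp{k}"] = "".join(c for g, c in zip(gaps, codons) if not g)
        return names, prots, cds


class TestClassification:
    @pytest.mark.parametrize(
        "ref,codon,kind",
        [
            ("CTG", "CTT", SYNONYMOUS),     # both Leu
            ("ATT", "CTT", NON_SYNONYMOUS),  # Ile vs Leu
            ("CTT", "CTT", IDENTICAL),
            ("CTT", "---", GAP),
            ("---", "CTT", GAP),
        ],
    )
    def test_pairwise_kinds(self, ref, codon, kind):
        assert classify_codon_pair(ref, codon) == kind

    def test_matches_codon_table_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            a = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
            b = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
            got = classify_codon_pair(a, b)
            if a == b:
                assert got == IDENTICAL
            elif CODON_TO_AA[a] == CODON_TO_AA[b]:
                assert got == SYNONYMOUS
            else:
                assert got == NON_SYNONYMOUS

    def test_kind_symmetric_under_reference_swap(self, rng):
        for _ in range(200):
            a = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
            b = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
            assert classify_codon_pair(a, b) == classify_codon_pair(b, a)

    def test_classify_columns_covers_all_nonreference_cells(self):
        aln = CodonAlignment(["r", "x", "y"],
                             [["ATG", "CTT"], ["ATG", "CTG"], ["---", "ATT"]], 0)
        calls = classify_columns(aln)
        assert len(calls) == 4
        kinds = {(c.row, c.column): c.kind for c in calls}
        assert kinds[(1, 1)] == SYNONYMOUS
        assert kinds[(2, 0)] == GAP
        assert kinds[(2, 1)] == NON_SYNONYMOUS


class TestWindowScan:
    def test_identical_rows_are_all_undefined(self):
        row = ["ATG", "CTT", "AAA", "GGG", "CCC", "TTT"]
        aln = CodonAlignment(["a", "b", "c"], [list(row) for _ in range(3)], 0)
        stats = window_synonymy_scan(aln, window=3)
        assert stats and all(not w.defined for w in stats)
        assert all(w.observed_syn == 0 for w in stats)

    def test_window_bounds_validation(self):
        aln = CodonAlignment(["a", "b"], [["ATG"] * 10, ["ATG"] * 10], 0)
        with pytest.raises(ValueError):
            window_synonymy_scan(aln, window=2)
        with pytest.raises(ValueError):
            window_synonymy_scan(aln, window=11)

    def test_window_sums_match_column_sums(self, rng):
        """Sum of per-window observed counts equals overlap multiplicity x column counts."""
        cds = random_cds(60, rng)
        aln = simulate_codon_alignment(cds, 8, SimConfig(seed=9), rng=rng)
        w = 17
        stats = window_synonymy_scan(aln, window=w)
        from riboshift.conservation_scan import _call_matrices

        _, syn = _call_matrices(aln)
        per_col = syn.sum(axis=0)
        ncol = aln.n_columns
        # windows covering column c: starts in [max(0, c-w+1), min(c, ncol-w)]
        starts_lo = np.maximum(0, np.arange(ncol) - w + 1)
        starts_hi = np.minimum(np.arange(ncol), ncol - w)
        multiplicity = np.maximum(0, starts_hi - starts_lo + 1)
        assert sum(s.observed_syn for s in stats) == int((per_col * multiplicity).sum())

    def test_null_p_values_are_conservative(self, rng):
        """Under the unconstrained simulator the p<0.05 rate does not exceed nominal."""
        flagged, total = 0, 0
        for seed in range(30):
            cds = random_cds(120, rng)
            aln = simulate_codon_alignment(cds, 12, SimConfig(seed=seed), rng=rng)
            for wstat in window_synonymy_scan(aln, window=17):
                if wstat.defined:
                    total += 1
                    flagged += wstat.p_value < 0.05
        assert flagged / total < 0.08

    def test_constrained_window_is_localised(self, rng):
        hits = 0
        n = 40
        for seed in range(n):
            cds = random_cds(200, rng)
            start = int(rng.integers(30, 150))
            aln = simulate_codon_alignment(
                cds, 20, SimConfig(seed=seed, constraint_factor=0.2),
                constraint_window=(start, start + 17), rng=rng,
            )
            stats = [w for w in window_synonymy_scan(aln, window=17) if w.defined]
            best = min(stats, key=lambda w: w.p_value)
            hits += abs(best.center_codon - (start + 8)) <= 3
        assert hits / n >= 0.85

    def test_bh_correction_adds_monotone_q_values(self, rng):
        cds = random_cds(80, rng)
        aln = simulate_codon_alignment(cds, 10, SimConfig(seed=2), rng=rng)
        stats = [w for w in window_synonymy_scan(aln, 17, bh_correct=True) if w.defined]
        assert all(w.q_value is not None and w.q_value >= w.p_value - 1e-12 for w in stats)


def test_alignment_fasta_round_trip(tmp_path, rng):
    cds = random_cds(40, rng)
    aln = simulate_codon_alignment(cds, 5, SimConfig(seed=3), rng=rng)
    path = tmp_path / "aln.fasta"
    write_codon_alignment_fasta(aln, path)
    back = read_codon_alignment_fasta(path)
    assert back.names == aln.names and back.rows == aln.rows
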