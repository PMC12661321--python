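"""Hairpin dynamic programme, spacer geometry and DMS agreement."""

import itertools
import math

import numpy as np
import pytest

from riboshift import (
    FrameshiftSite,
    MOTIFS,
    ReactivityTrack,
    SimConfig,
    StemLoop,
    dms_consistency,
    find_best_hairpin,
    simulate_dms,
    spacer_to_site,
)
from riboshift.structure_probe import (
    GU_PAIRS,
    enumerate_hairpins,
    read_reactivity_tsv,
    to_dot_bracket,
    write_reactivity_tsv,
)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _brute_best(seq):
    scores = [s for s, _ in enumerate_hairpins(seq)]
    best = max(scores, default=None)
    return best if best is not None and best > 0 else None


class TestFindBestHairpin:
    def test_perfect_three_bp_stem(self):
        stem = find_best_hairpin("GGGAAACCC")
        assert stem is not None
        assert stem.pairs == [(0, 8), (1, 7), (2, 6)]
        assert stem.loop == (3, 6)          # loop positions 3-5
        assert stem.score == 3 * 2 - 3      # three stacked WC pairs, opening penalty
        assert _brute_best("GGGAAACCC") == stem.score

    def test_unpairable_sequence_returns_none(self):
        assert find_best_hairpin("AAAAAAAAA") is None

    def test_gu_pairs_score_less_than_wc(self):
        wc = find_best_hairpin("GGGGAAACCCC")
        gu = find_best_hairpin("GGGGAAATCCC")  # one G.U in place of G-C
        assert wc is not None and gu is not None
        assert gu.score < wc.score

    def test_matches_enumeration_oracle_on_random_short_sequences(self, rng):
        for _ in range(500):
            n = int(rng.integers(5, 13))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            stem = find_best_hairpin(seq)
            dp = stem.score if stem is not None else None
            assert dp == _brute_best(seq), seq

    def test_bulge_penalty_applied(self):
        # helix interrupted by a 1-nt bulge should beat nothing but score
        # below the equivalent uninterrupted helix
        contiguous = find_best_hairpin("GGGGAAAACCCC")
        bulged = find_best_hairpin("GGGGAAAACCACC")
        assert contiguous is not None and bulged is not None
        assert bulged.score <= contiguous.score

    def test_window_restriction_and_limit(self):
        seq = "T" * 20 + "GGGAAACCC" + "T" * 20
        stem = find_best_hairpin(seq, (20, 29))
        assert stem is not None and stem.span == (20, 29)
        with pytest.raises(ValueError, match="window"):
            find_best_hairpin("A" * 300, (0, 250))

    def test_reverse_complement_symmetry_for_wc_only_optima(self, rng):
        """A WC-only hairpin maps onto the reverse complement with equal score;
        G.U pairs break the bijection (they map to unpairable A.C), so the
        guarantee is one-sided unless both optima are WC-only."""
        for _ in range(200):
            n = int(rng.integers(8, 13))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            fwd = find_best_hairpin(seq)
            if fwd is None:
                continue
            rc = seq.translate(COMPLEMENT)[::-1]
            rev = find_best_hairpin(rc)
            fwd_wc = all((seq[i], seq[j]) not in GU_PAIRS for i, j in fwd.pairs)
            if fwd_wc:
                assert rev is not None and rev.score >= fwd.score
                rev_wc = all((rc[i], rc[j]) not in GU_PAIRS for i, j in rev.pairs)
                if rev_wc:
                    assert rev.score == fwd.score

    def test_tie_break_prefers_five_prime_hairpin(self):
        # two identical hairpins; the 5'-most must be reported
        seq = "GGGAAACCC" + "TT" + "GGGAAACCC"
        stem = find_best_hairpin(seq)
        assert stem.span == (0, 9)


class TestSpacer:
    def _site_at(self, start):
        return FrameshiftSite("s", start, MOTIFS["Ty1-type"], orf_start=0)

    def test_six_nt_two_codon_spacer(self):
        # hairpin base ending 6 nt before the heptamer: the native geometry
        seq = "GGGAAACCC" + "ACAGTA" + "CTTAGGC" + "TAA"
        stem = find_best_hairpin(seq, (0, 9))
        site = self._site_at(15)
        assert spacer_to_site(stem, site) == (6, 2)
        assert stem.spacer_nt == 6

    def test_abutting_hairpin(self):
        seq = "GGGAAACCC" + "CTTAGGC"
        stem = find_best_hairpin(seq, (0, 9))
        assert spacer_to_site(stem, self._site_at(9)) == (0, 0)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_codon_insertions_extend_spacer(self, k):
        """Inserting k codons between stem and site gives a 2+k codon spacer."""
        insert = "ACA" * k
        seq = "GGGAAACCC" + "ACAGTA" + insert + "CTTAGGC" + "TAA"
        stem = find_best_hairpin(seq, (0, 9))
        nt, codons = spacer_to_site(stem, self._site_at(15 + 3 * k))
        assert (nt, codons) == (6 + 3 * k, 2 + k)

    def test_non_codon_multiple_reports_nt_only(self):
        stem = StemLoop([(0, 8)], (1, 8), (0, 9), 3)
        nt, codons = spacer_to_site(stem, self._site_at(13))
        assert nt == 4 and codons is None

    def test_downstream_stem_rejected(self):
        stem = StemLoop([(10, 20)], (11, 20), (10, 21), 3)
        with pytest.raises(ValueError):
            spacer_to_site(stem, self._site_at(5))


class TestDmsConsistency:
    def _stem(self):
        return StemLoop([(0, 8), (1, 7), (2, 6)], (3, 6), (0, 9), 3)

    def test_perfect_separation(self):
        # paired A/C at 0 reactivity, unpaired at 1 -> 1.0
        bases = "ACACAACCA"
        react = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        assert dms_consistency(self._stem(), ReactivityTrack(bases, react)) == 1.0

    def test_reversed_separation(self):
        bases = "ACACAACCA"
        react = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        assert dms_consistency(self._stem(), ReactivityTrack(bases, react)) == 0.0

    def test_matches_all_pairs_oracle(self, rng):
        bases = "ACACAACCA"
        for _ in range(50):
            react = rng.exponential(1.0, size=9)
            react[3] = react[4]  # introduce a tie across classes sometimes
            track = ReactivityTrack(bases, react)
            stem = self._stem()
            paired = {p for ij in stem.pairs for p in ij}
            up = [react[p] for p in range(9) if bases[p] in "AC" and p not in paired]
            pa = [react[p] for p in range(9) if bases[p] in "AC" and p in paired]
            oracle = np.mean([
                1.0 if u > q else 0.5 if u == q else 0.0
                for u, q in itertools.product(up, pa)
            ])
            assert dms_consistency(stem, track) == pytest.approx(oracle)

    def test_no_eligible_bases_is_nan(self):
        track = ReactivityTrack("GGGTTTGGG", np.full(9, np.nan))
        assert math.isnan(dms_consistency(self._stem(), track))

    def test_simulated_track_auc_tracks_snr(self):
        """Exponential unpaired/paired reactivities give AUC ~ snr/(1+snr)."""
        seq = "CACACACAAAACACACACA"[:19]
        stem = StemLoop([(i, 18 - i) for i in range(8)], (8, 11), (0, 19), 10)
        for snr, expected in [(1.0, 0.5), (3.0, 0.75), (9.0, 0.9)]:
            scores = []
            for seed in range(300):
                cfg = SimConfig(seed=seed, dms_snr=snr)
                track = simulate_dms(stem, seq, cfg)
                scores.append(dms_consistency(stem, track))
            assert np.mean(scores) == pytest.approx(expected, abs=0.04)


def test_dot_bracket_and_reactivity_io(tmp_path):
    stem = find_best_hairpin("GGGAAACCC")
    assert to_dot_bracket(stem, 9) == "(((...)))"
    track = ReactivityTrack("ACGTACGTA", np.array(
        [0.1, np.nan, np.nan, np.nan, 1.2, 0.3, np.nan, np.nan, 0.7]))
    path = tmp_path / "dms.tsv"
    write_reactivity_tsv(track, path)
    back = read_reactivity_tsv(path, length=9)
    mask = ~np.isnan(track.reactivity)
    assert np.allclose(back.reactivity[mask], track.reactivity[mask], rtol=1e-5)
    assert np.all(np.isnan(back.reactivity[~mask]))
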