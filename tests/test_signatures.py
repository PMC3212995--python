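import numpy as np
import pytest

from tecat.signatures import (DirectRepeatPair, InvertedRepeat,
                              classify_geometry, detect_direct_repeats,
                              detect_inverted_repeats, detect_pbs,
                              detect_ppt, find_orfs, ltr_pair_identity)
from tecat.seqio import SequenceRecord, revcomp

from conftest import mutate_subst, random_dna
import oracles


class TestInvertedRepeats:
    def test_planted_perfect_tir(self, rng):
        T = random_dna(rng, 25)
        seq = T + random_dna(rng, 800) + revcomp(T)
        irs = detect_inverted_repeats(seq)
        assert len(irs) == 1
        ir = irs[0]
        assert ir.arm1 == (0, 25)
        assert ir.arm2 == (825, 850)
        assert ir.arm_identity == 1.0
        assert ir.geometry == "terminal"

    def test_perfect_palindrome(self, rng):
        half = random_dna(rng, 30)
        irs = detect_inverted_repeats(half + revcomp(half))
        assert len(irs) == 1
        assert irs[0].geometry == "palindromic"
        assert irs[0].arm1 == (0, 30) and irs[0].arm2 == (30, 60)

    def test_random_sequences_produce_no_signature_irs(self):
        """i.i.d. 800-mers must yield no terminal/palindromic IR call; the
        E-value gate bounds chance sub-terminal micro-IRs at roughly its
        cutoff (0.1) per sequence, so a 100-sequence panel may contain a
        few 15-mer coincidences but nothing resembling a TE signature."""
        total = signature_like = 0
        for seed in range(100):
            r = np.random.default_rng(5_000 + seed)
            seq = random_dna(r, 800)
            irs = detect_inverted_repeats(seq, min_arm=15,
                                          min_arm_identity=0.9)
            total += len(irs)
            signature_like += sum(1 for i in irs
                                  if i.geometry in ("terminal", "palindromic"))
        assert signature_like == 0
        assert total <= 10  # Poisson bound from the e_max=0.1 gate

    def test_strand_symmetry(self, rng):
        T = random_dna(rng, 20)
        seq = random_dna(rng, 100) + T + random_dna(rng, 500) + revcomp(T) \
            + random_dna(rng, 50)
        fwd = detect_inverted_repeats(seq)
        rev = detect_inverted_repeats(revcomp(seq))
        L = len(seq)
        mirrored = sorted((L - i.arm2[1], L - i.arm2[0], L - i.arm1[1],
                           L - i.arm1[0]) for i in rev)
        assert sorted(i.arm1 + i.arm2 for i in fwd) == mirrored

    def test_diverged_arms_still_found(self, rng):
        # per-arm substitution 0.03: the TIR must still be recovered
        found = 0
        for _ in range(20):
            T = random_dna(rng, 40)
            seq = (mutate_subst(T, 0.03, rng) + random_dna(rng, 600)
                   + revcomp(mutate_subst(T, 0.03, rng)))
            irs = detect_inverted_repeats(seq, min_arm=15,
                                          min_arm_identity=0.8)
            found += any(i.geometry == "terminal" for i in irs)
        assert found >= 19


class TestGeometry:
    def test_terminal_windows(self):
        ir = InvertedRepeat((0, 25), (775, 800), 1.0)
        assert classify_geometry(ir, 800) == "terminal"

    def test_subterminal(self):
        ir = InvertedRepeat((200, 225), (500, 525), 1.0)
        assert classify_geometry(ir, 800) == "subterminal"

    def test_adjacent_arms_covering_sequence_palindromic(self):
        ir = InvertedRepeat((1, 29), (31, 59), 1.0)
        assert classify_geometry(ir, 60) == "palindromic"


class TestDirectRepeats:
    def test_planted_ltr_pair(self, rng):
        L = random_dna(rng, 150)
        seq = L + random_dna(rng, 3000) + L
        pairs = detect_direct_repeats(seq)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.five_prime == (0, 150)
        assert p.three_prime == (3150, 3300)
        assert p.pair_identity == 100.0

    def test_two_substitutions_identity(self, rng):
        L = random_dna(rng, 150)
        L2 = list(L)
        L2[30] = {"A": "C"}.get(L2[30], "A")
        L2[90] = {"G": "T"}.get(L2[90], "G")
        seq = L + random_dna(rng, 3000) + "".join(L2)
        pairs = detect_direct_repeats(seq)
        assert len(pairs) == 1
        assert pairs[0].pair_identity == pytest.approx(100 * 148 / 150,
                                                       abs=0.2)

    def test_repeat_free_sequences_empty(self):
        for seed in range(30):
            r = np.random.default_rng(9_000 + seed)
            assert detect_direct_repeats(random_dna(r, 3000)) == []


class TestLtrPairIdentity:
    def test_identical_arms(self, rng):
        L = random_dna(rng, 149)
        seq = L + random_dna(rng, 1000) + L
        pair = DirectRepeatPair((0, 149), (1149, 1298), 100.0)
        assert ltr_pair_identity(seq, pair) == 100.0

    def test_single_mismatch(self, rng):
        L = random_dna(rng, 149)
        L2 = list(L)
        L2[70] = "A" if L2[70] != "A" else "C"
        seq = L + random_dna(rng, 1000) + "".join(L2)
        pair = DirectRepeatPair((0, 149), (1149, 1298), 0.0)
        assert ltr_pair_identity(seq, pair) == pytest.approx(100 * 148 / 149)

    def test_indel_counts_as_column(self, rng):
        L = random_dna(rng, 100)
        L2 = L[:50] + L[51:]  # 1-nt deletion
        seq = L + random_dna(rng, 1000) + L2
        pair = DirectRepeatPair((0, 100), (1100, 1199), 0.0)
        # identity over alignment columns including the gap column
        assert ltr_pair_identity(seq, pair) == pytest.approx(100 * 99 / 100)


class TestOrfs:
    def test_minimal_forward_orf(self):
        orfs = find_orfs("ATGAAATAA", min_len_nt=3)
        fwd = [o for o in orfs if o.frame == 1]
        assert ("MK", (0, 6)) in [(o.aa_seq, o.nt_interval) for o in fwd]

    def test_reverse_strand_symmetric(self):
        orfs = find_orfs(revcomp("ATGAAATAA"), min_len_nt=3)
        assert any(o.aa_seq == "MK" and o.frame == -1 for o in orfs)

    def test_no_stop_in_reported_orfs(self, rng):
        for _ in range(10):
            orfs = find_orfs(random_dna(rng, 2000), min_len_nt=150)
            for o in orfs:
                assert "*" not in o.aa_seq
                assert o.length_nt == 3 * o.length_aa

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_scanner(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            seq = random_dna(rng, int(rng.integers(60, 500)))
            got = {(o.frame, *o.nt_interval, o.aa_seq)
                   for o in find_orfs(seq, min_len_nt=60)}
            want = oracles.orf_scan(seq, 60)
            assert got == want


class TestPrimingSignals:
    def _pair(self):
        return DirectRepeatPair((0, 150), (3150, 3300), 100.0)

    def test_ppt_found(self, rng):
        seq = random_dna(rng, 3140).replace("AAGGG", "ACTGT") + "AAGGGAGGAA" \
            + random_dna(rng, 150)
        site = detect_ppt(seq, self._pair())
        assert site is not None
        assert site.run_length >= 10

    def test_pyrimidine_window_none(self, rng):
        seq = random_dna(rng, 3140) + "TTCCTTTCCC" + random_dna(rng, 150)
        seq = seq[:3140] + "CTTCCTTCCT" + seq[3150:]
        assert detect_ppt(seq, self._pair()) is None

    def test_run_clipped_to_window(self, rng):
        # a purine run straddling the window edge counts only inside it
        head = random_dna(rng, 3110)
        head = head[:3100] + "CCCCCCCCCC"  # block upstream extension
        seq = head + "A" * 40 + random_dna(rng, 150)
        site = detect_ppt(seq, self._pair(), window=20)
        assert site.interval == (3130, 3150)
        assert site.run_length == 20

    def test_pbs_planted_trna_match(self, rng):
        trna = SequenceRecord("tRNA-Pro", random_dna(rng, 72))
        pbs = revcomp(trna.residues[-18:])
        seq = random_dna(rng, 150) + pbs + random_dna(rng, 3000)
        pair = DirectRepeatPair((0, 150), (3100, 3168), 100.0)
        sites = detect_pbs(seq, pair, [trna])
        assert [s.trna_id for s in sites] == ["tRNA-Pro"]
        assert sites[0].match_length == 18
        assert sites[0].interval == (150, 168)

    def test_pbs_no_complementarity_empty(self, rng):
        trna = SequenceRecord("tRNA-Val", random_dna(rng, 72))
        seq = random_dna(rng, 3400)
        pair = DirectRepeatPair((0, 150), (3200, 3268), 100.0)
        assert detect_pbs(seq, pair, [trna]) == []

    def test_pbs_two_matching_trnas_both_reported(self, rng):
        t1 = SequenceRecord("tRNA-Val1", random_dna(rng, 72))
        t2 = SequenceRecord("tRNA-Val2", t1.residues[:-18] + t1.residues[-18:])
        pbs = revcomp(t1.residues[-18:])
        seq = random_dna(rng, 150) + pbs + random_dna(rng, 2000)
        pair = DirectRepeatPair((0, 150), (2000, 2068), 100.0)
        sites = detect_pbs(seq, pair, [t1, t2])
        assert sorted(s.trna_id for s in sites) == ["tRNA-Val1", "tRNA-Val2"]

    def test_pbs_skipped_without_library(self, rng, caplog):
        with caplog.at_level("WARNING", logger="tecat"):
            out = detect_pbs(random_dna(rng, 500),
                             DirectRepeatPair((0, 50), (400, 450), 100.0),
                             None)
        assert out == []
        assert "skipped" in caplog.text
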