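import numpy as np
import pytest

from tecat.msa import (AlignerParams, build_consensus, progressive_align,
                       select_centroid, trim_sparse_ends, truncation_profile)
from tecat.seqio import GAP, MultipleAlignment, SequenceRecord

from conftest import mutate_subst, random_dna
import oracles


def _members(*seqs):
    return [SequenceRecord(f"m{i}", s) for i, s in enumerate(seqs)]


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self, rng):
        s = random_dna(rng, 80)
        aln = progressive_align(_members(s, s, s))
        assert aln.width == len(s)
        assert all(row == s for row in aln.rows.values())

    def test_three_prime_fragments_left_padded(self, rng):
        full = random_dna(rng, 1000)
        aln = progressive_align(_members(full, full[400:], full[500:]))
        assert aln.rows["m1"] == GAP * 400 + full[400:]
        assert aln.rows["m2"] == GAP * 500 + full[500:]
        assert aln.width == 1000

    def test_width_at_least_longest_member(self, rng):
        for _ in range(5):
            seqs = [random_dna(rng, int(rng.integers(60, 200)))
                    for _ in range(int(rng.integers(2, 6)))]
            aln = progressive_align(_members(*seqs))
            assert aln.width >= max(len(s) for s in seqs)

    def test_degapping_recovers_members(self, rng):
        base = random_dna(rng, 300)
        seqs = [mutate_subst(base, 0.05, rng) for _ in range(4)]
        seqs.append(base[120:])
        members = _members(*seqs)
        aln = progressive_align(members)
        for m in members:
            assert aln.degapped(m.id) == m.residues

    def test_single_member_rejected(self, rng):
        with pytest.raises(ValueError):
            progressive_align(_members(random_dna(rng, 100)))

    def test_invalid_gap_params_rejected(self):
        with pytest.raises(ValueError):
            AlignerParams(gap_open=-10, gap_extend=-50)


class TestConsensus:
    def test_identical_rows_uppercase_identity(self):
        aln = MultipleAlignment({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert build_consensus(aln).residues == "ACGT"

    def test_terminal_gap_does_not_span(self):
        # column 0: A,A,C span; the terminal-gap row does not: A wins 2/3
        aln = MultipleAlignment({"a": "AG", "b": "AG", "c": "CG", "d": "-G"})
        assert build_consensus(aln).residues[0] == "A"

    def test_tie_emits_alphabetical_lowercase(self):
        aln = MultipleAlignment({"a": "AG", "b": "AG", "c": "CG", "d": "CG"})
        assert build_consensus(aln).residues[0] == "a"

    def test_minority_span_lowercase(self):
        # only 1 of 3 rows spans the first 2 columns
        aln = MultipleAlignment({"a": "ACGGG", "b": "--GGG", "c": "--GGG"})
        cons = build_consensus(aln)
        assert cons.residues == "acGGG"

    def test_majority_internal_gap_drops_column(self):
        aln = MultipleAlignment({"a": "A-G", "b": "A-G", "c": "ACG"})
        assert build_consensus(aln).residues == "AG"

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_counting_oracle_on_random_alignments(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            width = int(rng.integers(5, 40))
            rows = {}
            for i in range(n):
                lead = int(rng.integers(0, width // 2))
                trail = int(rng.integers(0, (width - lead) // 2))
                mid = "".join(rng.choice(list("ACGT-N"), width - lead - trail,
                                         p=[.22, .22, .22, .22, .06, .06]))
                # avoid accidental terminal gaps inside the random middle
                mid = "A" + mid[1:-1] + "G" if len(mid) >= 2 else "A"
                rows[f"r{i}"] = GAP * lead + mid + GAP * trail
            aln = MultipleAlignment(rows)
            assert build_consensus(aln).residues == \
                oracles.consensus(list(rows.values()))


class TestCentroid:
    def test_identical_members_tie_breaks_to_first_id(self, rng):
        s = random_dna(rng, 60)
        assert select_centroid(_members(s, s, s)) == "m0"

    def test_full_length_beats_fragments(self, rng):
        full = random_dna(rng, 120)
        members = [SequenceRecord("frag1", full[:70]),
                   SequenceRecord("full", full),
                   SequenceRecord("frag2", full[50:])]
        assert select_centroid(members) == "full"

    def test_permutation_invariant(self, rng):
        members = _members(*(random_dna(rng, 80) for _ in range(4)))
        first = select_centroid(members)
        assert select_centroid(list(reversed(members))) == first

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(4):
            n = int(rng.integers(3, 7))
            base = random_dna(rng, int(rng.integers(40, 90)))
            seqs = []
            for i in range(n):
                s = mutate_subst(base, float(rng.uniform(0, 0.3)), rng)
                lo = int(rng.integers(0, len(s) // 3))
                seqs.append(s[lo:])
            ids = [f"m{i}" for i in range(n)]
            members = [SequenceRecord(i, s) for i, s in zip(ids, seqs)]
            assert select_centroid(members) == oracles.centroid(ids, seqs)


class TestTruncationProfile:
    def test_gap_free_alignment_all_zero(self, rng):
        s = random_dna(rng, 50)
        aln = MultipleAlignment({"a": s, "b": s})
        tp = truncation_profile(aln)
        assert set(tp.leading.values()) == {0}
        assert set(tp.trailing.values()) == {0}

    def test_leading_run_counted(self):
        aln = MultipleAlignment({"a": "----ACGT", "b": "ACGTACGT"})
        tp = truncation_profile(aln)
        assert tp.leading["a"] == 4 and tp.trailing["a"] == 0

    def test_matches_regex_oracle_on_random_rows(self, rng):
        for _ in range(100):
            width = int(rng.integers(4, 60))
            row = "".join(rng.choice(list("ACGT-"), width,
                                     p=[.2, .2, .2, .2, .2]))
            other = "A" * width
            aln = MultipleAlignment({"x": row, "y": other})
            tp = truncation_profile(aln)
            lead, trail = oracles.terminal_gaps(row)
            if lead == width:  # an all-gap row has no residues at all
                continue
            assert (tp.leading["x"], tp.trailing["x"]) == (lead, trail)


class TestTrim:
    def test_sparse_ends_removed(self):
        aln = MultipleAlignment({"a": "A--ACGT", "b": "---ACGT",
                                 "c": "---ACGT", "d": "---ACGT",
                                 "e": "---ACGT", "f": "---ACGT"})
        trimmed = trim_sparse_ends(aln, max_gap_frac=0.8)
        assert trimmed.width == 4

    def test_dense_alignment_untouched(self, rng):
        s = random_dna(rng, 30)
        aln = MultipleAlignment({"a": s, "b": s})
        assert trim_sparse_ends(aln) is aln
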