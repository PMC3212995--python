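import numpy as np
import pytest

from tecat.discovery import (LocalHit, build_piles, call_families,
                             family_passes, hit_passes, read_hit_dump,
                             self_align_genome, write_hit_dump)
from tecat.seqio import GenomeInterval, SequenceRecord

from conftest import mutate_subst, random_dna
import oracles


def _genome(*parts, name="chr1"):
    return [SequenceRecord(name, "".join(parts))]


class TestSelfAlign:
    def test_random_genome_yields_no_hits(self, rng):
        g = [SequenceRecord("chr1", random_dna(rng, 50_000))]
        assert self_align_genome(g) == []

    def test_two_exact_copies_one_hit(self, rng):
        E = random_dna(rng, 600)
        g = _genome(random_dna(rng, 10_000), E, random_dna(rng, 5_000), E,
                    random_dna(rng, 10_000))
        hits = self_align_genome(g)
        assert len(hits) == 1
        h = hits[0]
        truth_a = GenomeInterval("chr1", 10_000, 10_600)
        truth_b = GenomeInterval("chr1", 15_600, 16_200)
        assert h.a.jaccard(truth_a) > 0.95
        assert h.b.jaccard(truth_b) > 0.95
        assert h.identity >= 0.99

    def test_three_exact_copies_three_hits(self, rng):
        E = random_dna(rng, 600)
        g = _genome(random_dna(rng, 5_000), E, random_dna(rng, 5_000), E,
                    random_dna(rng, 5_000), E, random_dna(rng, 5_000))
        hits = self_align_genome(g)
        # brute force: all unordered pairs of the three copies
        assert len(hits) == 3

    def test_inverted_copy_detected(self, rng):
        from tecat.seqio import revcomp
        E = random_dna(rng, 600)
        g = _genome(random_dna(rng, 5_000), E, random_dna(rng, 5_000),
                    revcomp(E), random_dna(rng, 5_000))
        hits = self_align_genome(g)
        assert len(hits) == 1
        assert hits[0].strand_relation == "inverted"

    def test_short_genome_warns_and_returns_empty(self, rng, caplog):
        g = [SequenceRecord("chr1", random_dna(rng, 100))]
        with caplog.at_level("WARNING", logger="tecat"):
            assert self_align_genome(g) == []
        assert "shorter than" in caplog.text

    def test_hit_dump_roundtrip(self, rng, tmp_path):
        E = random_dna(rng, 700)
        g = _genome(random_dna(rng, 5_000), E, random_dna(rng, 5_000), E,
                    random_dna(rng, 5_000))
        hits = self_align_genome(g)
        p = tmp_path / "hits.tsv"
        write_hit_dump(hits, p)
        back = read_hit_dump(p)
        assert [(h.a, h.b, h.strand_relation) for h in back] == \
            [(h.a, h.b, h.strand_relation) for h in hits]


def _hit(a, b, identity=0.99, rel="same"):
    return LocalHit(a, b, identity, 100.0, rel)


class TestPiles:
    def test_disjoint_intervals_two_piles(self):
        h = _hit(GenomeInterval("c", 100, 600), GenomeInterval("c", 2000, 2500))
        piles = build_piles([h])
        assert len(piles) == 2

    def test_overlap_merges(self):
        h1 = _hit(GenomeInterval("c", 100, 700), GenomeInterval("c", 5000, 5600))
        h2 = _hit(GenomeInterval("c", 650, 1300), GenomeInterval("c", 8000, 8650))
        piles = build_piles([h1, h2])
        footprints = sorted((p.footprint.start, p.footprint.end) for p in piles)
        assert (100, 1300) in footprints

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_chain_merging_matches_component_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ivs = []
        pos = 0
        for _ in range(12):
            pos += int(rng.integers(0, 800))
            width = int(rng.integers(200, 900))
            ivs.append((pos, pos + width))
            pos += width
        # random shuffling of interval order must not matter
        order = rng.permutation(len(ivs))
        hits = []
        for i in range(0, len(ivs) - 1, 2):
            a, b = ivs[order[i]], ivs[order[i + 1]]
            if a > b:
                a, b = b, a
            hits.append(_hit(GenomeInterval("c", *a), GenomeInterval("c", *b)))
        piles = build_piles(hits)
        # oracle: union-find over overlapping intervals
        used = [iv for h in hits for iv in
                ((h.a.start, h.a.end), (h.b.start, h.b.end))]
        edges = [(i, j) for i in range(len(used)) for j in range(i + 1, len(used))
                 if min(used[i][1], used[j][1]) > max(used[i][0], used[j][0])]
        comps = oracles.components(len(used), edges)
        assert len(piles) == len(comps)

    def test_chain_of_five_overlapping(self):
        ivs = [(i * 500, i * 500 + 700) for i in range(5)]
        hits = [_hit(GenomeInterval("c", *ivs[i]),
                     GenomeInterval("c", 10_000 + i * 2000, 10_700 + i * 2000))
                for i in range(5)]
        piles = build_piles(hits)
        merged = [p for p in piles if len(p) > 1000]
        assert len(merged) == 1
        assert (merged[0].footprint.start, merged[0].footprint.end) == (0, 2700)


class TestFamilies:
    def _run(self, rng, n_copies, mutate=0.0, two_families=False):
        parts = [random_dna(rng, 3_000)]
        E = random_dna(rng, 600)
        F = random_dna(rng, 700)
        for i in range(n_copies):
            seq = mutate_subst(E, mutate, rng) if mutate else E
            parts += [seq, random_dna(rng, 3_000)]
        if two_families:
            for i in range(3):
                parts += [F, random_dna(rng, 3_000)]
        g = _genome(*parts)
        hits = self_align_genome(g)
        piles = build_piles(hits)
        return call_families(piles, hits, g), g

    def test_pair_is_not_a_family(self, rng):
        fams, _ = self._run(rng, 2)
        assert fams == []

    def test_three_diverged_copies_one_family(self, rng):
        fams, g = self._run(rng, 3, mutate=0.01)
        assert len(fams) == 1
        assert len(fams[0].member_piles) == 3
        for m in fams[0].member_sequences:
            assert len(m) > 400

    def test_two_unrelated_families_stay_separate(self, rng):
        fams, _ = self._run(rng, 3, two_families=True)
        assert len(fams) == 2
        sizes = sorted(len(f.member_piles) for f in fams)
        assert sizes == [3, 3]
        # no member interval shared between the families
        fps = [set((iv.start, iv.end) for iv in f.member_footprints())
               for f in fams]
        assert not fps[0] & fps[1]

    def test_scaffold_permutation_invariance(self, rng):
        E = random_dna(rng, 600)
        s1 = SequenceRecord("s1", random_dna(rng, 4000) + E + random_dna(rng, 4000))
        s2 = SequenceRecord("s2", random_dna(rng, 3000) + E + random_dna(rng, 3000)
                            + E + random_dna(rng, 3000))

        def footprints(genome):
            hits = self_align_genome(genome)
            fams = call_families(build_piles(hits), hits, genome)
            return sorted((iv.seq_id, iv.start, iv.end)
                          for f in fams for iv in f.member_footprints())

        assert footprints([s1, s2]) == footprints([s2, s1])


class TestFilterPredicates:
    def test_hit_filter_thresholds(self):
        assert hit_passes(0.95, 401)
        assert not hit_passes(0.93, 500)
        assert not hit_passes(0.99, 399)

    def test_family_size_threshold(self):
        assert not family_passes(2)
        assert family_passes(3)
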