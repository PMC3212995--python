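import random

import pytest

from tecat.classify import (ClusterFeatures, assign_element_type,
                            classify_cluster, detect_solo_ltr,
                            link_tir_subfamilies)
from tecat.seqio import SequenceRecord, revcomp
from tecat.signatures import DirectRepeatPair, InvertedRepeat, OpenReadingFrame

from conftest import mutate_subst, random_dna


def _summary(positive, subject="hit1"):
    return {"positive": positive, "best_match": subject if positive else "",
            "e_value": 1e-30 if positive else 1.0}


def _features(rng, **kw):
    defaults = dict(cluster_id=0, consensus=random_dna(rng, 2000))
    defaults.update(kw)
    return ClusterFeatures(**defaults)


class TestDecisionLadder:
    def test_ltr_pair_plus_rvt_gives_order_ltr(self, rng):
        f = _features(
            rng,
            ltr_pairs=[DirectRepeatPair((0, 150), (1850, 2000), 100.0)],
            orfs=[OpenReadingFrame(1, (200, 1700), "M" * 500)],
            summaries={"RVT": _summary(True)},
            library_roles={"RVT": "domain"})
        c = classify_cluster(f)
        assert (c.te_class, c.order) == ("I", "LTR")
        rules = [r for r, _ in c.evidence]
        assert "terminal direct repeat pair" in rules
        assert "reverse-transcriptase domain" in rules

    def test_rvt_without_ltr_pair_gives_nltr(self, rng):
        f = _features(rng, summaries={"RVT": _summary(True)},
                      library_roles={"RVT": "domain"})
        c = classify_cluster(f)
        assert (c.te_class, c.order) == ("I", "NLTR")

    def test_tirs_plus_transposase_gives_class_ii(self, rng):
        f = _features(
            rng,
            inverted_repeats=[InvertedRepeat((0, 30), (1970, 2000), 1.0,
                                             "terminal")],
            summaries={"transposase": _summary(True)},
            library_roles={"transposase": "domain"})
        c = classify_cluster(f)
        assert (c.te_class, c.order) == ("II", "TIR")

    def test_small_tir_element_without_hits_is_mite_like_novel(self, rng):
        cons = random_dna(rng, 450)
        f = ClusterFeatures(
            0, cons,
            inverted_repeats=[InvertedRepeat((0, 20), (430, 450), 1.0,
                                             "terminal")])
        c = classify_cluster(f)
        assert c.element_type == "MITE-like-novel"
        assert (c.te_class, c.order) == ("II", "TIR")

    def test_rrna_only_hit_is_non_te(self, rng):
        f = _features(rng, summaries={"rRNA_lib": _summary(True)},
                      library_roles={"rRNA_lib": "rRNA"})
        c = classify_cluster(f)
        assert c.te_class == "non-TE"
        assert c.element_type == "rRNA"

    def test_known_element_sets_superfamily_and_na_flag(self, rng):
        f = _features(
            rng,
            inverted_repeats=[InvertedRepeat((0, 30), (1970, 2000), 1.0,
                                             "terminal")],
            summaries={"repbase_like": _summary(True, "TcToy1")},
            library_roles={"repbase_like": "known_te"},
            entry_metadata={"repbase_like": {
                "TcToy1": {"order": "TIR", "superfamily": "Tc1-Mariner",
                           "na": "true"}}})
        c = classify_cluster(f)
        assert c.superfamily == "Tc1-Mariner"
        assert c.family == "TcToy1"
        assert c.element_type == "Class II-NA"

    def test_mite_via_known_family_arms(self, rng):
        arm = random_dna(rng, 25)
        cons = arm + random_dna(rng, 400) + revcomp(arm)
        f = ClusterFeatures(
            0, cons,
            inverted_repeats=[InvertedRepeat((0, 25), (425, 450), 1.0,
                                             "terminal")])
        c = classify_cluster(f, known_tir_arms=[("TcToy1", arm)])
        assert c.element_type == "MITE"
        assert c.family == "TcToy1"

    def test_no_signature_fallback(self, rng):
        c = classify_cluster(_features(rng))
        assert c.te_class == "unknown"
        assert c.element_type in {"repeat-no-signature", "fragment"}
        assert c.evidence  # every assignment carries evidence

    def test_ladder_deterministic_under_evidence_shuffle(self, rng):
        cons = random_dna(rng, 2000)
        labels = set()
        for seed in range(5):
            r = random.Random(seed)
            irs = [InvertedRepeat((0, 30), (1970, 2000), 1.0, "terminal"),
                   InvertedRepeat((400, 430), (800, 830), 0.9, "subterminal")]
            r.shuffle(irs)
            summaries = [("transposase", _summary(True)),
                         ("RVT", _summary(False))]
            r.shuffle(summaries)
            f = ClusterFeatures(0, cons, inverted_repeats=irs,
                                summaries=dict(summaries),
                                library_roles={"transposase": "domain",
                                               "RVT": "domain"})
            c = classify_cluster(f)
            labels.add((c.te_class, c.order, c.element_type))
        assert len(labels) == 1


class TestElementType:
    def _cls(self, rng, with_termini=False, with_orf=False):
        from tecat.classify import TEClassification
        c = TEClassification()
        if with_termini:
            c.add("terminal direct repeat pair", "x")
        c.activity_flags = {"full_orf_with_domains": with_orf}
        return c

    def test_identical_to_canonical_is_full(self, rng):
        canonical = SequenceRecord("can", random_dna(rng, 3000))
        c = self._cls(rng)
        label, cov = assign_element_type(canonical.residues, canonical, c)
        assert label == "full"
        assert cov == pytest.approx(1.0, abs=0.01)

    def test_small_piece_is_remnant(self, rng):
        canonical = SequenceRecord("can", random_dna(rng, 5000))
        c = self._cls(rng)
        label, cov = assign_element_type(canonical.residues[1000:1300],
                                         canonical, c)
        assert label == "remnant"
        assert cov == pytest.approx(0.06, abs=0.01)

    def test_half_element_is_fragment(self, rng):
        canonical = SequenceRecord("can", random_dna(rng, 5000))
        c = self._cls(rng)
        label, cov = assign_element_type(canonical.residues[:2500],
                                         canonical, c)
        assert label == "fragment"
        assert cov == pytest.approx(0.5, abs=0.02)

    def test_structural_full_without_canonical(self, rng):
        c = self._cls(rng, with_termini=True, with_orf=True)
        label, _ = assign_element_type(random_dna(rng, 3000), None, c)
        assert label == "full"

    def test_preassigned_type_kept(self, rng):
        from tecat.classify import TEClassification
        c = TEClassification(element_type="MITE")
        label, _ = assign_element_type(random_dna(rng, 400), None, c)
        assert label == "MITE"


class TestSoloLtr:
    def test_exact_arm_is_solo(self, rng):
        arm = random_dna(rng, 150)
        assert detect_solo_ltr(arm, [("famA", arm)])

    def test_full_element_fails_length_test(self, rng):
        arm = random_dna(rng, 150)
        element = arm + random_dna(rng, 2000) + arm
        assert not detect_solo_ltr(element, [("famA", arm)])

    def test_arm_with_small_flank_is_solo(self, rng):
        arm = random_dna(rng, 150)
        assert detect_solo_ltr(arm + random_dna(rng, 50), [("famA", arm)])


class TestTirSubfamilyLinking:
    def test_shared_arms_random_interiors_linked(self, rng):
        arm = random_dna(rng, 25)
        c1 = (1, arm + random_dna(rng, 500) + revcomp(arm), arm)
        c2 = (2, arm + random_dna(rng, 700) + revcomp(arm), arm)
        assert link_tir_subfamilies([c1, c2]) == [[1, 2]]

    def test_unrelated_arms_unlinked(self, rng):
        c1 = (1, random_dna(rng, 500), random_dna(rng, 25))
        c2 = (2, random_dna(rng, 500), random_dna(rng, 25))
        assert link_tir_subfamilies([c1, c2]) == []

    def test_chained_identity_closes_transitively(self, rng):
        arm = random_dna(rng, 30)
        arm_b = mutate_subst(arm, 0.1, rng)
        clusters = [(i, arm_x + random_dna(rng, 400) + revcomp(arm_x), arm_x)
                    for i, arm_x in [(1, arm), (2, arm), (3, arm_b)]]
        groups = link_tir_subfamilies(clusters)
        assert groups == [[1, 2, 3]]

    def test_similar_interiors_not_subfamilies(self, rng):
        # whole-consensus identity >= 0.5 means same family, not subfamilies
        arm = random_dna(rng, 25)
        body = random_dna(rng, 500)
        c1 = (1, arm + body + revcomp(arm), arm)
        c2 = (2, arm + mutate_subst(body, 0.05, rng) + revcomp(arm), arm)
        assert link_tir_subfamilies([c1, c2]) == []
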