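"""Grouping of discovered repeat copies into family clusters.

Primary pass: single-linkage clustering at >90% identity over >=90% of the
length of the shorter sequence (the shorter-sequence denominator lets
fragments join their family).  Components of fewer than 3 members are
reported as unclustered records, not clusters.

Relaxed pass: clusters whose consensus sequences share translated-space
similarity (best of the 6x6 frame pairs) are linked at a ladder of identity
thresholds over >=50% of the shorter consensus, emulating a tblastx
comparison; the link set is nested across thresholds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from ._align import infix_identity, local_alignment_stats, protein_local_aligner
from .seqio import SequenceRecord, logger, six_frame_translations

DEFAULT_RELAXED_THRESHOLDS = (0.35, 0.50, 0.75, 0.90)


@dataclass
class Cluster:
    id: int
    member_ids: list[str]
    linked_cluster_ids: dict[float, list[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.member_ids)


def edge_passes(identity: float, coverage: float, id_min: float = 0.90,
                cov_min: float = 0.90) -> bool:
    """The clustering edge rule: identity strictly above id_min over at
    least cov_min of the shorter sequence."""
    return identity > id_min and coverage >= cov_min


def pair_qualifies(a: SequenceRecord, b: SequenceRecord, id_min: float = 0.90,
                   cov_min: float = 0.90) -> bool:
    """Edge rule applied to two sequences: the infix alignment of the
    shorter inside the longer consumes the whole shorter sequence, so its
    coverage is 1 and only the identity is decisive."""
    return edge_passes(infix_identity(a.residues, b.residues), 1.0,
                       id_min, cov_min)


def cluster_sequences(seqs: list[SequenceRecord], id_min: float = 0.90,
                      cov_min: float = 0.90, min_members: int = 3,
                      edge_fn=None) -> tuple[list[Cluster], list[str]]:
    """Single-linkage components over the qualifying-pair graph.

    Returns (clusters, unclustered_member_ids); deterministic and
    order-independent (members are canonically sorted by id first).
    """
    order = sorted(seqs, key=lambda s: s.id)
    ids = [s.id for s in order]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in clustering input")
    edge = edge_fn or (lambda a, b: pair_qualifies(a, b, id_min, cov_min))
    parent = list(range(len(order)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in combinations(range(len(order)), 2):
        if find(i) != find(j) and edge(order[i], order[j]):
            ri, rj = find(i), find(j)
            parent[max(ri, rj)] = min(ri, rj)

    comps: dict[int, list[str]] = {}
    for i in range(len(order)):
        comps.setdefault(find(i), []).append(ids[i])
    clusters: list[Cluster] = []
    unclustered: list[str] = []
    for root in sorted(comps):
        members = comps[root]
        if len(members) >= min_members:
            clusters.append(Cluster(len(clusters), members))
        else:
            unclustered.extend(members)
    logger.info("clustering: %d sequences -> %d clusters, %d unclustered",
                len(seqs), len(clusters), len(unclustered))
    return clusters, unclustered


def translated_similarity(a: str, b: str, cov_min: float = 0.50
                          ) -> tuple[float, float]:
    """Best six-frame x six-frame protein local alignment of two nucleotide
    sequences: the maximal identity over frame pairs whose aligned span
    covers >= cov_min of the shorter sequence.  Returns (identity, coverage
    at that frame pair); (0, 0) when no frame pair reaches the coverage."""
    aligner = protein_local_aligner()
    fa = six_frame_translations(a)
    fb = six_frame_translations(b)
    shorter = min(len(a), len(b))
    best = (0.0, 0.0)
    for pa in fa.values():
        for pb in fb.values():
            st = local_alignment_stats(aligner, pa, pb)
            if st is None:
                continue
            span = (st["query_span"] if len(a) <= len(b) else st["target_span"])
            cov = min((span[1] - span[0]) / max(shorter // 3, 1), 1.0)
            if cov >= cov_min and st["identity"] > best[0]:
                best = (st["identity"], cov)
    return best


def relaxed_link_pass(clusters: list[Cluster],
                      consensi: dict[int, SequenceRecord],
                      thresholds=DEFAULT_RELAXED_THRESHOLDS,
                      cov_min: float = 0.50) -> list[dict]:
    """Translated-space linkage between cluster consensus sequences.

    For every threshold t, clusters are linked when the best translated
    alignment reaches identity >= t with coverage >= cov_min of the shorter
    consensus.  One (identity, coverage) value is computed per pair, so the
    link set at a higher threshold is a subset of that at a lower one.
    Clusters without a consensus are skipped with a warning.
    """
    thresholds = sorted(thresholds)
    usable = []
    for c in clusters:
        if c.id in consensi:
            usable.append(c)
        else:
            logger.warning("relaxed pass: cluster %s has no consensus; skipped", c.id)
    links: list[dict] = []
    for ca, cb in combinations(usable, 2):
        ident, cov = translated_similarity(consensi[ca.id].residues,
                                           consensi[cb.id].residues, cov_min)
        if cov < cov_min:
            continue
        for t in thresholds:
            if ident >= t:
                links.append({"threshold": t, "cluster_a": ca.id,
                              "cluster_b": cb.id, "identity": ident,
                              "coverage": cov})
                ca.linked_cluster_ids.setdefault(t, []).append(cb.id)
                cb.linked_cluster_ids.setdefault(t, []).append(ca.id)
    return links


def write_membership(clusters: list[Cluster], unclustered: list[str],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember_id\n")
        for c in clusters:
            for m in c.member_ids:
                fh.write(f"{c.id}\t{m}\n")
        for m in unclustered:
            fh.write(f"unclustered\t{m}\n")


def write_linkage(links: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tcluster_a\tcluster_b\tidentity\tcoverage\n")
        for l in links:
            fh.write(f"{l['threshold']}\t{l['cluster_a']}\t{l['cluster_b']}\t"
                     f"{l['identity']:.4f}\t{l['coverage']:.4f}\n")
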