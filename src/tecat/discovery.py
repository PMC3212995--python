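"""Dispersed-repeat discovery by genome self-alignment and pile condensation.

The self-aligner is a banded seed-and-extend aligner: exact k-mer seeds on
both strand relations, chaining of co-diagonal seeds, and gapped refinement
of each chained candidate with edlib.  Only the hit contract matters to the
rest of the pipeline (coordinates of substring pairs sharing >=94% identity
over >=400 bp by default), so an external aligner producing the same
12-column hit table can be dropped in via `read_hit_dump`.

Overlapping hit footprints are condensed into piles; piles connected by hits
that cover >=90% of both footprints become dispersed families with >=3
members.  Piles whose two hit ends fall inside the same pile are flagged
tandem and excluded from dispersed-family calling.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from ._align import KA_NUC_1_3, evalue, parse_cigar
from .seqio import (GenomeInterval, SequenceRecord, extract_interval, logger,
                    revcomp)


def hit_passes(identity: float, length: int, min_identity: float = 0.94,
               min_len: int = 400) -> bool:
    """The discovery filter: a local self-alignment counts only when it
    reaches the identity floor over at least the minimum copy length."""
    return identity >= min_identity and length >= min_len


def family_passes(n_members: int, min_members: int = 3) -> bool:
    """Dispersed families need three or more copies."""
    return n_members >= min_members


@dataclass
class LocalHit:
    """One off-diagonal local self-alignment (stored once, a before b)."""

    a: GenomeInterval
    b: GenomeInterval
    identity: float
    score: float
    strand_relation: str  # same | inverted

    def footprints(self) -> tuple[GenomeInterval, GenomeInterval]:
        return self.a, self.b


@dataclass
class Pile:
    """Union of overlapping hit footprints on one scaffold."""

    id: int
    footprint: GenomeInterval
    member_hit_ids: list[int] = field(default_factory=list)
    tandem: bool = False

    def __len__(self) -> int:
        return len(self.footprint)


@dataclass
class RepeatFamily:
    id: int
    member_piles: list[int]
    member_sequences: list[SequenceRecord]
    footprints: list[GenomeInterval]

    def member_footprints(self) -> list[GenomeInterval]:
        return self.footprints


def _base_codes(seq: str) -> np.ndarray:
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(idx.shape, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[idx == b] = i
    return code


def _kmer_codes(code: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers; -1 where the window contains non-ACGT."""
    n = len(code) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        w = code[j:j + n]
        out = out * 4 + np.maximum(w, 0)
        bad |= w < 0
    out[bad] = -1
    return out


def _groups_by_code(codes: np.ndarray, max_occ: int):
    """Yield position arrays sharing the same valid k-mer code (count>=2)."""
    valid = np.flatnonzero(codes >= 0)
    order = valid[np.argsort(codes[valid], kind="stable")]
    vals = codes[order]
    breaks = np.flatnonzero(np.diff(vals)) + 1
    start = 0
    for stop in list(breaks) + [len(vals)]:
        if 2 <= stop - start <= max_occ:
            yield order[start:stop]
        start = stop


def _chain_pairs(p1: np.ndarray, p2: np.ndarray, k: int, chain_gap: int,
                 diag_band: int) -> list[tuple[int, int, int, int]]:
    """Chain co-diagonal seed pairs into candidate segment pairs.

    Returns (a_start, a_end, b_start, b_end) spans (end exclusive, includes k).
    """
    if len(p1) == 0:
        return []
    diag = p2 - p1
    order = np.lexsort((p1, diag))
    p1, p2, diag = p1[order], p2[order], diag[order]
    new_seg = np.empty(len(p1), dtype=bool)
    new_seg[0] = True
    new_seg[1:] = (np.diff(diag) != 0) | (np.diff(p1) > chain_gap)
    seg_id = np.cumsum(new_seg) - 1
    nseg = seg_id[-1] + 1
    a_lo = np.full(nseg, np.iinfo(np.int64).max)
    a_hi = np.zeros(nseg, dtype=np.int64)
    np.minimum.at(a_lo, seg_id, p1)
    np.maximum.at(a_hi, seg_id, p1 + k)
    d = np.zeros(nseg, dtype=np.int64)
    d[seg_id] = diag
    segs = sorted(zip(d.tolist(), a_lo.tolist(), a_hi.tolist()))
    # merge chain fragments of the same copy pair: group by diagonal band,
    # then stitch fragments that are adjacent along the a-axis (indels shift
    # the diagonal by a few nt and break exact-diagonal chains)
    merged: list[tuple[int, int, int]] = []
    i = 0
    while i < len(segs):
        j = i + 1
        while j < len(segs) and segs[j][0] - segs[j - 1][0] <= diag_band:
            j += 1
        group = sorted(segs[i:j], key=lambda s: s[1])
        cur = list(group[0])
        for dg, lo, hi in group[1:]:
            if lo <= cur[2] + chain_gap:
                cur[2] = max(cur[2], hi)
            else:
                merged.append(tuple(cur))
                cur = [dg, lo, hi]
        merged.append(tuple(cur))
        i = j
    return [(lo, hi, lo + dg, hi + dg) for dg, lo, hi in merged]


def _refine(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(identity, score) of the global alignment of a candidate pair."""
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    eq, x, ins, dele = parse_cigar(res["cigar"])
    cols = eq + x + ins + dele
    identity = eq / cols if cols else 0.0
    score = eq - 3 * (x + ins + dele)
    return identity, float(score)


def self_align_genome(genome: list[SequenceRecord], min_identity: float = 0.94,
                      min_hit_len: int = 400, k: int = 14, max_occ: int = 200,
                      chain_gap: int = 120, diag_band: int = 16
                      ) -> list[LocalHit]:
    """All off-diagonal local self-alignments above the identity/length floor.

    Hits are emitted once with canonical ordering (a before b in genome
    coordinates); both strand relations are searched.
    """
    if not genome:
        raise ValueError("genome is empty")
    offsets: list[int] = []
    names: list[str] = []
    cursor = 0
    parts = []
    for rec in genome:
        offsets.append(cursor)
        names.append(rec.id)
        parts.append(rec.residues)
        cursor += len(rec.residues)
    concat = "".join(parts)
    total = len(concat)
    if total < min_hit_len:
        logger.warning("genome (%d nt) shorter than min_hit_len=%d; no hits",
                       total, min_hit_len)
        return []
    starts = offsets
    ends = [o + len(r.residues) for o, r in zip(offsets, genome)]

    def scaffold_of(pos: int) -> int:
        return bisect.bisect_right(starts, pos) - 1

    def to_interval(lo: int, hi: int, strand: str = "+") -> GenomeInterval | None:
        si = scaffold_of(lo)
        if hi > ends[si]:  # crosses a scaffold boundary
            return None
        return GenomeInterval(names[si], lo - starts[si], hi - starts[si], strand)

    code = _base_codes(concat)
    codes_f = _kmer_codes(code, k)

    hits: list[LocalHit] = []
    seen: set[tuple] = set()

    # --- same-strand relation ---
    P1, P2 = [], []
    for grp in _groups_by_code(codes_f, max_occ):
        grp = np.sort(grp)
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                P1.append(grp[i])
                P2.append(grp[j])
    cands = _chain_pairs(np.asarray(P1, dtype=np.int64),
                         np.asarray(P2, dtype=np.int64), k, chain_gap, diag_band)
    for alo, ahi, blo, bhi in cands:
        la, lb = ahi - alo, bhi - blo
        if min(la, lb) < min_hit_len:
            continue
        overlap = max(0, min(ahi, bhi) - max(alo, blo))
        if overlap > 0.5 * min(la, lb):
            continue  # self-diagonal / tandem-overlap exclusion
        iva = to_interval(alo, ahi)
        ivb = to_interval(blo, bhi)
        if iva is None or ivb is None:
            continue
        identity, score = _refine(concat[alo:ahi], concat[blo:bhi])
        if not hit_passes(identity, min(la, lb), min_identity, min_hit_len):
            continue
        key = (iva.seq_id, iva.start, iva.end, ivb.seq_id, ivb.start, ivb.end, "same")
        if key in seen:
            continue
        seen.add(key)
        hits.append(LocalHit(iva, ivb, identity, score, "same"))

    # --- inverted relation: forward k-mers vs k-mers of the reverse strand ---
    rc = revcomp(concat)
    codes_r = _kmer_codes(_base_codes(rc), k)
    both = np.concatenate([codes_f, codes_r])
    src = np.concatenate([np.zeros(len(codes_f), dtype=np.int8),
                          np.ones(len(codes_r), dtype=np.int8)])
    pos = np.concatenate([np.arange(len(codes_f)), np.arange(len(codes_r))])
    valid = np.flatnonzero(both >= 0)
    order = valid[np.argsort(both[valid], kind="stable")]
    vals = both[order]
    breaks = np.flatnonzero(np.diff(vals)) + 1
    P1, P2 = [], []
    start = 0
    for stop in list(breaks) + [len(vals)]:
        grp = order[start:stop]
        start = stop
        if not (2 <= len(grp) <= 2 * max_occ):
            continue
        f = pos[grp[src[grp] == 0]]
        r = pos[grp[src[grp] == 1]]
        for pf in f:
            for pr in r:
                P1.append(pf)
                P2.append(pr)
    cands = _chain_pairs(np.asarray(P1, dtype=np.int64),
                         np.asarray(P2, dtype=np.int64), k, chain_gap, diag_band)
    for alo, ahi, rlo, rhi in cands:
        blo, bhi = total - rhi, total - rlo  # map back to forward coordinates
        if bhi <= alo:  # canonical: keep the copy pair once, a before b
            alo, ahi, blo, bhi = blo, bhi, alo, ahi
        la, lb = ahi - alo, bhi - blo
        if min(la, lb) < min_hit_len:
            continue
        overlap = max(0, min(ahi, bhi) - max(alo, blo))
        if overlap > 0.5 * min(la, lb):
            continue
        iva = to_interval(alo, ahi)
        ivb = to_interval(blo, bhi)
        if iva is None or ivb is None:
            continue
        identity, score = _refine(concat[alo:ahi], revcomp(concat[blo:bhi]))
        if not hit_passes(identity, min(la, lb), min_identity, min_hit_len):
            continue
        key = (iva.seq_id, iva.start, iva.end, ivb.seq_id, ivb.start, ivb.end, "inv")
        if key in seen:
            continue
        seen.add(key)
        hits.append(LocalHit(iva, ivb, identity, score, "inverted"))

    hits.sort(key=lambda h: (h.a.seq_id, h.a.start, h.b.seq_id, h.b.start))
    logger.info("self-alignment: %d hits (identity>=%.2f, len>=%d)",
                len(hits), min_identity, min_hit_len)
    return hits


def build_piles(hits: list[LocalHit]) -> list[Pile]:
    """Condense overlapping hit footprints into per-scaffold piles."""
    endpoints: list[tuple[str, int, int, int]] = []  # (scaffold, start, end, hit)
    for hi, hit in enumerate(hits):
        for iv in hit.footprints():
            endpoints.append((iv.seq_id, iv.start, iv.end, hi))
    endpoints.sort()
    piles: list[Pile] = []
    cur: list | None = None  # [seq_id, start, end, hit_ids]
    for seq_id, s, e, hi in endpoints:
        if cur is not None and seq_id == cur[0] and s <= cur[2]:
            cur[2] = max(cur[2], e)
            cur[3].append(hi)
        else:
            if cur is not None:
                piles.append(Pile(len(piles),
                                  GenomeInterval(cur[0], cur[1], cur[2]),
                                  cur[3]))
            cur = [seq_id, s, e, [hi]]
    if cur is not None:
        piles.append(Pile(len(piles), GenomeInterval(cur[0], cur[1], cur[2]),
                          cur[3]))
    # tandem flag: a hit whose two ends land in the same pile
    locator = _PileLocator(piles)
    for hit in hits:
        pa = locator.find(hit.a)
        pb = locator.find(hit.b)
        if pa is not None and pa == pb:
            piles[pa].tandem = True
    return piles


class _PileLocator:
    def __init__(self, piles: list[Pile]):
        self._by_scaffold: dict[str, tuple[list[int], list[int]]] = {}
        self._ids: dict[str, list[int]] = {}
        for p in piles:
            sid = p.footprint.seq_id
            st, en = self._by_scaffold.setdefault(sid, ([], []))
            st.append(p.footprint.start)
            en.append(p.footprint.end)
            self._ids.setdefault(sid, []).append(p.id)

    def find(self, iv: GenomeInterval) -> int | None:
        if iv.seq_id not in self._by_scaffold:
            return None
        starts, ends = self._by_scaffold[iv.seq_id]
        i = bisect.bisect_right(starts, iv.start) - 1
        if i >= 0 and iv.start < ends[i]:
            return self._ids[iv.seq_id][i]
        return None


def call_families(piles: list[Pile], hits: list[LocalHit],
                  genome: list[SequenceRecord], min_members: int = 3,
                  min_len: int = 400, cov_frac: float = 0.90
                  ) -> list[RepeatFamily]:
    """Group piles into dispersed families by globally-alignable linkage.

    Two piles are linked when some hit's two footprints each cover
    >= cov_frac of their pile; families are connected components with
    >= min_members piles.  Member sequences are extracted on the + strand.
    """
    usable = {p.id for p in piles
              if len(p) >= min_len and not p.tandem}
    locator = _PileLocator(piles)
    parent = {pid: pid for pid in usable}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for hit in hits:
        pa = locator.find(hit.a)
        pb = locator.find(hit.b)
        if pa is None or pb is None or pa == pb:
            continue
        if pa not in usable or pb not in usable:
            continue
        cov_a = hit.a.overlap(piles[pa].footprint) / len(piles[pa])
        cov_b = hit.b.overlap(piles[pb].footprint) / len(piles[pb])
        if cov_a >= cov_frac and cov_b >= cov_frac:
            union(pa, pb)

    components: dict[int, list[int]] = {}
    for pid in sorted(usable):
        components.setdefault(find(pid), []).append(pid)

    lookup = {rec.id: rec for rec in genome}
    families: list[RepeatFamily] = []
    for root in sorted(components):
        member_ids = components[root]
        if not family_passes(len(member_ids), min_members):
            continue
        fid = len(families)
        seqs, fps = [], []
        for pid in member_ids:
            fp = piles[pid].footprint
            rec = extract_interval(lookup, fp)
            rec.id = f"fam{fid}_p{pid}_{fp.seq_id}:{fp.start}-{fp.end}"
            seqs.append(rec)
            fps.append(fp)
        families.append(RepeatFamily(fid, member_ids, seqs, fps))
    logger.info("family calling: %d piles -> %d dispersed families",
                len(piles), len(families))
    return families


def write_hit_dump(hits: list[LocalHit], path: str | Path) -> None:
    """12-column (outfmt-6-style) dump; inverted hits use s.start > s.end."""
    with open(path, "w") as fh:
        for h in hits:
            length = max(len(h.a), len(h.b))
            mism = int(round((1 - h.identity) * length))
            if h.strand_relation == "same":
                ss, se = h.b.start + 1, h.b.end
            else:
                ss, se = h.b.end, h.b.start + 1
            ev = evalue(h.score, len(h.a), len(h.b), KA_NUC_1_3)
            fh.write("\t".join(map(str, [
                h.a.seq_id, h.b.seq_id, f"{h.identity * 100:.2f}", length,
                mism, 0, h.a.start + 1, h.a.end, ss, se,
                f"{ev:.2e}", f"{h.score:.1f}"])) + "\n")


def read_hit_dump(path: str | Path) -> list[LocalHit]:
    """Adapter for external aligners emitting the same 12-column hit tuple."""
    hits: list[LocalHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ValueError(f"{path}:{ln}: expected 12 columns, got {len(f)}")
            qs, qe = int(f[6]) - 1, int(f[7])
            ss, se = int(f[8]), int(f[9])
            if ss <= se:
                b = GenomeInterval(f[1], ss - 1, se)
                rel = "same"
            else:
                b = GenomeInterval(f[1], se - 1, ss)
                rel = "inverted"
            hits.append(LocalHit(GenomeInterval(f[0], qs, qe), b,
                                 float(f[2]) / 100.0, float(f[11]), rel))
    return hits
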