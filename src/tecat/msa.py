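"""Longest-first progressive multiple alignment, consensus and centroid.

Cluster members are sorted by decreasing length; the two longest are aligned
first and every shorter member is then aligned onto the running profile.
This handles clusters mixing full-length elements with fragments from
different regions of the same element, which defeat ordinary guide-tree
aligners.  The profile aligner is an affine-gap (Gotoh) dynamic program with
free terminal gaps, honouring the prescribed gap parameters
(gap open -500, gap extend -50) against a +300/-300 match/mismatch profile
scale.

The consensus keeps, at every column, the nucleotide present in more than
half of the sequences spanning that position -- independently of how many
sequences span it -- which yields the longest possible consensus; positions
spanned by fewer than half of all members (or without a majority base) are
written in lowercase.  The centroid is the member with the highest sum of
all-to-all local alignment scores, an empirical representative kept
alongside the consensus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._align import local_alignment_stats, nucleotide_local_aligner
from .seqio import GAP, MultipleAlignment, SequenceRecord, logger

NEG = -10 ** 9


@dataclass
class AlignerParams:
    center: float = -1.0
    gap_open: float = -500.0
    gap_extend: float = -50.0
    match: float = 300.0
    mismatch: float = -300.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")


@dataclass
class ConsensusSequence:
    residues: str  # over {A,C,G,T,N,a,c,g,t,n}
    cluster_id: int | str | None = None
    column_map: list[int] = field(default_factory=list)  # consensus pos -> column

    def __len__(self) -> int:
        return len(self.residues)

    def record(self, prefix: str = "consensus") -> SequenceRecord:
        return SequenceRecord(f"{prefix}_{self.cluster_id}", self.residues.upper())


@dataclass
class TruncationProfile:
    leading: dict[str, int]
    trailing: dict[str, int]
    rendering: str


@dataclass
class LengthStats:
    longest: int
    shortest: int
    consensus_len: int
    ratio: float


_BASE_IDX = {b: i for i, b in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_IDX.get(c, 4) for c in seq], dtype=np.int64)


def _profile_align(rows: list[str], seq: str, params: AlignerParams
                   ) -> tuple[list[str], str]:
    """Align one sequence onto a profile (gapped rows); free terminal gaps."""
    n = len(rows[0])
    m = len(seq)
    nrows = len(rows)
    # per-column residue counts (A,C,G,T; N and gaps score 0)
    counts = np.zeros((n, 4), dtype=np.float64)
    for r in rows:
        e = _encode(r.replace(GAP, "N"))  # gaps -> neutral for scoring
        for b in range(4):
            counts[:, b] += (e == b)
    sub = np.full((4, 5), params.mismatch)
    np.fill_diagonal(sub, params.match)
    sub[:, 4] = 0.0
    col_scores = counts @ sub / nrows  # (n, 5): profile column vs base
    s_enc = _encode(seq)

    go, ge = params.gap_open, params.gap_extend
    M = np.full((n + 1, m + 1), NEG, dtype=np.float64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.float64)  # gap in seq
    Y = np.full((n + 1, m + 1), NEG, dtype=np.float64)  # gap in profile
    M[0, 0] = 0.0
    Y[0, 1:] = 0.0  # free leading overhang of the sequence
    X[1:, 0] = 0.0  # free leading overhang of the profile
    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = col_scores[i - 1, s_enc] + prev_best[:-1]
        X[i, 1:] = np.maximum.reduce([M[i - 1, 1:] + go, X[i - 1, 1:] + ge,
                                      Y[i - 1, 1:] + go])
        # Y via prefix scan: affine gap opened from M/X anywhere to the left
        mx = np.maximum(M[i, :-1], X[i, :-1])
        g = mx + go - ge * np.arange(1, m + 1)
        Y[i, 1:] = np.maximum.accumulate(g) + ge * js

    # free trailing gaps: best cell on the last row or last column
    last_row = np.maximum(np.maximum(M[n], X[n]), Y[n])
    last_col = np.maximum(np.maximum(M[:, m], X[:, m]), Y[:, m])
    if last_row.max() >= last_col.max():
        i, j = n, int(last_row.argmax())
    else:
        i, j = int(last_col.argmax()), m
    ops: list[str] = []
    ops.extend("Y" * (m - j))  # trailing seq overhang
    ops.extend("X" * (n - i))  # trailing profile overhang
    state = max((M[i, j], "M"), (X[i, j], "X"), (Y[i, j], "Y"))[1]
    while i > 0 or j > 0:
        if i == 0:
            ops.append("Y")
            j -= 1
            continue
        if j == 0:
            ops.append("X")
            i -= 1
            continue
        if state == "M":
            ops.append("M")
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state = "MXY"[int(np.argmax(prev))]
            i -= 1
            j -= 1
        elif state == "X":
            ops.append("X")
            v = X[i, j]
            if abs(v - (X[i - 1, j] + ge)) < 1e-6:
                state = "X"
            elif abs(v - (M[i - 1, j] + go)) < 1e-6:
                state = "M"
            else:
                state = "Y"
            i -= 1
        else:
            ops.append("Y")
            v = Y[i, j]
            if abs(v - (Y[i, j - 1] + ge)) < 1e-6 and j > 1:
                state = "Y"
            elif abs(v - (M[i, j - 1] + go)) < 1e-6:
                state = "M"
            else:
                state = "X" if X[i, j - 1] > M[i, j - 1] else "M"
            j -= 1
    ops.reverse()

    new_rows = [[] for _ in rows]
    new_seq: list[str] = []
    pi = si = 0
    for op in ops:
        if op == "M":
            for rr, r in zip(new_rows, rows):
                rr.append(r[pi])
            new_seq.append(seq[si])
            pi += 1
            si += 1
        elif op == "X":
            for rr, r in zip(new_rows, rows):
                rr.append(r[pi])
            new_seq.append(GAP)
            pi += 1
        else:  # Y: insert a gap column into the profile
            for rr in new_rows:
                rr.append(GAP)
            new_seq.append(seq[si])
            si += 1
    return ["".join(r) for r in new_rows], "".join(new_seq)


def progressive_align(members: list[SequenceRecord],
                      params: AlignerParams | None = None,
                      source_cluster=None) -> MultipleAlignment:
    """Longest-first progressive profile alignment of cluster members."""
    if len(members) < 2:
        raise ValueError("progressive alignment needs >= 2 members")
    params = params or AlignerParams()
    order = sorted(members, key=lambda s: (-len(s), s.id))
    rows = [order[0].residues]
    ids = [order[0].id]
    for rec in order[1:]:
        rows, new_row = _profile_align(rows, rec.residues, params)
        rows.append(new_row)
        ids.append(rec.id)
    aln = MultipleAlignment(dict(zip(ids, rows)), source_cluster=source_cluster)
    for rec in members:  # every input must be recoverable from its row
        assert aln.degapped(rec.id) == rec.residues
    return aln


def _terminal_gap_mask(row: str) -> np.ndarray:
    """True where the position belongs to a leading/trailing gap run."""
    mask = np.zeros(len(row), dtype=bool)
    lead = len(row) - len(row.lstrip(GAP))
    trail = len(row) - len(row.rstrip(GAP))
    mask[:lead] = True
    if trail:
        mask[len(row) - trail:] = True
    return mask


def build_consensus(aln: MultipleAlignment, majority: float = 0.5,
                    cluster_id=None) -> ConsensusSequence:
    """Majority-rule consensus with lowercase low-confidence positions.

    Spanning rows at a column are those whose residues extend across it
    (internal gaps span, terminal gap runs do not).  A column emits the base
    held by more than `majority` of the spanning rows; it is dropped when
    the deletion state wins; lowercase marks positions spanned by fewer than
    half of all rows or without a strict majority base (plurality emitted,
    alphabetical tie-break).
    """
    ids = aln.ids()
    rows = [aln.rows[i] for i in ids]
    nrows = len(rows)
    width = aln.width
    spanning = np.zeros(width, dtype=np.int64)
    base_counts = np.zeros((width, 5), dtype=np.int64)  # A C G T N
    gap_counts = np.zeros(width, dtype=np.int64)
    for row in rows:
        term = _terminal_gap_mask(row)
        enc = _encode(row.replace(GAP, "N"))
        isgap = np.frombuffer(row.encode(), dtype=np.uint8) == ord(GAP)
        span = ~term
        spanning += span
        gap_counts += span & isgap
        for b in range(5):
            base_counts[:, b] += span & ~isgap & (enc == b)
    out: list[str] = []
    col_map: list[int] = []
    for j in range(width):
        sp = spanning[j]
        if sp == 0:
            continue
        if gap_counts[j] * 2 > sp:
            continue  # deletion state wins; column dropped
        acgt = base_counts[j, :4]
        if acgt.sum() == 0:
            base, has_majority = "N", base_counts[j, 4] * 2 > sp
        else:
            b = int(acgt.argmax())  # argmax takes the alphabetically first tie
            base = "ACGT"[b]
            has_majority = acgt[b] > majority * sp
        upper = has_majority and sp * 2 >= nrows
        out.append(base if upper else base.lower())
        col_map.append(j)
    return ConsensusSequence("".join(out), cluster_id, col_map)


def all_vs_all_scores(members: list[SequenceRecord]) -> np.ndarray:
    """Symmetric matrix of pairwise local alignment scores (zero diagonal)."""
    aligner = nucleotide_local_aligner()
    n = len(members)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(members[i].residues, members[j].residues)
            mat[i, j] = mat[j, i] = s
    return mat


def select_centroid(members: list[SequenceRecord],
                    score_matrix: np.ndarray | None = None) -> str:
    """Member id with the highest sum of all-to-all alignment scores.

    Ties break toward the longest sequence, then the smallest id, so the
    choice is invariant under member order permutation.
    """
    if score_matrix is None:
        score_matrix = all_vs_all_scores(members)
    sums = score_matrix.sum(axis=1)
    ranked = sorted(range(len(members)),
                    key=lambda i: (-sums[i], -len(members[i]), members[i].id))
    return members[ranked[0]].id


def compare_consensus_centroid(cons: ConsensusSequence,
                               centroid_seq: SequenceRecord) -> dict:
    """Local-alignment identity plus length ratio of consensus vs centroid."""
    st = local_alignment_stats(nucleotide_local_aligner(),
                               cons.residues.upper(), centroid_seq.residues)
    if st is None:
        return {"identity": 0.0, "length_ratio":
                len(cons) / len(centroid_seq), "low_coverage": True}
    span = st["query_span"][1] - st["query_span"][0]
    cov = span / min(len(cons), len(centroid_seq))
    return {"identity": st["identity"],
            "length_ratio": len(cons) / len(centroid_seq),
            "low_coverage": cov < 0.5}


def truncation_profile(aln: MultipleAlignment) -> TruncationProfile:
    """Terminal gap-run counts per member: the 5'/3' deletion pattern."""
    leading: dict[str, int] = {}
    trailing: dict[str, int] = {}
    lines = []
    width = aln.width
    scale = max(width // 60, 1)
    for rid, row in aln.rows.items():
        lead = len(row) - len(row.lstrip(GAP))
        trail = len(row) - len(row.rstrip(GAP))
        leading[rid] = lead
        trailing[rid] = trail
        bar = ("." * (lead // scale)
               + "=" * max((width - lead - trail) // scale, 1)
               + "." * (trail // scale))
        lines.append(f"{rid:<40s} 5'gaps={lead:<6d} 3'gaps={trail:<6d} {bar}")
    return TruncationProfile(leading, trailing, "\n".join(lines) + "\n")


def length_stats(members: list[SequenceRecord],
                 cons: ConsensusSequence) -> LengthStats:
    lens = [len(m) for m in members]
    return LengthStats(max(lens), min(lens), len(cons),
                       max(lens) / min(lens))


def trim_sparse_ends(aln: MultipleAlignment, max_gap_frac: float = 0.8
                     ) -> MultipleAlignment:
    """Trim terminal alignment columns where > max_gap_frac of rows are gaps
    (automatic stand-in for by-eye end curation); logged."""
    ids = aln.ids()
    rows = [aln.rows[i] for i in ids]
    n = len(rows)
    width = aln.width
    gap_frac = [sum(r[j] == GAP for r in rows) / n for j in range(width)]
    lo = 0
    while lo < width and gap_frac[lo] > max_gap_frac:
        lo += 1
    hi = width
    while hi > lo and gap_frac[hi - 1] > max_gap_frac:
        hi -= 1
    if lo == 0 and hi == width:
        return aln
    logger.info("trimmed %d sparse end column(s) from alignment %s",
                width - (hi - lo), aln.source_cluster)
    return MultipleAlignment({i: aln.rows[i][lo:hi] for i in ids},
                             source_cluster=aln.source_cluster)
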