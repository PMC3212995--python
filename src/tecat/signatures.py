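"""Structural TE signature detection on element/consensus sequences.

Inverted repeats are found by comparing a sequence against its own reverse
complement (exact 8-mer seeds, ungapped +1/-1 extension with maximal-span
trimming), then classified by geometry: terminal (TIR) when the arms occupy
the first and last 10% of the sequence, palindromic when near-adjacent arms
cover most of the sequence, sub-terminal otherwise.  Reported IRs must also
clear a Karlin-Altschul-style E-value cutoff computed against an i.i.d.
null, so that multi-kb sequences do not accumulate chance micro-IRs --
the same statistical gating a BLAST-based two-sequence comparison applies.

Direct terminal repeats (LTR candidates) are same-strand off-diagonal
self-matches whose two copies fall in the terminal 20% windows.  ORFs are
stop-to-stop segments in all six frames (no start-codon requirement, since
degenerate TE copies lose their starts).  PPT/PBS are the reverse-
transcription priming signals flanked by the LTRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._align import KA_NUC_1_2, evalue, global_identity
from .discovery import _chain_pairs
from .seqio import SequenceRecord, logger, revcomp, translate


@dataclass
class InvertedRepeat:
    arm1: tuple[int, int]  # 0-based half-open, arm1 before arm2
    arm2: tuple[int, int]
    arm_identity: float
    geometry: str = "subterminal"  # terminal | subterminal | palindromic
    e_value: float = 0.0

    @property
    def arm_len(self) -> int:
        return self.arm1[1] - self.arm1[0]


@dataclass
class DirectRepeatPair:
    five_prime: tuple[int, int]
    three_prime: tuple[int, int]
    pair_identity: float  # percent


@dataclass
class OpenReadingFrame:
    frame: int  # +1..+3, -1..-3
    nt_interval: tuple[int, int]  # forward-strand coordinates
    aa_seq: str

    @property
    def length_aa(self) -> int:
        return len(self.aa_seq)

    @property
    def length_nt(self) -> int:
        return self.nt_interval[1] - self.nt_interval[0]


@dataclass
class PptSite:
    interval: tuple[int, int]
    run_length: int


@dataclass
class PbsSite:
    interval: tuple[int, int]
    trna_id: str
    match_length: int


def _seed_matches(seq: str, target: str, k: int):
    """All (i, j) with seq[i:i+k] == target[j:j+k]."""
    index: dict[str, list[int]] = {}
    for j in range(len(target) - k + 1):
        index.setdefault(target[j:j + k], []).append(j)
    for i in range(len(seq) - k + 1):
        for j in index.get(seq[i:i + k], ()):
            yield i, j


def _extend_ungapped(a: str, b: str, i: int, j: int, k: int,
                     xdrop: int = 12) -> tuple[int, int, int, int]:
    """Extend an exact k-seed at (a[i:], b[j:]) in both directions, +1/-1
    scoring, trimming to the maximal-scoring span (ties extend outward).
    Returns (start_offset, end_offset, matches, length) relative to i/j."""
    # right extension (+1/-2: random sequence cannot drift the span outward)
    best_r, best_score = k, k
    score = k
    li = min(len(a) - i, len(b) - j)
    p = k
    while p < li and score > best_score - xdrop:
        score += 1 if a[i + p] == b[j + p] else -2
        p += 1
        if score >= best_score:  # >= : prefer the longer span on ties
            best_score, best_r = score, p
    # left extension
    best_l, best_score2 = 0, 0
    score = 0
    q = 0
    lim = min(i, j)
    while q < lim and score > best_score2 - xdrop:
        q += 1
        score += 1 if a[i - q] == b[j - q] else -2
        if score >= best_score2:
            best_score2, best_l = score, q
    start, end = -best_l, best_r
    length = end - start
    matches = sum(1 for t in range(start, end) if a[i + t] == b[j + t])
    return start, end, matches, length


def detect_inverted_repeats(seq: str | SequenceRecord, min_arm: int = 10,
                            min_arm_identity: float = 0.80,
                            e_max: float = 0.1, k: int = 8
                            ) -> list[InvertedRepeat]:
    """Inverted repeats of seq, mapped back to forward coordinates.

    Mirrored duplicates are collapsed; matches crossing a palindrome center
    are split into two adjacent arms.
    """
    if isinstance(seq, SequenceRecord):
        seq = seq.residues
    L = len(seq)
    if L < 2 * min_arm:
        return []
    rc = revcomp(seq)
    space = L * L / 2.0
    found: dict[tuple, InvertedRepeat] = {}
    covered: set[tuple[int, int]] = set()
    for i, j in _seed_matches(seq, rc, k):
        d = j - i
        if (d, i) in covered:
            continue
        start, end, matches, length = _extend_ungapped(seq, rc, i, j, k)
        for t in range(start, end):
            covered.add((d, i + t))
        if length < min_arm:
            continue
        identity = matches / length
        if identity < min_arm_identity:
            continue
        score = matches - 2 * (length - matches)
        ev = evalue(score, L, L, KA_NUC_1_2) / 2.0
        if e_max is not None and ev > e_max:
            continue
        i0, i1 = i + start, i + end
        j0, j1 = j + start, j + end
        a2 = (L - j1, L - j0)
        a1 = (i0, i1)
        if a1[0] > a2[0]:
            a1, a2 = a2, a1
        if a1 == a2 or (a1[1] > a2[0] and a2[0] - a1[0] == a1[1] - a2[0]):
            # self-mirrored match across a palindrome center: split in half
            mid_lo = (a1[0] + a2[1]) // 2
            half = (a2[1] - a1[0]) // 2
            a1 = (a1[0], a1[0] + half)
            a2 = (a2[1] - half, a2[1])
            del mid_lo
        elif a1[1] > a2[0]:
            trim = (a1[1] - a2[0] + 1) // 2
            a1 = (a1[0], a1[1] - trim)
            a2 = (a2[0] + trim, a2[1])
        if a1[1] - a1[0] < min_arm or a2[1] - a2[0] < min_arm:
            continue  # palindrome split / overlap trim can shorten the arms
        key = (a1, a2)
        if key not in found or found[key].arm_identity < identity:
            found[key] = InvertedRepeat(a1, a2, identity, e_value=ev)
    irs = sorted(found.values(), key=lambda r: (r.arm1, r.arm2))
    for ir in irs:
        ir.geometry = classify_geometry(ir, L)
    return irs


def classify_geometry(ir: InvertedRepeat, seq_len: int,
                      term_frac: float = 0.10) -> str:
    """terminal / palindromic / sub-terminal geometry of an IR."""
    gap = ir.arm2[0] - ir.arm1[1]
    arms_span = (ir.arm1[1] - ir.arm1[0]) + (ir.arm2[1] - ir.arm2[0])
    if gap <= 0.10 * seq_len and arms_span >= 0.80 * seq_len:
        return "palindromic"
    if (ir.arm1[0] < term_frac * seq_len
            and ir.arm2[1] > (1 - term_frac) * seq_len):
        return "terminal"
    return "subterminal"


def _best_diagonal_span(a: str, b: str, i: int, j: int, lo: int, hi: int
                        ) -> tuple[int, int, int, int]:
    """Maximal-scoring (+1/-2, ties to the longer span) ungapped segment on
    the diagonal through (i, j), searched within offsets [lo, hi).
    Returns (start, end, matches, length) as offsets relative to i/j."""
    lo = max(lo, -min(i, j))
    hi = min(hi, min(len(a) - i, len(b) - j))
    best = (0, lo, lo)  # (score, start, end)
    cur_score, cur_start = 0, lo
    for t in range(lo, hi):
        cur_score += 1 if a[i + t] == b[j + t] else -2
        if cur_score <= 0:
            cur_score, cur_start = 0, t + 1
            continue
        cand = (cur_score, cur_start, t + 1)
        if (cand[0], cand[2] - cand[1]) >= (best[0], best[2] - best[1]):
            best = cand
    score, start, end = best
    matches = sum(1 for t in range(start, end) if a[i + t] == b[j + t])
    return start, end, matches, end - start


def detect_direct_repeats(seq: str | SequenceRecord, min_len: int = 80,
                          min_identity: float = 0.85, k: int = 12,
                          term_frac: float = 0.20) -> list[DirectRepeatPair]:
    """Same-strand terminal repeat pairs (LTR candidates).

    Off-diagonal self-matches whose two copies both fall in the terminal
    `term_frac` windows and whose lengths agree within 20%.
    """
    if isinstance(seq, SequenceRecord):
        seq = seq.residues
    L = len(seq)
    if L <= 2 * min_len:
        return []
    P1, P2 = [], []
    for i, j in _seed_matches(seq, seq, k):
        if j - i >= min_len:  # strictly off-diagonal, one orientation
            P1.append(i)
            P2.append(j)
    cands = _chain_pairs(np.asarray(P1, dtype=np.int64),
                         np.asarray(P2, dtype=np.int64), k,
                         chain_gap=150, diag_band=12)
    out: list[DirectRepeatPair] = []
    seen = set()
    for alo, ahi, blo, bhi in cands:
        # refine the seed bounding box to the maximal-scoring ungapped span
        pad = 200
        start, end, matches, length = _best_diagonal_span(
            seq, seq, alo, blo, -pad, (ahi - alo) + pad)
        alo2, ahi2 = alo + start, alo + end
        blo2, bhi2 = blo + start, blo + end
        la, lb = ahi2 - alo2, bhi2 - blo2
        if min(la, lb) < min_len:
            continue
        if abs(la - lb) > 0.2 * min(la, lb):
            continue
        if bhi2 <= alo2 or blo2 < ahi2:  # arms must not overlap
            continue
        if not (alo2 < term_frac * L and bhi2 > (1 - term_frac) * L):
            continue
        ident = global_identity(seq[alo2:ahi2], seq[blo2:bhi2])
        if ident < min_identity:
            continue
        key = (alo2, ahi2, blo2, bhi2)
        if key in seen:
            continue
        seen.add(key)
        out.append(DirectRepeatPair((alo2, ahi2), (blo2, bhi2), ident * 100.0))
    out.sort(key=lambda p: (p.five_prime, p.three_prime))
    return out


def ltr_pair_identity(seq: str | SequenceRecord, pair: DirectRepeatPair
                      ) -> float:
    """Percent identity of the two arms over global-alignment columns."""
    if isinstance(seq, SequenceRecord):
        seq = seq.residues
    a = seq[pair.five_prime[0]:pair.five_prime[1]]
    b = seq[pair.three_prime[0]:pair.three_prime[1]]
    return global_identity(a, b) * 100.0


def find_orfs(seq: str | SequenceRecord, min_len_nt: int = 300
              ) -> list[OpenReadingFrame]:
    """Stop-to-stop segments >= min_len_nt in all six frames, longest first."""
    if isinstance(seq, SequenceRecord):
        seq = seq.residues
    L = len(seq)
    rc = revcomp(seq)
    out: list[OpenReadingFrame] = []
    for sign, s in ((1, seq), (-1, rc)):
        for off in range(3):
            aa = translate(s[off:])
            start = 0
            for seg in aa.split("*"):
                if 3 * len(seg) >= min_len_nt and seg:
                    nt_lo = off + 3 * start
                    nt_hi = nt_lo + 3 * len(seg)
                    if sign == 1:
                        iv = (nt_lo, nt_hi)
                    else:
                        iv = (L - nt_hi, L - nt_lo)
                    out.append(OpenReadingFrame(sign * (off + 1), iv, seg))
                start += len(seg) + 1
    out.sort(key=lambda o: (-o.length_aa, o.frame, o.nt_interval))
    return out


def longest_orf(seq: str | SequenceRecord) -> OpenReadingFrame | None:
    orfs = find_orfs(seq, min_len_nt=3)
    return orfs[0] if orfs else None


def detect_ppt(seq: str | SequenceRecord, ltr_pair: DirectRepeatPair,
               min_run: int = 8, window: int = 20) -> PptSite | None:
    """Longest purine (A/G) run within `window` nt upstream of the 3' LTR."""
    if isinstance(seq, SequenceRecord):
        seq = seq.residues
    s3 = ltr_pair.three_prime[0]
    lo = max(0, s3 - window)
    region = seq[lo:s3]
    best_len, best_start = 0, None
    run_start = None
    for idx, c in enumerate(region + "$"):
        if c in "AG":
            if run_start is None:
                run_start = idx
        else:
            if run_start is not None and idx - run_start > best_len:
                best_len, best_start = idx - run_start, run_start
            run_start = None
    if best_len >= min_run:
        return PptSite((lo + best_start, lo + best_start + best_len), best_len)
    return None


def detect_pbs(seq: str | SequenceRecord, ltr_pair: DirectRepeatPair,
               trna_lib: list[SequenceRecord] | None, min_match: int = 8,
               window: int = 20, tail: int = 18) -> list[PbsSite]:
    """Reverse-complement matches between the region just downstream of the
    5' LTR and the 3'-terminal `tail` nt of any library tRNA."""
    if not trna_lib:
        logger.warning("PBS detection skipped: no tRNA library supplied")
        return []
    if isinstance(seq, SequenceRecord):
        seq = seq.residues
    e5 = ltr_pair.five_prime[1]
    region = seq[e5:e5 + window + tail]
    out: list[PbsSite] = []
    for trna in trna_lib:
        probe = revcomp(trna.residues[-tail:])
        best = None  # (length, start)
        for m in range(len(probe), min_match - 1, -1):
            for off in range(len(probe) - m + 1):
                sub = probe[off:off + m]
                pos = region.find(sub)
                while pos != -1:
                    if pos <= window:
                        best = (m, pos)
                        break
                    pos = region.find(sub, pos + 1)
                if best:
                    break
            if best:
                break
        if best:
            m, pos = best
            out.append(PbsSite((e5 + pos, e5 + pos + m), trna.id, m))
    out.sort(key=lambda p: (p.interval, p.trna_id))
    return out


def ir_alignment_text(seq: str | SequenceRecord,
                      irs: list[InvertedRepeat]) -> str:
    """Human-readable rendering of each IR: arm1 against revcomp(arm2)."""
    if isinstance(seq, SequenceRecord):
        seq = seq.residues
    lines = []
    for n, ir in enumerate(irs, 1):
        a = seq[ir.arm1[0]:ir.arm1[1]]
        b = revcomp(seq[ir.arm2[0]:ir.arm2[1]])
        marks = "".join("|" if x == y else " " for x, y in zip(a, b))
        lines += [
            f"IR {n}: {ir.geometry}  arm1 {ir.arm1[0] + 1}-{ir.arm1[1]}  "
            f"arm2 {ir.arm2[0] + 1}-{ir.arm2[1]}  "
            f"identity {ir.arm_identity * 100:.1f}%",
            f"  arm1          5' {a} 3'",
            f"                   {marks}",
            f"  arm2 (revcomp) 3' {b} 5'",
            "",
        ]
    return "\n".join(lines) + ("\n" if lines else "")
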