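"""Independent brute-force implementations used as oracles.

Everything here is deliberately written in the most literal way possible
(plain loops, no shared code with the package) so the implementations under
test are checked against genuinely independent logic.
"""

from __future__ import annotations

import itertools
import math
import re

CODE = {}


def _codon_table():
    # build the standard code literally from the RNA codon wheel
    bases = "TCAG"
    aas = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
           "VVVVAAAADDEEGGGG")
    table = {}
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = aas[i]
                i += 1
    return table


CODON = _codon_table()


def orf_scan(seq: str, min_len_nt: int) -> set[tuple[int, int, int, str]]:
    """All stop-to-stop six-frame segments >= min_len_nt:
    {(frame, start, end, aa)} in forward coordinates."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rc = "".join(comp[c] for c in reversed(seq))
    out = set()
    L = len(seq)
    for sign, s in ((1, seq), (-1, rc)):
        for off in range(3):
            aa_chunks = []
            pos = off
            cur = []
            while pos + 3 <= len(s):
                codon = s[pos:pos + 3]
                aa = CODON.get(codon, "X")
                if aa == "*":
                    aa_chunks.append((pos - 3 * len(cur), "".join(cur)))
                    cur = []
                else:
                    cur.append(aa)
                pos += 3
            aa_chunks.append((pos - 3 * len(cur), "".join(cur)))
            for start, aa in aa_chunks:
                if aa and 3 * len(aa) >= min_len_nt:
                    lo, hi = start, start + 3 * len(aa)
                    if sign == -1:
                        lo, hi = L - hi, L - lo
                    out.add((sign * (off + 1), lo, hi, aa))
    return out


def consensus(rows: list[str], majority: float = 0.5) -> str:
    """Literal restatement of the consensus rules."""
    n = len(rows)
    width = len(rows[0])
    lead = [len(r) - len(r.lstrip("-")) for r in rows]
    trail = [len(r) - len(r.rstrip("-")) for r in rows]
    out = []
    for j in range(width):
        spanning = [i for i in range(n)
                    if lead[i] <= j < width - trail[i]]
        if not spanning:
            continue
        gaps = sum(1 for i in spanning if rows[i][j] == "-")
        if gaps * 2 > len(spanning):
            continue
        counts = {}
        for b in "ACGT":
            counts[b] = sum(1 for i in spanning if rows[i][j] == b)
        if sum(counts.values()) == 0:
            n_count = sum(1 for i in spanning if rows[i][j] == "N")
            has_majority = n_count * 2 > len(spanning)
            base = "N"
        else:
            top = max(counts.values())
            base = min(b for b in "ACGT" if counts[b] == top)
            has_majority = top > majority * len(spanning)
        upper = has_majority and 2 * len(spanning) >= n
        out.append(base if upper else base.lower())
    return "".join(out)


def smith_waterman_score(a: str, b: str, match=1.0, mismatch=-3.0,
                         gap_open=-5.0, gap_ext=-2.0) -> float:
    """Plain O(nm) affine-gap local alignment score (Gotoh)."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (left)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (up)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_ext)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_ext)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def centroid(ids: list[str], seqs: list[str]) -> str:
    """Brute-force argmax of all-to-all local score sums; ties to the
    longest sequence then the smallest id."""
    n = len(ids)
    sums = [0.0] * n
    for i in range(n):
        for j in range(n):
            if i != j:
                sums[i] += smith_waterman_score(seqs[i], seqs[j])
    order = sorted(range(n), key=lambda i: (-sums[i], -len(seqs[i]), ids[i]))
    return ids[order[0]]


def terminal_gaps(row: str) -> tuple[int, int]:
    lead = re.match(r"-*", row).end()
    trail = re.search(r"-*$", row).start()
    return lead, len(row) - trail


def p_distance_pairs(rows: list[str]) -> list[float]:
    out = []
    for a, b in itertools.combinations(rows, 2):
        comp = diff = 0
        for x, y in zip(a, b):
            if x in "ACGT" and y in "ACGT":
                comp += 1
                if x != y:
                    diff += 1
        if comp:
            out.append(diff / comp)
    return out


def tajima_d(rows: list[str]) -> float:
    n = len(rows)
    width = len(rows[0])
    S = 0
    for j in range(width):
        states = set()
        for r in rows:
            if r[j] in "ACGT":
                states.add(r[j])
        if len(states) >= 2:
            S += 1
    diffs = []
    for a, b in itertools.combinations(rows, 2):
        diffs.append(sum(1 for x, y in zip(a, b)
                         if x in "ACGT" and y in "ACGT" and x != y))
    pi = sum(diffs) / len(diffs)
    if S == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def components(n: int, edges: list[tuple[int, int]]) -> list[frozenset]:
    """Transitive closure by repeated sweeps (deliberately naive)."""
    groups = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            ga = next(g for g in groups if a in g)
            gb = next(g for g in groups if b in g)
            if ga is not gb:
                groups.remove(gb)
                ga |= gb
                changed = True
    return [frozenset(g) for g in groups]
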