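"""Shared pairwise-alignment primitives.

Two engines are used: edlib for fast edit-distance alignments with extended
cigars (identity/coverage bookkeeping on long nucleotide pairs), and
Bio.Align.PairwiseAligner for scored local/global alignments, including
BLOSUM62 protein alignments for the translated search modes.

E-values follow the ungapped Karlin-Altschul form E = K * m * n * exp(-lambda*S)
with the standard parameter sets for the scoring schemes used here; they are
used for ranking and thresholding, not for byte-agreement with any external
search engine.
"""

from __future__ import annotations

import math
import re
from functools import lru_cache

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

_CIG = re.compile(r"(\d+)([=XIDM])")

# Ungapped Karlin-Altschul parameters (lambda, K) per scoring scheme.
KA_NUC_1_3 = (1.374, 0.711)     # match +1 / mismatch -3
KA_NUC_1_2 = (1.3326, 0.28)     # match +1 / mismatch -2
KA_NUC_1_1 = (math.log(3.0), 0.333)  # match +1 / mismatch -1
KA_BLOSUM62 = (0.3176, 0.134)


def evalue(score: float, m: int, n: int, params=KA_NUC_1_3) -> float:
    lam, k = params
    return k * m * n * math.exp(-lam * score)


def parse_cigar(cigar: str) -> tuple[int, int, int, int]:
    """Return (matches, mismatches, insertions, deletions) from an edlib cigar."""
    eq = x = ins = dele = 0
    for num, op in _CIG.findall(cigar):
        num = int(num)
        if op == "=":
            eq += num
        elif op in "XM":
            x += num
        elif op == "I":
            ins += num
        elif op == "D":
            dele += num
    return eq, x, ins, dele


def edlib_identity(query: str, target: str, mode: str = "NW") -> float:
    """Identity over alignment columns (gap columns count against identity)."""
    res = edlib.align(query, target, mode=mode, task="path")
    eq, x, ins, dele = parse_cigar(res["cigar"])
    cols = eq + x + ins + dele
    return eq / cols if cols else 0.0


def infix_identity(shorter: str, longer: str) -> float:
    """Identity of the best placement of `shorter` inside `longer` (edlib HW).

    The whole shorter sequence is consumed, so coverage of the shorter
    sequence is 1 by construction; this is the workhorse behind the
    identity-over->=90%-of-the-shorter clustering rule.
    """
    if len(shorter) > len(longer):
        shorter, longer = longer, shorter
    res = edlib.align(shorter, longer, mode="HW", task="path")
    eq, x, ins, dele = parse_cigar(res["cigar"])
    cols = eq + x + ins + dele
    return eq / cols if cols else 0.0


@lru_cache(maxsize=None)
def nucleotide_local_aligner() -> Align.PairwiseAligner:
    """blastn-like local scoring: +1/-3, gap open 5, extend 2."""
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1.0
    a.mismatch_score = -3.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -2.0
    return a


@lru_cache(maxsize=None)
def nucleotide_global_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -1.0
    return a


@lru_cache(maxsize=None)
def protein_local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def local_alignment_stats(aligner: Align.PairwiseAligner, query: str,
                          target: str) -> dict | None:
    """Best local alignment of query vs target.

    Returns a dict with score, identity (over aligned columns), aligned
    column count, and 0-based half-open spans on query and target, or None
    when no positive-scoring alignment exists.
    """
    if not query or not target:
        return None
    alns = aligner.align(query, target)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    qspan = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    tspan = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    return {
        "score": float(aln.score),
        "identity": counts.identities / cols if cols else 0.0,
        "columns": cols,
        "identities": counts.identities,
        "query_span": qspan,
        "target_span": tspan,
    }


def global_identity(a: str, b: str) -> float:
    """Global (end-to-end) percent identity over all alignment columns, in [0,1]."""
    return edlib_identity(a, b, mode="NW")
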