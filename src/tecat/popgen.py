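"""Evolutionary diagnostics per cluster.

Three statistics summarise the dynamics of each repeat family from its
multiple alignment: the pairwise p-distance (proportion of differing sites,
gaps/N deleted pairwise), the Nei-Gojobori (1986) dN/dS with Jukes-Cantor
correction computed on the in-frame codon alignment of the family's longest
ORF (dN/dS < 1 indicates purifying selection on a still-functional coding
region), and Tajima's D contrasting mean pairwise diversity with the
segregating-site count (strongly negative D is consistent with a recent
copy-number expansion).  Significance of D uses the beta-distribution
approximation with its two-sided 95% interval.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .seqio import GAP, MultipleAlignment, logger, revcomp, translate
from .msa import ConsensusSequence
from .signatures import OpenReadingFrame

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

#: standard-code codon table, built once (Bio translation per 3-mer is slow)
_CODON_AA = {a + b + c: translate(a + b + c)
             for a in _BASES for b in _BASES for c in _BASES}
_SYN_FRAC_CACHE: dict[str, float] = {}
_PATHWAY_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


@dataclass
class PairwiseDistanceSummary:
    mean_p: float
    sd_p: float
    n_pairs: int


@dataclass
class DnDsResult:
    dN: float
    dS: float
    ratio: float  # nan when dS == 0
    S: float  # mean synonymous sites per pair
    N: float
    Sd: float  # mean synonymous differences per pair
    Nd: float
    undefined_correction: bool = False


@dataclass
class TajimaResult:
    n: int
    S: int
    pi: float
    D: float  # nan when S == 0
    significant: bool
    p_beta: float = float("nan")


def p_distance(aln: MultipleAlignment) -> PairwiseDistanceSummary:
    """Mean/sd of pairwise p-distances with pairwise deletion of gap/N sites."""
    ids = aln.ids()
    if len(ids) < 2:
        raise ValueError("p-distance needs >= 2 rows")
    dists = []
    for a, b in itertools.combinations(ids, 2):
        ra, rb = aln.rows[a], aln.rows[b]
        comparable = mism = 0
        for x, y in zip(ra, rb):
            if x in "ACGT" and y in "ACGT":
                comparable += 1
                mism += x != y
        if comparable == 0:
            logger.warning("p-distance: pair (%s, %s) has no comparable "
                           "sites; skipped", a, b)
            continue
        dists.append(mism / comparable)
    arr = np.asarray(dists)
    return PairwiseDistanceSummary(float(arr.mean()), float(arr.std(ddof=0)),
                                   len(dists))


def _codon_syn_fraction(codon: str) -> float:
    """Fraction of the 9 single-nt changes that are synonymous; changes to
    stop codons count as nonsynonymous."""
    cached = _SYN_FRAC_CACHE.get(codon)
    if cached is not None:
        return cached
    aa = _CODON_AA[codon]
    syn = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in _STOPS and _CODON_AA[alt] == aa:
                syn += 1
    _SYN_FRAC_CACHE[codon] = syn / 3.0
    return syn / 3.0


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaging over all
    minimal mutational pathways; pathways through stop codons are excluded
    when any stop-free pathway exists."""
    cached = _PATHWAY_CACHE.get((c1, c2))
    if cached is not None:
        return cached
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    if len(diff) == 1:
        # single step: synonymous iff the amino acid is unchanged
        res = (1.0, 0.0) if _CODON_AA[c1] == _CODON_AA[c2] else (0.0, 1.0)
        _PATHWAY_CACHE[(c1, c2)] = res
        return res
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1:]
            if nxt in _STOPS:
                through_stop = True
            if _CODON_AA[cur] == _CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((through_stop, sd, nd))
    usable = [(s, n) for stop, s, n in paths if not stop]
    if not usable:
        usable = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    _PATHWAY_CACHE[(c1, c2)] = (sd, nd)
    return sd, nd


def _jc(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * math.log(1 - 4.0 * p / 3.0), False


def nei_gojobori(codon_rows: dict[str, str]) -> DnDsResult:
    """Nei-Gojobori (1986) pairwise dN/dS over an in-frame codon alignment.

    `codon_rows` maps member id to an aligned, in-frame nucleotide string
    (length divisible by 3); codons containing a gap or N in either member
    of a pair are excluded pairwise.  Distances are Jukes-Cantor corrected
    and averaged over all pairs; the ratio is mean dN / mean dS.
    """
    ids = list(codon_rows)
    width = {len(r) for r in codon_rows.values()}
    if len(width) != 1 or width.pop() % 3 != 0:
        raise ValueError("codon alignment must be rectangular with length "
                         "divisible by 3")
    per_pair = []
    undefined = False
    for a, b in itertools.combinations(ids, 2):
        ra, rb = codon_rows[a], codon_rows[b]
        S = N = Sd = Nd = 0.0
        for k in range(0, len(ra), 3):
            ca, cb = ra[k:k + 3], rb[k:k + 3]
            if any(c not in _BASES for c in ca + cb):
                continue
            if ca in _STOPS or cb in _STOPS:
                continue
            sa = _codon_syn_fraction(ca)
            sb = _codon_syn_fraction(cb)
            S += (sa + sb) / 2.0
            N += 3.0 - (sa + sb) / 2.0
            sd, nd = _pathway_counts(ca, cb)
            Sd += sd
            Nd += nd
        if S == 0 or N == 0:
            continue
        dS, u1 = _jc(Sd / S)
        dN, u2 = _jc(Nd / N)
        undefined |= u1 or u2
        per_pair.append((dN, dS, S, N, Sd, Nd))
    if not per_pair:
        return DnDsResult(float("nan"), float("nan"), float("nan"),
                          0, 0, 0, 0, True)
    arr = np.asarray(per_pair)

    def _nanmean(col: np.ndarray) -> float:
        ok = col[~np.isnan(col)]
        return float(ok.mean()) if len(ok) else float("nan")

    mdN = _nanmean(arr[:, 0])
    mdS = _nanmean(arr[:, 1])
    ratio = mdN / mdS if mdS > 0 else float("nan")
    return DnDsResult(mdN, mdS, ratio, float(arr[:, 2].mean()),
                      float(arr[:, 3].mean()), float(arr[:, 4].mean()),
                      float(arr[:, 5].mean()), undefined)


def codon_alignment_from_orf(aln: MultipleAlignment, cons: ConsensusSequence,
                             orf: OpenReadingFrame) -> dict[str, str]:
    """Project a consensus ORF back onto the alignment columns to obtain an
    in-frame codon alignment of all members (reading frame = frame of the
    cluster's longest ORF)."""
    lo, hi = orf.nt_interval
    cols = cons.column_map[lo:hi]
    rows: dict[str, str] = {}
    for rid, row in aln.rows.items():
        sub = "".join(row[c] for c in cols)
        if orf.frame < 0:
            sub = revcomp(sub.replace(GAP, "N"))
        rows[rid] = sub
    # keep whole codons only
    usable = len(next(iter(rows.values()))) // 3 * 3
    return {rid: r[:usable] for rid, r in rows.items()}


def tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajima_d(aln: MultipleAlignment) -> TajimaResult:
    """Tajima's D over the alignment columns (>= 4 rows required).

    S counts columns with >= 2 base states among rows holding a base; pi is
    the mean pairwise difference count.  D is undefined (NaN, flagged not
    significant) when S = 0.
    """
    ids = aln.ids()
    n = len(ids)
    if n < 4:
        raise ValueError("Tajima's D needs >= 4 sequences")
    rows = [aln.rows[i] for i in ids]
    width = aln.width
    S = 0
    for j in range(width):
        states = {r[j] for r in rows if r[j] in _BASES}
        if len(states) >= 2:
            S += 1
    diffs = []
    for a, b in itertools.combinations(rows, 2):
        d = sum(1 for x, y in zip(a, b)
                if x in _BASES and y in _BASES and x != y)
        diffs.append(d)
    pi = float(np.mean(diffs))
    if S == 0:
        return TajimaResult(n, 0, pi, float("nan"), False)
    k = tajima_constants(n)
    D = (pi - S / k["a1"]) / math.sqrt(k["e1"] * S + k["e2"] * S * (S - 1))

    # beta approximation for the null distribution of D (two-sided 0.05)
    dmin = (2.0 / n - 1.0 / k["a1"]) / math.sqrt(k["e2"])
    dmax = (n / (2.0 * (n - 1.0)) - 1.0 / k["a1"]) / math.sqrt(k["e2"])
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    x = (D - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    p = float(sps.beta.cdf(x, beta, alpha))
    significant = p < 0.025 or p > 0.975
    return TajimaResult(n, S, pi, D, significant, p)
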