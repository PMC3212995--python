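"""Seeded genome simulator planting TE families with known ground truth.

The simulator emulates the repeat landscape the pipeline is built for:
dispersed families (>=3 copies, >400 bp) of LTR retrotransposons (flanking
direct repeats, PBS/PPT priming signals, pol-like ORF cassette), 5'-truncated
non-LTR copies, TIR-flanked Class II elements with a transposase-like ORF,
solo LTRs left by recombination between an element's two LTRs, and short
non-coding MITEs.  Background sequence is i.i.d. with configurable GC, which
makes chance 400-bp/94%-identity alignments effectively impossible and keeps
discovery tests sharp.

ORF cassettes embed fixed synthetic 60-aa domain tags that ship with the
package (data/*_synthetic.faa), so homology-dependent classification is
testable without any external reference library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .seqio import (GenomeInterval, SequenceRecord, read_fasta, revcomp,
                    write_bed, write_fasta, logger)

_BASES = np.array(list("ACGT"))

# one fixed codon per amino acid; stop-free by construction
_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAC", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}

CASSETTE_LIBRARIES = {
    "rvt_like": "rvt_synthetic.faa",
    "transposase_like": "transposase_synthetic.faa",
}


def packaged_path(name: str) -> str:
    """Filesystem path of one of the bundled synthetic FASTA fixtures."""
    return str(resources.files("tecat.data") / name)


def packaged_fasta(name: str, molecule: str = "nucleotide"):
    """Load a bundled synthetic FASTA fixture (protein files bypass the
    DNA normalization)."""
    ref = resources.files("tecat.data") / name
    with resources.as_file(ref) as p:
        if molecule == "protein":
            from Bio import SeqIO
            return [SequenceRecord(r.id, str(r.seq).upper(), r.description)
                    for r in SeqIO.parse(str(p), "fasta")]
        return read_fasta(p)


def bundled_library_specs() -> list[dict]:
    """Library entries (report-config style) for the bundled synthetic
    domain tags; lets homology-dependent classification run offline."""
    return [
        {"name": "RVT", "path": packaged_path("rvt_synthetic.faa"),
         "molecule": "protein", "role": "domain"},
        {"name": "RVE", "path": packaged_path("rve_synthetic.faa"),
         "molecule": "protein", "role": "domain"},
        {"name": "Peptidase_A17",
         "path": packaged_path("peptidase_a17_synthetic.faa"),
         "molecule": "protein", "role": "domain"},
        {"name": "transposase",
         "path": packaged_path("transposase_synthetic.faa"),
         "molecule": "protein", "role": "domain"},
        {"name": "gag", "path": packaged_path("gag_synthetic.faa"),
         "molecule": "protein", "role": "domain"},
    ]


def _encode_protein(aa: str) -> str:
    return "".join(_CODON[a] for a in aa)


@dataclass
class FamilySpec:
    """Declarative description of one planted TE family."""

    label: str
    te_kind: str  # LTR | NLTR | TIR | MITE
    element_length: int
    copy_number: int
    ltr_len: int | None = None
    tir_len: int | None = None
    subst_rate: float = 0.01
    indel_rate: float = 0.0005
    truncation: tuple[str, int] | None = None  # ("five_prime_geometric", mean_nt)
    solo_ltr_prob: float = 0.0
    orf_cassette: str = "none"  # none | rvt_like | transposase_like
    pbs_trna: str = "tRNA-Pro"

    def __post_init__(self) -> None:
        if self.te_kind not in {"LTR", "NLTR", "TIR", "MITE"}:
            raise ValueError(f"unknown te_kind {self.te_kind!r}")
        for r in (self.subst_rate, self.indel_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("mutation rates must lie in [0, 0.2]")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.te_kind == "LTR":
            if self.ltr_len is None or self.ltr_len < 50:
                raise ValueError("LTR families require ltr_len >= 50")
        if self.te_kind in {"TIR", "MITE"}:
            if self.tir_len is None or self.tir_len < 10:
                raise ValueError("TIR/MITE families require tir_len >= 10")
        if self.orf_cassette not in {"none"} | set(CASSETTE_LIBRARIES):
            raise ValueError(f"unknown orf_cassette {self.orf_cassette!r}")


@dataclass
class TruthAnnotation:
    """Ground-truth record for one planted copy."""

    interval: GenomeInterval
    family: str
    copy_type: str  # full | truncated | solo_ltr | mite

    def label(self) -> str:
        return f"{self.family}|{self.copy_type}"


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def mutate(seq: str, subst_rate: float, indel_rate: float,
           rng: np.random.Generator) -> str:
    """Per-site substitutions plus sparse 1-3 nt indels."""
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(idx.shape, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[idx == b] = i
    hit = (rng.random(len(code)) < subst_rate) & (code >= 0)
    shift = rng.integers(1, 4, size=int(hit.sum()))
    code[hit] = (code[hit] + shift) % 4
    out = np.where(code >= 0, _BASES[np.clip(code, 0, 3)], "N")
    s = "".join(out)
    if indel_rate > 0:
        n_events = rng.poisson(indel_rate * len(s))
        for _ in range(n_events):
            pos = int(rng.integers(0, len(s)))
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                s = s[:pos] + random_dna(rng, size) + s[pos:]
            else:
                s = s[:pos] + s[pos + size:]
    return s


class _Archetype:
    """Unmutated master copy of a family, with its structural parts."""

    def __init__(self, spec: FamilySpec, rng: np.random.Generator, gc: float,
                 trna_lib: dict[str, str]):
        self.spec = spec
        cassette = ""
        if spec.orf_cassette != "none":
            tags = packaged_fasta(CASSETTE_LIBRARIES[spec.orf_cassette],
                                  molecule="protein")
            aa = "".join(t.residues for t in tags)
            # pad with random residues to a pol-like ~400-aa ORF
            filler = max(400 - len(aa), 0)
            aa += "".join(rng.choice(list(_CODON), filler))
            cassette = "ATG" + _encode_protein(aa)
        if spec.te_kind == "LTR":
            self.ltr = random_dna(rng, spec.ltr_len, gc)
            pbs = revcomp(trna_lib[spec.pbs_trna][-18:])
            ppt = "AAGGAGGGGAAGGAGG"  # purine tract upstream of the 3' LTR
            internal = spec.element_length - 2 * spec.ltr_len - len(pbs) - len(ppt)
            internal = max(internal, len(cassette) + 20)
            left = (internal - len(cassette)) // 2
            right = internal - len(cassette) - left
            body = random_dna(rng, left, gc) + cassette + random_dna(rng, right, gc)
            self.seq = self.ltr + pbs + body + ppt + self.ltr
        elif spec.te_kind in {"TIR", "MITE"}:
            self.arm = random_dna(rng, spec.tir_len, gc)
            internal = max(spec.element_length - 2 * spec.tir_len,
                           len(cassette) + 20)
            left = (internal - len(cassette)) // 2
            right = internal - len(cassette) - left
            body = random_dna(rng, left, gc) + cassette + random_dna(rng, right, gc)
            self.seq = self.arm + body + revcomp(self.arm)
        else:  # NLTR: body with the cassette in the 3' half (5' ends get lost)
            internal = max(spec.element_length, len(cassette) + 20)
            right_pad = max((internal - len(cassette)) // 5, 10)
            left = internal - len(cassette) - right_pad
            self.seq = (random_dna(rng, left, gc) + cassette
                        + random_dna(rng, right_pad, gc))

    def copies(self, rng: np.random.Generator) -> list[tuple[str, str]]:
        """Mutated copies as (sequence, copy_type) tuples."""
        spec = self.spec
        n_solo = 0
        if spec.te_kind == "LTR" and spec.solo_ltr_prob > 0:
            n_solo = int(round(spec.copy_number * spec.solo_ltr_prob))
        out: list[tuple[str, str]] = []
        for i in range(spec.copy_number):
            if i < n_solo:
                base, ctype = self.ltr, "solo_ltr"
            elif spec.te_kind == "MITE":
                base, ctype = self.seq, "mite"
            elif spec.truncation is not None:
                kind, mean = spec.truncation
                if kind != "five_prime_geometric":
                    raise ValueError(f"unknown truncation model {kind!r}")
                t = int(rng.geometric(1.0 / mean)) if mean > 0 else 0
                t = min(t, len(self.seq) // 2)
                base = self.seq[t:]
                ctype = "truncated" if t > len(self.seq) * 0.02 else "full"
            else:
                base, ctype = self.seq, "full"
            out.append((mutate(base, spec.subst_rate, spec.indel_rate, rng), ctype))
        return out


def simulate_genome(specs: list[FamilySpec], genome_length: int = 2_000_000,
                    gc: float = 0.44, seed: int = 0, n_scaffolds: int = 1,
                    min_gap: int = 500
                    ) -> tuple[list[SequenceRecord], list[TruthAnnotation]]:
    """Plant the families into i.i.d. background; deterministic under seed.

    `genome_length` is the background length before insertions; planted
    copies are inserted between background positions so every copy is
    flanked by unique sequence ("isolated").
    """
    rng = np.random.default_rng(seed)
    trna_lib = {r.id: r.residues for r in packaged_fasta("trna3_synthetic.fa")}

    all_copies: list[tuple[str, str, str]] = []  # (seq, family, copy_type)
    total_planted = 0
    for spec in specs:
        arch = _Archetype(spec, rng, gc, trna_lib)
        for seq, ctype in arch.copies(rng):
            all_copies.append((seq, spec.label, ctype))
            total_planted += len(seq)
    if total_planted >= 0.5 * genome_length:
        raise ValueError("planted length exceeds half the genome; "
                         "increase genome_length")

    # shuffle copy order so families interleave along the genome
    order = rng.permutation(len(all_copies))
    all_copies = [all_copies[i] for i in order]

    scaffold_len = genome_length // max(n_scaffolds, 1)
    backgrounds = [random_dna(rng, scaffold_len, gc) for _ in range(n_scaffolds)]
    scaffold_of = rng.integers(0, n_scaffolds, size=len(all_copies))

    records: list[SequenceRecord] = []
    truth: list[TruthAnnotation] = []
    for si in range(n_scaffolds):
        mine = [c for c, s in zip(all_copies, scaffold_of) if s == si]
        # insertion points in the background, separated by >= min_gap
        pts: list[int] = []
        attempts = 0
        while len(pts) < len(mine):
            p = int(rng.integers(min_gap, scaffold_len - min_gap))
            if all(abs(p - q) >= min_gap for q in pts):
                pts.append(p)
            attempts += 1
            if attempts > 1000 * max(len(mine), 1):
                raise RuntimeError("could not place all copies; "
                                   "use a longer genome")
        pts.sort()
        bg = backgrounds[si]
        name = f"scaffold_{si + 1}"
        parts: list[str] = []
        cursor = 0
        offset = 0
        for p, (seq, fam, ctype) in zip(pts, mine):
            parts.append(bg[cursor:p])
            start = p + offset
            parts.append(seq)
            truth.append(TruthAnnotation(
                GenomeInterval(name, start, start + len(seq)), fam, ctype))
            offset += len(seq)
            cursor = p
        parts.append(bg[cursor:])
        records.append(SequenceRecord(name, "".join(parts)))
    truth.sort(key=lambda t: (t.interval.seq_id, t.interval.start))
    logger.info("simulated %d scaffold(s), %d planted copies (%d families)",
                n_scaffolds, len(truth), len(specs))
    return records, truth


def write_truth(truth: list[TruthAnnotation], bed_path: str | Path,
                json_path: str | Path | None = None) -> None:
    write_bed([(t.interval, t.label()) for t in truth], bed_path)
    if json_path is not None:
        fams: dict[str, dict] = {}
        for t in truth:
            d = fams.setdefault(t.family, {"copies": 0, "types": {}})
            d["copies"] += 1
            d["types"][t.copy_type] = d["types"].get(t.copy_type, 0) + 1
        with open(json_path, "w") as fh:
            json.dump(fams, fh, indent=2, sort_keys=True)


def default_benchmark_specs() -> list[FamilySpec]:
    """The 12-family desk-scale benchmark configuration.

    3 LTR families (one a solo-LTR donor at probability 0.5), 3 5'-truncated
    non-LTR families with an RVT-like cassette, 3 TIR families with a
    transposase-like cassette, 3 MITE families; all at substitution rate 0.01.
    """
    specs = [
        FamilySpec("LTR_A", "LTR", 3000, 5, ltr_len=200,
                   orf_cassette="rvt_like", pbs_trna="tRNA-Pro"),
        FamilySpec("LTR_B", "LTR", 4000, 5, ltr_len=300,
                   orf_cassette="rvt_like", pbs_trna="tRNA-Val"),
        FamilySpec("LTR_C", "LTR", 2500, 10, ltr_len=250, solo_ltr_prob=0.5,
                   orf_cassette="rvt_like", pbs_trna="tRNA-Met"),
        FamilySpec("NLTR_A", "NLTR", 3000, 6, orf_cassette="rvt_like",
                   truncation=("five_prime_geometric", 150)),
        FamilySpec("NLTR_B", "NLTR", 3200, 6, orf_cassette="rvt_like",
                   truncation=("five_prime_geometric", 150)),
        FamilySpec("NLTR_C", "NLTR", 3500, 6, orf_cassette="rvt_like",
                   truncation=("five_prime_geometric", 150)),
        FamilySpec("TIR_A", "TIR", 1500, 5, tir_len=30,
                   orf_cassette="transposase_like"),
        FamilySpec("TIR_B", "TIR", 2000, 5, tir_len=40,
                   orf_cassette="transposase_like"),
        FamilySpec("TIR_C", "TIR", 2500, 5, tir_len=50,
                   orf_cassette="transposase_like"),
        FamilySpec("MITE_A", "MITE", 450, 8, tir_len=25),
        FamilySpec("MITE_B", "MITE", 520, 8, tir_len=30),
        FamilySpec("MITE_C", "MITE", 600, 8, tir_len=40),
    ]
    return specs


_STOPS = {"TAA", "TAG", "TGA"}


def simulate_selected_orfs(n_seqs: int = 10, n_codons: int = 300,
                           attempt_rate: float = 0.08, omega: float = 0.2,
                           seed: int = 0) -> dict[str, str]:
    """Coding sequences evolved under purifying selection.

    Each sequence descends independently from a random stop-free ancestor;
    proposed substitutions (per-site probability `attempt_rate`) fix with
    probability 1 when synonymous and `omega` when nonsynonymous; changes
    creating stops never fix.  Nei-Gojobori counting on the output should
    recover dN/dS ~ omega.
    """
    from .seqio import translate
    rng = np.random.default_rng(seed)
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
              if a + b + c not in _STOPS]
    anc = [codons[i] for i in rng.integers(0, len(codons), size=n_codons)]
    out: dict[str, str] = {}
    for s in range(n_seqs):
        seq = list(anc)
        for ci in range(n_codons):
            codon = seq[ci]
            for pos in range(3):
                if rng.random() >= attempt_rate:
                    continue
                alt_base = "ACGT"[rng.integers(0, 4)]
                if alt_base == codon[pos]:
                    continue
                alt = codon[:pos] + alt_base + codon[pos + 1:]
                if alt in _STOPS:
                    continue
                if translate(alt) == translate(codon):
                    codon = alt
                elif rng.random() < omega:
                    codon = alt
            seq[ci] = codon
        out[f"seq{s}"] = "".join(seq)
    return out


EXPECTED_CLASS_ORDER = {
    "LTR": ("I", "LTR"),
    "NLTR": ("I", "NLTR"),
    "TIR": ("II", "TIR"),
    "MITE": ("II", "TIR"),
}


def _reciprocal_match(a: GenomeInterval, b: GenomeInterval,
                      frac: float = 0.5) -> bool:
    ov = a.overlap(b)
    return ov >= frac * len(a) and ov >= frac * len(b)


def evaluate_discovery(truth: list[TruthAnnotation],
                       families, eligible_min_len: int = 400,
                       min_members: int = 3, frac: float = 0.5) -> dict:
    """Score discovered families against ground truth.

    A discovered member matches a truth copy by reciprocal overlap >= frac
    (one-to-one, greedy by overlap).  A planted family counts as recovered
    when a single discovered family matches a strict majority of its
    *eligible* copies -- those longer than `eligible_min_len`, which is what
    the discovery contract can see; families with fewer than `min_members`
    eligible copies are outside the contract and excluded from family-level
    recall.
    """
    members: list[tuple[int, GenomeInterval]] = []
    for fam in families:
        for iv in fam.member_footprints():
            members.append((fam.id, iv))

    eligible = [t for t in truth if len(t.interval) > eligible_min_len]
    pairs = []
    for ti, t in enumerate(eligible):
        for mi, (fid, iv) in enumerate(members):
            ov = t.interval.overlap(iv)
            if ov and _reciprocal_match(t.interval, iv, frac):
                pairs.append((ov, ti, mi))
    pairs.sort(reverse=True)
    t_used: dict[int, int] = {}
    m_used: set[int] = set()
    for ov, ti, mi in pairs:
        if ti in t_used or mi in m_used:
            continue
        t_used[ti] = mi
        m_used.add(mi)

    fam_names = sorted({t.family for t in truth})
    per_family: dict[str, dict] = {}
    recovered = 0
    denom = 0
    for name in fam_names:
        idxs = [i for i, t in enumerate(eligible) if t.family == name]
        n_elig = len(idxs)
        matched = [t_used[i] for i in idxs if i in t_used]
        votes: dict[int, int] = {}
        for mi in matched:
            fid = members[mi][0]
            votes[fid] = votes.get(fid, 0) + 1
        best = max(votes.values()) if votes else 0
        rec = n_elig >= min_members and best * 2 > n_elig
        info = {
            "eligible_copies": n_elig,
            "matched_copies": len(matched),
            "recall": len(matched) / n_elig if n_elig else float("nan"),
            "recovered": bool(rec),
            "split": len(votes) > 1,
        }
        per_family[name] = info
        if n_elig >= min_members:
            denom += 1
            recovered += rec
    tp = len(m_used)
    fp = len(members) - tp
    fn = len(eligible) - tp
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {
        "per_family": per_family,
        "family_recall": recovered / denom if denom else float("nan"),
        "copy_precision": precision,
        "copy_recall": recall,
        "copy_f1": f1,
    }
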