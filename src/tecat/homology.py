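"""Similarity annotation of consensus sequences against reference libraries.

Searches run in three modes: plain nucleotide, translated query vs protein
library (blastx-like), and translated query vs translated nucleotide library
(tblastx-like) -- the translated modes exist to catch highly diverged or
deteriorated elements.  E-values use the ungapped Karlin-Altschul form with
an effective search space of query length x total library residues; the
annotation logic downstream depends only on the positivity rule (e-value
below 1e-15) and on ranking, not on agreement with any external engine.

Hits can also be supplied as 12-column (outfmt-6-style) tables produced by
an external search engine; the positivity flag is applied on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ._align import (KA_BLOSUM62, KA_NUC_1_3, evalue, local_alignment_stats,
                     nucleotide_local_aligner, protein_local_aligner)
from .seqio import SequenceRecord, logger, read_fasta, six_frame_translations

E_POSITIVE = 1e-15


def is_positive(e_value: float, e_max: float = E_POSITIVE) -> bool:
    """The annotation positivity rule: e-value strictly below the cutoff."""
    return e_value < e_max


_MODES = {"nucleotide", "translated_x_translated", "translated_x_protein"}


@dataclass
class ReferenceLibrary:
    name: str
    molecule: str  # nucleotide | protein
    entries: list[SequenceRecord]
    role: str = ""  # free tag: e.g. rRNA, expression, known_te, domain
    metadata: dict[str, dict] = field(default_factory=dict)  # per-entry tags

    def __post_init__(self) -> None:
        if self.molecule not in {"nucleotide", "protein"}:
            raise ValueError(f"bad molecule {self.molecule!r}")
        if not self.entries:
            raise ValueError(f"library {self.name!r} is empty")

    @property
    def total_residues(self) -> int:
        return sum(len(e.residues) for e in self.entries)

    @classmethod
    def from_fasta(cls, name: str, path: str | Path, molecule: str,
                   role: str = "") -> "ReferenceLibrary":
        if molecule == "protein":
            entries = []
            from Bio import SeqIO
            for rec in SeqIO.parse(str(path), "fasta"):
                entries.append(SequenceRecord(rec.id, str(rec.seq).upper(),
                                              rec.description))
            if not entries:
                raise ValueError(f"no records in {path}")
        else:
            entries = read_fasta(path)
        return cls(name, molecule, entries, role)


@dataclass
class HomologyHit:
    query_id: str
    subject_id: str
    e_value: float
    score: float
    identity_pct: float
    query_span: tuple[int, int]  # 0-based half-open on the query (nt)
    subject_span: tuple[int, int]
    frame: int = 0  # query frame for translated modes; 0 = nucleotide
    positive: bool = False
    aln_length: int = 0
    mismatches: int = 0
    gap_opens: int = 0

    @property
    def orientation(self) -> str:
        return "-" if self.frame < 0 else "+"


def _protein_entries(library: ReferenceLibrary):
    """Subject-side protein sequences: entries themselves, or their six
    frames for a nucleotide library searched in translated mode."""
    if library.molecule == "protein":
        for e in library.entries:
            yield e.id, e.residues, 0
    else:
        for e in library.entries:
            for fr, aa in six_frame_translations(e.residues).items():
                yield e.id, aa, fr


def search_library(query: SequenceRecord, library: ReferenceLibrary,
                   mode: str = "nucleotide", e_max: float = E_POSITIVE
                   ) -> list[HomologyHit]:
    """Best local alignment per library subject, ranked by e-value.

    All hits are retained; the `positive` flag marks those below e_max.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not query.residues:
        raise ValueError("empty query")
    if mode == "nucleotide" and library.molecule != "nucleotide":
        raise ValueError("nucleotide mode needs a nucleotide library")
    if mode == "translated_x_protein" and library.molecule != "protein":
        raise ValueError("translated_x_protein mode needs a protein library")
    if mode == "translated_x_translated" and library.molecule != "nucleotide":
        raise ValueError("translated_x_translated mode needs a nucleotide library")

    n_space = library.total_residues
    hits: list[HomologyHit] = []
    if mode == "nucleotide":
        aligner = nucleotide_local_aligner()
        m_space = len(query.residues)
        for entry in library.entries:
            st = local_alignment_stats(aligner, query.residues, entry.residues)
            if st is None:
                continue
            ev = evalue(st["score"], m_space, n_space, KA_NUC_1_3)
            cols = st["columns"]
            hits.append(HomologyHit(
                query.id, entry.id, ev, st["score"], st["identity"] * 100.0,
                st["query_span"], st["target_span"], 0, is_positive(ev, e_max), cols,
                cols - st["identities"], 0))
    else:
        aligner = protein_local_aligner()
        m_space = max(len(query.residues) // 3, 1)
        if library.molecule == "nucleotide":
            n_space = max(n_space // 3, 1)
        frames = six_frame_translations(query.residues)
        L = len(query.residues)
        best_per_subject: dict[str, HomologyHit] = {}
        for sid, subject_aa, _sfr in _protein_entries(library):
            for qfr, qaa in frames.items():
                st = local_alignment_stats(aligner, qaa, subject_aa)
                if st is None:
                    continue
                ev = evalue(st["score"], m_space, n_space, KA_BLOSUM62)
                qs_aa, qe_aa = st["query_span"]
                off = abs(qfr) - 1
                if qfr > 0:
                    q_nt = (off + 3 * qs_aa, off + 3 * qe_aa)
                else:
                    q_nt = (L - off - 3 * qe_aa, L - off - 3 * qs_aa)
                cols = st["columns"]
                hit = HomologyHit(
                    query.id, sid, ev, st["score"], st["identity"] * 100.0,
                    q_nt, st["target_span"], qfr, is_positive(ev, e_max), cols,
                    cols - st["identities"], 0)
                prev = best_per_subject.get(sid)
                if prev is None or (hit.e_value, -hit.score) < (prev.e_value,
                                                                -prev.score):
                    best_per_subject[sid] = hit
        hits = list(best_per_subject.values())
    hits.sort(key=lambda h: (h.e_value, -h.score, h.subject_id))
    return hits


def write_hit_table(hits: list[HomologyHit], path: str | Path) -> None:
    """outfmt-6-style 12-column TSV (1-based inclusive spans)."""
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.query_span[0] + 1, h.query_span[1]
            ss, se = h.subject_span[0] + 1, h.subject_span[1]
            if h.frame < 0:
                ss, se = se, ss
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, f"{h.identity_pct:.2f}",
                h.aln_length, h.mismatches, h.gap_opens, qs, qe, ss, se,
                f"{h.e_value:.3e}", f"{h.score:.1f}"])) + "\n")


def load_hit_table(path: str | Path, e_max: float = E_POSITIVE
                   ) -> list[HomologyHit]:
    """Parse a 12-column hit table; the positivity flag is applied at e_max."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ValueError(
                    f"{path}:{ln}: expected 12 tab-separated columns, "
                    f"got {len(f)}")
            try:
                qs, qe = int(f[6]), int(f[7])
                ss, se = int(f[8]), int(f[9])
                ev = float(f[10])
                frame = 0 if ss <= se else -1
                hits.append(HomologyHit(
                    f[0], f[1], ev, float(f[11]), float(f[2]),
                    (qs - 1, qe), (min(ss, se) - 1, max(ss, se)), frame,
                    is_positive(ev, e_max), int(f[3]), int(f[4]), int(f[5])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed field: {exc}") from exc
    return hits


#: the 11 per-(query, library) match-summary fields
SUMMARY_FIELDS = (
    "e_value", "best_match", "score", "extent_of_match",
    "length_of_best_match", "pct_identity", "pct_match_length",
    "first_residue_of_match", "first_residue_of_sequence",
    "number_of_segments", "orientation",
)


def best_hit_summary(hits: list[HomologyHit],
                     query_length: int | None = None) -> dict:
    """11-field summary of the best hit (lowest e-value; ties by score then
    subject id); number_of_segments counts hits to the best subject."""
    if not hits:
        return {f: "" for f in SUMMARY_FIELDS} | {"positive": False}
    best = min(hits, key=lambda h: (h.e_value, -h.score, h.subject_id))
    segments = sum(1 for h in hits if h.subject_id == best.subject_id)
    extent = best.query_span[1] - best.query_span[0]
    qlen = query_length or max(h.query_span[1] for h in hits)
    return {
        "e_value": best.e_value,
        "best_match": best.subject_id,
        "score": best.score,
        "extent_of_match": extent,
        "length_of_best_match": best.aln_length,
        "pct_identity": best.identity_pct,
        "pct_match_length": 100.0 * extent / qlen if qlen else 0.0,
        "first_residue_of_match": best.subject_span[0] + 1,
        "first_residue_of_sequence": best.query_span[0] + 1,
        "number_of_segments": segments,
        "orientation": best.orientation,
        "positive": best.positive,
    }
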