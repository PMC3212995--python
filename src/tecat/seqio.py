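"""Sequence, interval and alignment containers plus FASTA/BED readers/writers.

Internal coordinate convention is 0-based half-open throughout; conversion to
1-based inclusive happens only in human-facing reports.  DNA is held uppercase
over the alphabet {A,C,G,T,N}; any other (IUPAC-ambiguity) letter is
normalized to N and the count of such replacements is logged, because the
identity computations downstream are defined over four letters and N never
counts as a match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("tecat")

DNA_ALPHABET = set("ACGTN")
GAP = "-"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an {A,C,G,T,N} string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_residues(raw: str, context: str = "") -> str:
    """Uppercase and map non-ACGTN letters to N, logging the replacement count."""
    up = raw.upper()
    n_bad = sum(1 for c in up if c not in DNA_ALPHABET)
    if n_bad:
        up = "".join(c if c in DNA_ALPHABET else "N" for c in up)
        logger.info("normalized %d ambiguous residue(s) to N%s", n_bad,
                    f" in {context}" if context else "")
    return up


@dataclass
class SequenceRecord:
    """A named DNA sequence (genome scaffold, repeat copy, consensus...)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open interval on a named scaffold."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def jaccard(self, other: "GenomeInterval") -> float:
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        union = len(self) + len(other) - ov
        return ov / union


@dataclass
class MultipleAlignment:
    """Gapped rows (member id -> aligned string), all the same length."""

    rows: dict[str, str]
    source_cluster: int | str | None = None

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        widths = {len(r) for r in self.rows.values()}
        if len(widths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {widths}")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    def degapped(self, member_id: str) -> str:
        return self.rows[member_id].replace(GAP, "")

    def ids(self) -> list[str]:
        return list(self.rows)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read unaligned FASTA; rejects gap characters and duplicate ids."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if GAP in raw or "." in raw:
            raise ValueError(
                f"gap character in unaligned FASTA record {rec.id!r} ({path})")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, normalize_residues(raw, rec.id), desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_alignment(path: str | Path, source_cluster=None) -> MultipleAlignment:
    """Read an aligned FASTA (.afa) with '-' gaps."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate row id {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper()
    return MultipleAlignment(rows, source_cluster=source_cluster)


def write_alignment(aln: MultipleAlignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, row in aln.rows.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


def extract_interval(genome: Sequence[SequenceRecord] | dict[str, SequenceRecord],
                     iv: GenomeInterval) -> SequenceRecord:
    """Extract iv from the genome; minus strand returns the reverse complement."""
    if isinstance(genome, dict):
        lookup = genome
    else:
        lookup = {rec.id: rec for rec in genome}
    if iv.seq_id not in lookup:
        raise KeyError(f"unknown scaffold {iv.seq_id!r}")
    scaffold = lookup[iv.seq_id]
    if iv.end > len(scaffold):
        raise ValueError(
            f"interval [{iv.start},{iv.end}) out of bounds for "
            f"{iv.seq_id} (length {len(scaffold)})")
    sub = scaffold.residues[iv.start:iv.end]
    if iv.strand == "-":
        sub = revcomp(sub)
    name = f"{iv.seq_id}:{iv.start}-{iv.end}({iv.strand})"
    return SequenceRecord(name, sub)


def write_bed(annotations: Iterable[tuple[GenomeInterval, str]],
              path: str | Path) -> None:
    """BED6 (0-based half-open), label in the name column, score 0."""
    with open(path, "w") as fh:
        for iv, label in annotations:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{label}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[GenomeInterval, str]]:
    out: list[tuple[GenomeInterval, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            seq_id, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((GenomeInterval(seq_id, start, end, strand), label))
    return out


def translate(seq: str) -> str:
    """Standard-code translation of an in-frame nucleotide string ('*' = stop)."""
    return str(Seq(seq[: len(seq) - len(seq) % 3]).translate())


def six_frame_translations(seq: str) -> dict[int, str]:
    """Translations of the six frames, keyed +1,+2,+3,-1,-2,-3."""
    out: dict[int, str] = {}
    rc = revcomp(seq)
    for off in range(3):
        out[off + 1] = translate(seq[off:])
        out[-(off + 1)] = translate(rc[off:])
    return out
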