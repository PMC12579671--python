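"""Sequence containers, FASTA/FASTQ I/O, translation and ORF enumeration.

Conventions used throughout the package:

* Nucleotide sequences are uppercase strings over ``{A, C, G, T, N}``.
* All intervals are 0-based, half-open internally; conversion to the
  1-based inclusive convention used in reports happens only at the
  report boundary (:meth:`Interval.to_1based`).
* ORF lengths count the ATG through the stop codon inclusive, so an
  ORF encoding ``n`` amino acids spans ``3 * (n + 1)`` nucleotides.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

NUC_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised on malformed FASTA/FASTQ input; carries the offending line."""


@dataclass
class NucSeq:
    """A nucleotide sequence record (uppercase A/C/G/T/N).

    ``quality`` optionally carries per-base Phred scores for records read
    from FASTQ; it is annotation only and never affects sequence ops.
    """

    id: str
    seq: str
    description: str = ""
    quality: str | None = None  # Phred+33 string, annotation only

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - NUC_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid nucleotide characters {sorted(bad)}"
            )
        if self.quality is not None and len(self.quality) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: sequence and quality lengths differ"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def phred_scores(self) -> list[int] | None:
        """Decoded per-base Phred scores, if qualities are present."""
        if self.quality is None:
            return None
        return [ord(c) - 33 for c in self.quality]


@dataclass
class ProtSeq:
    """An amino-acid sequence; ``*`` may appear only as the final residue."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid amino-acid characters {sorted(bad)}"
            )
        if "*" in self.seq[:-1]:
            raise ValueError(
                f"record {self.id!r}: internal stop codon in protein sequence"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def residues(self) -> str:
        """Sequence with any terminal stop stripped."""
        return self.seq.rstrip("*")


@dataclass(frozen=True)
class Interval:
    """Half-open 0-based interval with strand, on a parent sequence."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[int, int]:
        """(start, end) in the 1-based inclusive convention used in reports."""
        return self.start + 1, self.end

    @classmethod
    def from_1based(cls, start: int, end: int, strand: str = "+") -> "Interval":
        return cls(start - 1, end, strand)

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class OrfCall:
    """A located ATG-initiated open reading frame ending at its first stop.

    ``interval`` is on the parent's forward strand regardless of ``strand``;
    ``frame`` is the 0/1/2 offset on the strand-oriented sequence.
    ``length_nt`` includes the stop codon; the encoded protein excludes it.
    """

    parent_id: str
    frame: int
    strand: str
    interval: Interval
    protein: ProtSeq
    length_nt: int

    def __post_init__(self) -> None:
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if len(self.protein.residues) != self.length_nt // 3 - 1:
            raise ValueError("protein length inconsistent with length_nt")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq.upper()) - NUC_ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0) -> str:
    """Translate under the standard genetic code from the given frame.

    Trailing bases that do not fill a codon are dropped; stops render as
    ``*`` and any codon containing N renders as ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    sub = seq.upper()[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def find_orfs(
    record: NucSeq,
    min_len_nt: int = 180,
    both_strands: bool = True,
) -> list[OrfCall]:
    """All ATG-initiated ORFs ending at their first in-frame stop codon.

    Every ATG opens a candidate; the ORF runs to the first in-frame stop
    and is reported when its span (ATG through stop, inclusive) is at
    least ``min_len_nt``. ATG runs without a downstream stop are never
    reported: a truncated locus must show a premature stop, not an open
    end. Nested ORFs (in-frame internal ATGs) are all reported.

    Coordinates are on the forward strand; reverse-strand calls carry
    ``strand='-'`` with the interval still in forward coordinates.
    """
    if min_len_nt < 3:
        raise ValueError("min_len_nt must be >= 3")
    calls: list[OrfCall] = []
    strands = ["+", "-"] if both_strands else ["+"]
    n = len(record.seq)
    for strand in strands:
        oriented = record.seq if strand == "+" else reverse_complement(record.seq)
        for frame in (0, 1, 2):
            open_starts: list[int] = []
            for pos in range(frame, n - 2, 3):
                codon = oriented[pos : pos + 3]
                if codon == "ATG":
                    open_starts.append(pos)
                if codon in STOP_CODONS:
                    for start in open_starts:
                        length = pos + 3 - start
                        if length >= min_len_nt:
                            if strand == "+":
                                iv = Interval(start, pos + 3, "+")
                            else:
                                iv = Interval(n - (pos + 3), n - start, "-")
                            prot = translate(oriented[start : pos + 3])
                            calls.append(
                                OrfCall(
                                    parent_id=record.id,
                                    frame=frame,
                                    strand=strand,
                                    interval=iv,
                                    protein=ProtSeq(
                                        f"{record.id}|orf", prot
                                    ),
                                    length_nt=length,
                                )
                            )
                    open_starts = []
    calls.sort(key=lambda c: (c.interval.start, c.interval.end, c.strand))
    return calls


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucSeq]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Lowercase residues are uppercased. Malformed headers and empty
    records raise :class:`FastaParseError` naming the offending line.
    """
    records: list[NucSeq] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"empty record {header!r} at line {header_line}"
            )
        name, _, desc = header.partition(" ")
        records.append(NucSeq(name, seq, description=desc))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise FastaParseError(f"empty FASTA header at line {lineno}")
            else:
                if header is None:
                    raise FastaParseError(
                        f"sequence before any header at line {lineno}"
                    )
                chunks.append(line)
        _flush()
    counts = Counter(r.id for r in records)
    dupes = sorted(i for i, c in counts.items() if c > 1)
    if dupes:
        raise FastaParseError(f"duplicate record ids {dupes}")
    return records


def write_fasta(
    records: Iterable[NucSeq], path: str | Path, width: int = 70
) -> None:
    """Write records as wrapped FASTA; deterministic bytes for fixed input."""
    if width < 1:
        raise ValueError("width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[NucSeq]:
    """Read 4-line-record FASTQ (Sanger Phred+33); qualities retained."""
    records: list[NucSeq] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise FastaParseError(
            f"truncated FASTQ record near line {len(lines) // 4 * 4 + 1}"
        )
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise FastaParseError(f"bad FASTQ header at line {i + 1}")
        if not plus.startswith("+"):
            raise FastaParseError(f"missing '+' separator at line {i + 3}")
        if len(seq) != len(qual):
            raise FastaParseError(
                f"sequence/quality length mismatch at line {i + 2}"
            )
        name = head[1:].split()[0]
        records.append(NucSeq(name, seq, quality=qual))
    return records


def write_fastq(records: Iterable[NucSeq], path: str | Path) -> None:
    """Write FASTQ; records lacking qualities get a constant Q40."""
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def read_protein_fasta(path: str | Path) -> list[ProtSeq]:
    """Read a protein FASTA (no alphabet coercion beyond uppercase)."""
    out: list[ProtSeq] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    out.append(ProtSeq(header, "".join(chunks).upper()))
                header = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if header is not None:
        out.append(ProtSeq(header, "".join(chunks).upper()))
    return out
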