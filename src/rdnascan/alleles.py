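"""Reference-anchored comparison of extracted ORF alleles.

Alleles recovered from reads are near-identical to the reference ORF,
so a reference-anchored star alignment (each allele pairwise-aligned to
the reference, columns indexed by reference position with insertion
columns keyed to the preceding reference position) is exact and
replaces a general progressive MSA. Indels are left-normalized against
the reference so their placement in homopolymers is deterministic.

Rare indel columns (present in at most a configurable percentage of
rows, default 5%) are treated as residual sequencing errors and
reverted; substitution columns are never touched. Alleles are then
classed by substitution count (exact / one / two / two-plus) with a
separate class for frame-preserving indels, and a per-position
substitution spectrum is tabulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .align import align_nucleotide, left_normalize
from .seqcore import NucSeq

ALLELE_CLASSES = (
    "exact",
    "one_change",
    "two_change",
    "two_plus_change",
    "frame_preserving_indel",
    "frameshift_indel",
)


@dataclass
class AlleleRow:
    """One allele projected onto reference coordinates.

    ``ref_cells[i]`` is the allele base aligned to reference position
    ``i+1`` or ``-`` for a deletion; ``insertions`` maps the preceding
    1-based reference position (0 for a leading insertion) to the
    inserted bases.
    """

    id: str
    ref_cells: list[str]
    insertions: dict[int, str] = field(default_factory=dict)


@dataclass
class AnchorMatrix:
    """Star alignment of alleles against one reference."""

    reference: NucSeq
    rows: list[AlleleRow]
    excluded: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class AlleleRecord:
    id: str
    n_substitutions: int
    has_frame_preserving_indel: bool
    net_indel_nt: int
    diffs: list[tuple[int, str, str]]  # (pos_1based, ref, alt)
    allele_class: str


@dataclass
class SpectrumTable:
    """Per-position substitution counts and allele-class totals."""

    n_alleles: int
    class_totals: dict[str, int]
    substitution_counts: dict[tuple[int, str, str], int]

    def class_pct(self) -> dict[str, float]:
        if self.n_alleles == 0:
            return {c: 0.0 for c in self.class_totals}
        return {
            c: 100.0 * v / self.n_alleles
            for c, v in self.class_totals.items()
        }


def anchor_align(
    alleles: list[NucSeq],
    reference: NucSeq,
    min_identity_pct: float = 80.0,
) -> AnchorMatrix:
    """Pairwise-glocal-align every allele to the reference.

    Alleles falling below the identity floor are excluded and listed in
    ``matrix.excluded`` (callers should surface a warning).
    """
    rows: list[AlleleRow] = []
    excluded: list[str] = []
    ref_len = len(reference.seq)
    for allele in alleles:
        aln = align_nucleotide(reference, allele, mode="global")
        if aln is None or aln.identity_pct < min_identity_pct:
            excluded.append(allele.id)
            continue
        ref_aligned, alt_aligned = left_normalize(
            aln.aligned_query, aln.aligned_target
        )
        cells: list[str] = []
        insertions: dict[int, str] = {}
        ref_pos = 0
        for r, a in zip(ref_aligned, alt_aligned):
            if r == "-":
                insertions[ref_pos] = insertions.get(ref_pos, "") + a
            else:
                cells.append(a)
                ref_pos += 1
        if len(cells) != ref_len:
            excluded.append(allele.id)
            continue
        rows.append(AlleleRow(id=allele.id, ref_cells=cells,
                              insertions=insertions))
    return AnchorMatrix(reference=reference, rows=rows, excluded=excluded)


def filter_rare_indels(
    matrix: AnchorMatrix, max_freq_pct: float = 5.0
) -> AnchorMatrix:
    """Revert indel events present in at most ``max_freq_pct`` of rows.

    Rare insertions are dropped from their rows; rare deletions are
    restored to the reference base. Substitution columns are untouched.
    The operation is idempotent and monotone in the threshold.
    """
    n = matrix.n_rows
    if n == 0:
        return matrix
    ins_freq: dict[int, int] = {}
    del_freq: dict[int, int] = {}
    for row in matrix.rows:
        for pos in row.insertions:
            ins_freq[pos] = ins_freq.get(pos, 0) + 1
        for i, cell in enumerate(row.ref_cells):
            if cell == "-":
                del_freq[i] = del_freq.get(i, 0) + 1
    rare_ins = {p for p, c in ins_freq.items() if 100.0 * c / n <= max_freq_pct}
    rare_del = {i for i, c in del_freq.items() if 100.0 * c / n <= max_freq_pct}
    ref = matrix.reference.seq
    new_rows: list[AlleleRow] = []
    for row in matrix.rows:
        cells = [
            ref[i] if (cell == "-" and i in rare_del) else cell
            for i, cell in enumerate(row.ref_cells)
        ]
        insertions = {
            p: s for p, s in row.insertions.items() if p not in rare_ins
        }
        new_rows.append(AlleleRow(id=row.id, ref_cells=cells,
                                  insertions=insertions))
    return AnchorMatrix(
        reference=matrix.reference, rows=new_rows, excluded=matrix.excluded
    )


def classify_alleles(
    matrix: AnchorMatrix,
) -> tuple[list[AlleleRecord], SpectrumTable]:
    """Substitution classes, indel flags and the substitution spectrum."""
    records: list[AlleleRecord] = []
    spectrum: dict[tuple[int, str, str], int] = {}
    class_totals = {c: 0 for c in ALLELE_CLASSES}
    ref = matrix.reference.seq
    for row in matrix.rows:
        diffs: list[tuple[int, str, str]] = []
        n_del = 0
        for i, cell in enumerate(row.ref_cells):
            if cell == "-":
                n_del += 1
            elif cell != ref[i] and cell != "N":
                diffs.append((i + 1, ref[i], cell))
        n_ins = sum(len(s) for s in row.insertions.values())
        net = n_ins - n_del
        n_subs = len(diffs)
        has_fpi = net != 0 and net % 3 == 0
        if net != 0 and net % 3 != 0:
            cls = "frameshift_indel"
        elif has_fpi:
            cls = "frame_preserving_indel"
        elif n_subs == 0:
            cls = "exact"
        elif n_subs == 1:
            cls = "one_change"
        elif n_subs == 2:
            cls = "two_change"
        else:
            cls = "two_plus_change"
        class_totals[cls] += 1
        for d in diffs:
            spectrum[d] = spectrum.get(d, 0) + 1
        records.append(
            AlleleRecord(
                id=row.id,
                n_substitutions=n_subs,
                has_frame_preserving_indel=has_fpi,
                net_indel_nt=net,
                diffs=diffs,
                allele_class=cls,
            )
        )
    table = SpectrumTable(
        n_alleles=len(records),
        class_totals=class_totals,
        substitution_counts=spectrum,
    )
    return records, table


def modal_one_change(
    records: list[AlleleRecord],
) -> tuple[tuple[int, str, str] | None, float]:
    """Most frequent substitution among one-change alleles + its share.

    The share is the percentage of one-change records carrying the
    modal substitution.
    """
    ones = [r for r in records if r.allele_class == "one_change"]
    if not ones:
        return None, 0.0
    counts: dict[tuple[int, str, str], int] = {}
    for r in ones:
        counts[r.diffs[0]] = counts.get(r.diffs[0], 0) + 1
    modal = max(counts, key=lambda d: (counts[d], -d[0]))
    return modal, 100.0 * counts[modal] / len(ones)


def spectrum_to_tsv(table: SpectrumTable) -> str:
    """Deterministic spectrum TSV ordered by (position, alt base)."""
    lines = ["pos_1based\tref_base\talt_base\tcount\tpct_of_alleles"]
    for (pos, ref, alt) in sorted(
        table.substitution_counts, key=lambda d: (d[0], d[2])
    ):
        count = table.substitution_counts[(pos, ref, alt)]
        pct = 100.0 * count / table.n_alleles if table.n_alleles else 0.0
        lines.append(f"{pos}\t{ref}\t{alt}\t{count}\t{pct:.2f}")
    return "\n".join(lines) + "\n"


def spectrum_to_json(table: SpectrumTable, records: list[AlleleRecord]) -> str:
    modal, modal_pct = modal_one_change(records)
    payload = {
        "n_alleles": table.n_alleles,
        "class_totals": table.class_totals,
        "class_pct": {k: round(v, 2) for k, v in table.class_pct().items()},
        "modal_one_change": (
            {
                "pos_1based": modal[0],
                "ref_base": modal[1],
                "alt_base": modal[2],
                "pct_of_one_change": round(modal_pct, 2),
            }
            if modal
            else None
        ),
        "substitutions": [
            {
                "pos_1based": pos,
                "ref_base": ref,
                "alt_base": alt,
                "count": count,
            }
            for (pos, ref, alt), count in sorted(
                table.substitution_counts.items(),
                key=lambda kv: (kv[0][0], kv[0][2]),
            )
        ],
    }
    return json.dumps(payload, indent=2)


def matrix_to_gapped_fasta(matrix: AnchorMatrix) -> str:
    """Gapped-FASTA export of the star alignment (reference row first).

    Insertion columns are materialized at their keyed positions so all
    rows have equal length.
    """
    all_ins: dict[int, int] = {}
    for row in matrix.rows:
        for pos, seq in row.insertions.items():
            all_ins[pos] = max(all_ins.get(pos, 0), len(seq))
    ref = matrix.reference.seq

    def _project(cells: list[str], insertions: dict[int, str]) -> str:
        out: list[str] = []
        for pos in range(len(ref) + 1):
            if pos in all_ins:
                ins = insertions.get(pos, "")
                out.append(ins.ljust(all_ins[pos], "-"))
            if pos < len(ref):
                out.append(cells[pos])
        return "".join(out)

    chunks = [f">{matrix.reference.id}\n"
              f"{_project(list(ref), {})}\n"]
    for row in matrix.rows:
        chunks.append(f">{row.id}\n{_project(row.ref_cells, row.insertions)}\n")
    return "".join(chunks)
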