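"""Per-repeat-unit ORF locus classification and array census.

Each rDNA repeat unit is screened for the spacer ORF locus by aligning
the reference ORF against both strands of the unit; the locus is then
classified from the alignment as COMPLETE, FRAME_PRESERVING_INDEL (net
indel a nonzero multiple of 3), FRAMESHIFT (net indel not a multiple of
3), DISRUPTED (frame intact but the start codon is lost or a premature
stop truncates the product) or NO_LOCUS. The census aggregates per
chromosome, mirroring a per-array survey of complete-ORF repeats.

The COMPLETE start-codon check is anchored to the alignment column of
the reference ATG, not to any ATG in the locus, so units whose locus is
intact except for a start-site loss are not counted complete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .align import (
    PairwiseAlignment,
    align_nucleotide,
    left_normalize,
)
from .protein import predicted_mass_kda
from .seqcore import Interval, NucSeq, ProtSeq, reverse_complement, translate

FRAME_STATUSES = (
    "COMPLETE",
    "FRAME_PRESERVING_INDEL",
    "FRAMESHIFT",
    "DISRUPTED",
    "NO_LOCUS",
)


@dataclass
class RepeatUnit:
    """One rDNA repeat unit, 45S-sense oriented, with array position."""

    id: str
    chrom: str
    index_in_array: int
    seq: NucSeq

    @classmethod
    def from_record(cls, record: NucSeq) -> "RepeatUnit":
        """Parse a unit from a FASTA record with header ``chrom|index``."""
        chrom, sep, idx = record.id.partition("|")
        if not sep or not idx.isdigit():
            raise ValueError(
                f"unit header {record.id!r} is not of the form 'chrom|index'"
            )
        return cls(record.id, chrom, int(idx), record)


@dataclass
class LocusHit:
    """Location of the ORF locus on a unit's forward coordinates."""

    interval: Interval
    strand: str
    alignment: PairwiseAlignment  # reference ORF vs strand-oriented unit
    identity_pct: float
    ref_coverage_pct: float


@dataclass
class Substitution:
    pos_1based: int  # in reference ORF coordinates
    ref_base: str
    alt_base: str
    aa_change: str  # e.g. 'L134V' or 'silent'


@dataclass
class UnitClassification:
    unit_id: str
    frame_status: str
    net_indel_nt: int = 0
    substitutions: list[Substitution] = field(default_factory=list)
    predicted_protein_len_aa: int = 0
    predicted_mass_kda: float = 0.0
    locus: LocusHit | None = None
    warning: str = ""

    def __post_init__(self) -> None:
        if self.frame_status not in FRAME_STATUSES:
            raise ValueError(f"unknown frame status {self.frame_status!r}")


def locate_orf_locus(
    unit: NucSeq,
    reference_orf: NucSeq,
    min_identity_pct: float = 80.0,
    min_ref_coverage_pct: float = 50.0,
) -> LocusHit | None:
    """Best alignment of the reference ORF against both unit strands.

    Returns ``None`` (NO_LOCUS) when the best alignment falls below the
    identity floor or covers less than the required fraction of the
    reference. The returned interval is on the unit's forward strand;
    the alignment itself is in ORF orientation (reference vs the
    strand-oriented unit) so downstream classification can read codons
    directly.
    """
    n = len(unit.seq)
    best: tuple[PairwiseAlignment, str] | None = None
    for strand in ("+", "-"):
        oriented = (
            unit.seq if strand == "+" else reverse_complement(unit.seq)
        )
        aln = align_nucleotide(reference_orf, oriented, mode="local")
        if aln is not None and (best is None or aln.score > best[0].score):
            best = (aln, strand)
    if best is None:
        return None
    aln, strand = best
    identity = aln.identity_pct
    coverage = 100.0 * len(aln.query_span) / len(reference_orf.seq)
    if identity < min_identity_pct or coverage < min_ref_coverage_pct:
        return None
    t0, t1 = aln.target_span.start, aln.target_span.end
    if strand == "+":
        interval = Interval(t0, t1, "+")
    else:
        interval = Interval(n - t1, n - t0, "-")
    return LocusHit(
        interval=interval,
        strand=strand,
        alignment=aln,
        identity_pct=identity,
        ref_coverage_pct=coverage,
    )


def _alignment_diffs(
    aligned_ref: str, aligned_alt: str, ref_offset: int
) -> tuple[int, list[tuple[int, str, str]]]:
    """Net indel and substitution list from a gapped reference/alt pair.

    ``ref_offset`` is the 0-based reference position of the first
    aligned reference base. Substitution positions are 1-based on the
    reference.
    """
    net = 0
    subs: list[tuple[int, str, str]] = []
    ref_pos = ref_offset
    for r, a in zip(aligned_ref, aligned_alt):
        if r == "-":
            net += 1
        elif a == "-":
            net -= 1
            ref_pos += 1
        else:
            if r != a:
                subs.append((ref_pos + 1, r, a))
            ref_pos += 1
    return net, subs


def _aa_change(reference_orf: str, pos1: int, alt: str) -> str:
    codon_idx = (pos1 - 1) // 3
    start = codon_idx * 3
    ref_codon = reference_orf[start : start + 3]
    if len(ref_codon) < 3:
        return "silent"
    mutated = list(ref_codon)
    mutated[(pos1 - 1) % 3] = alt
    ref_aa = translate(ref_codon)
    alt_aa = translate("".join(mutated))
    if ref_aa == alt_aa:
        return "silent"
    return f"{ref_aa}{codon_idx + 1}{alt_aa}"


def classify_unit(
    unit: NucSeq,
    reference_orf: NucSeq,
    min_identity_pct: float = 80.0,
    min_ref_coverage_pct: float = 50.0,
    downstream_slack_nt: int = 600,
) -> UnitClassification:
    """Frame status, indels, substitutions and predicted product.

    The predicted protein is obtained by translating the unit's locus
    from the alignment column of the reference ATG to the first stop,
    reading up to ``downstream_slack_nt`` beyond the locus so delayed
    stops (in-frame insertions, frameshifts) are found. The reference
    itself therefore classifies as COMPLETE with the reference product.
    """
    hit = locate_orf_locus(
        unit, reference_orf, min_identity_pct, min_ref_coverage_pct
    )
    if hit is None:
        return UnitClassification(unit_id=unit.id, frame_status="NO_LOCUS")
    aln = hit.alignment
    ref_aligned, unit_aligned = left_normalize(
        aln.aligned_query, aln.aligned_target
    )
    net, raw_subs = _alignment_diffs(
        ref_aligned, unit_aligned, aln.query_span.start
    )
    subs = [
        Substitution(p, r, a, _aa_change(reference_orf.seq, p, a))
        for p, r, a in raw_subs
    ]

    # start-codon check anchored at the reference ATG column
    starts_at_ref_atg = aln.query_span.start == 0
    oriented_unit = (
        unit.seq if hit.strand == "+" else reverse_complement(unit.seq)
    )
    t_start = aln.target_span.start
    window = oriented_unit[
        t_start : min(len(oriented_unit),
                      aln.target_span.end + downstream_slack_nt)
    ]
    has_atg = starts_at_ref_atg and window[:3] == "ATG"

    protein = ""
    if window:
        full = translate(window)
        stop_at = full.find("*")
        protein = full[: stop_at + 1] if stop_at >= 0 else ""

    ref_len_aa = len(reference_orf.seq) // 3 - 1
    product_len = max(0, len(protein) - 1)
    full_length = (
        has_atg
        and protein != ""
        and product_len == ref_len_aa
    )

    if net % 3 != 0:
        status = "FRAMESHIFT"
    elif net != 0:
        status = "FRAME_PRESERVING_INDEL"
    elif full_length:
        status = "COMPLETE"
    else:
        status = "DISRUPTED"

    warning = ""
    if hit.strand == "+":
        warning = "ORF found on the 45S-sense strand (expected antisense)"

    mass = 0.0
    if product_len > 0 and has_atg:
        mass = predicted_mass_kda(ProtSeq(f"{unit.id}|product", protein))
    return UnitClassification(
        unit_id=unit.id,
        frame_status=status,
        net_indel_nt=net,
        substitutions=subs,
        predicted_protein_len_aa=product_len if has_atg else 0,
        predicted_mass_kda=round(mass, 3),
        locus=hit,
        warning=warning,
    )


@dataclass
class ArrayCensus:
    """Per-chromosome counts of unit frame statuses."""

    per_chrom: dict[str, dict[str, int]]
    complete_indices: dict[str, list[int]]
    classifications: list[UnitClassification]

    @property
    def total_units(self) -> int:
        return sum(c["total"] for c in self.per_chrom.values())

    def count(self, status: str) -> int:
        key = status.lower()
        return sum(c[key] for c in self.per_chrom.values())

    @property
    def fraction_complete_pct(self) -> float:
        total = self.total_units
        if total == 0:
            return 0.0
        return 100.0 * self.count("COMPLETE") / total

    def summary(self) -> dict:
        return {
            "total_units": self.total_units,
            "complete": self.count("COMPLETE"),
            "frame_preserving_indel": self.count("FRAME_PRESERVING_INDEL"),
            "frameshift": self.count("FRAMESHIFT"),
            "disrupted": self.count("DISRUPTED"),
            "no_locus": self.count("NO_LOCUS"),
            "fraction_complete_pct": round(self.fraction_complete_pct, 2),
            "per_chrom": self.per_chrom,
            "complete_indices": self.complete_indices,
        }


def census(
    units: list[RepeatUnit],
    reference_orf: NucSeq,
    min_identity_pct: float = 80.0,
    min_ref_coverage_pct: float = 50.0,
) -> ArrayCensus:
    """Classify every unit and aggregate counts per chromosome."""
    per_chrom: dict[str, dict[str, int]] = {}
    complete_indices: dict[str, list[int]] = {}
    classifications: list[UnitClassification] = []
    for unit in units:
        cls = classify_unit(
            unit.seq, reference_orf, min_identity_pct, min_ref_coverage_pct
        )
        classifications.append(cls)
        chrom = per_chrom.setdefault(
            unit.chrom,
            {
                "total": 0,
                "complete": 0,
                "frame_preserving_indel": 0,
                "frameshift": 0,
                "disrupted": 0,
                "no_locus": 0,
            },
        )
        chrom["total"] += 1
        chrom[cls.frame_status.lower()] += 1
        if cls.frame_status == "COMPLETE":
            complete_indices.setdefault(unit.chrom, []).append(
                unit.index_in_array
            )
    for indices in complete_indices.values():
        indices.sort()
    return ArrayCensus(
        per_chrom=per_chrom,
        complete_indices=complete_indices,
        classifications=classifications,
    )


def census_to_tsv(result: ArrayCensus, units: list[RepeatUnit]) -> str:
    """One row per unit; coordinates are 1-based inclusive."""
    lines = [
        "unit_id\tchrom\tindex\tframe_status\tnet_indel_nt\t"
        "substitutions\tpredicted_protein_len_aa\tpredicted_mass_kda\t"
        "locus_start_1based\tlocus_end_1based\tlocus_strand\tidentity_pct"
    ]
    for unit, cls in zip(units, result.classifications):
        if cls.locus is not None:
            start1, end1 = cls.locus.interval.to_1based()
            locus_cols = (
                f"{start1}\t{end1}\t{cls.locus.strand}\t"
                f"{cls.locus.identity_pct:.2f}"
            )
        else:
            locus_cols = ".\t.\t.\t."
        subs = ";".join(
            f"{s.pos_1based}{s.ref_base}>{s.alt_base}({s.aa_change})"
            for s in cls.substitutions
        )
        lines.append(
            f"{unit.id}\t{unit.chrom}\t{unit.index_in_array}\t"
            f"{cls.frame_status}\t{cls.net_indel_nt}\t{subs or '.'}\t"
            f"{cls.predicted_protein_len_aa}\t{cls.predicted_mass_kda}\t"
            f"{locus_cols}"
        )
    return "\n".join(lines) + "\n"


def census_to_json(result: ArrayCensus) -> str:
    return json.dumps(result.summary(), indent=2, sort_keys=True)
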