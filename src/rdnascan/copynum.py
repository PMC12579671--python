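"""Coverage-normalized copy-number estimation.

Read counts become per-haploid-genome copy numbers by dividing by the
haploid genome coverage (total read bases / genome size; 3.1 Gbp for
human-scale inputs, the simulated genome size otherwise). Total rDNA
copies are estimated by mapping every read to a doubled canonical
repeat unit (two concatenated copies, so reads spanning the unit
junction of the circular-like tandem array align contiguously) and
counting reads that overlap the ORF locus in either copy at over 99%
identity, each read at most once.

Two mapping engines are provided. The default, ``minimap2``, shells out
to the minimap2 aligner in HiFi preset with base-level alignment and
takes identity as matches / alignment-block length of the primary
mapping — the approximate-mapper identity the survey design calls for.
The ``edlib`` engine embeds the whole read in the doubled reference by
bounded edit distance and scores identity as
``1 − editDistance / readLength``; it is slower and stricter at array
edges but has no external-process dependency, and serves as an
independent cross-check of the minimap2 route in the test suite.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .seqcore import Interval, NucSeq, reverse_complement, write_fasta

HUMAN_GENOME_BP = 3.1e9


@dataclass
class CoverageEstimate:
    total_bases: int
    genome_size_bp: float
    coverage_x: float = field(init=False)

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValueError("genome_size_bp must be positive")
        self.coverage_x = self.total_bases / self.genome_size_bp


@dataclass
class CopyNumberEstimate:
    orf_copies: float
    rdna_copies: float

    @property
    def orf_fraction_pct(self) -> float:
        return orf_fraction(self.orf_copies, self.rdna_copies)


def haploid_coverage(
    reads: list[NucSeq], genome_size_bp: float = HUMAN_GENOME_BP
) -> CoverageEstimate:
    """Total read bases divided by the haploid genome size."""
    total = sum(len(r.seq) for r in reads)
    if total == 0:
        warnings.warn("empty read set: coverage is 0", stacklevel=2)
    return CoverageEstimate(total_bases=total, genome_size_bp=genome_size_bp)


def normalize_count(raw_count: int, cov: CoverageEstimate) -> float:
    """Copies per haploid genome = raw read count / coverage."""
    if raw_count == 0:
        return 0.0
    if cov.coverage_x <= 0:
        raise ValueError("cannot normalize by zero coverage")
    return raw_count / cov.coverage_x


@dataclass
class DoubledReference:
    """Two concatenated copies of the canonical unit + ORF loci."""

    seq: NucSeq
    loci: tuple[Interval, Interval]
    unit_len: int


def build_doubled_reference(
    canonical_unit: NucSeq, orf_locus: Interval
) -> DoubledReference:
    """unit+unit with the ORF locus annotated in both copies."""
    n = len(canonical_unit.seq)
    if not canonical_unit.seq:
        raise ValueError("canonical unit is empty")
    doubled = NucSeq(
        f"{canonical_unit.id}|doubled", canonical_unit.seq * 2
    )
    second = Interval(orf_locus.start + n, orf_locus.end + n, orf_locus.strand)
    return DoubledReference(seq=doubled, loci=(orf_locus, second), unit_len=n)


class _SeedIndex:
    """Exact k-mer presence index over both strands of a reference.

    Seed hits also reveal the read's likely strand, so the expensive
    alignment is tried in the right orientation first.
    """

    def __init__(self, seq: str, k: int = 32) -> None:
        self.k = k
        self.fwd = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        rc = reverse_complement(seq)
        self.rev = {rc[i : i + k] for i in range(len(rc) - k + 1)}

    def strand_hint(self, read: str, stride: int = 64) -> str | None:
        """'+' / '-' when a sampled k-mer hits a strand, else None."""
        k = self.k
        if len(read) < k:
            return None
        positions = list(range(0, len(read) - k + 1, stride))
        positions.append(len(read) - k)
        for i in positions:
            kmer = read[i : i + k]
            if kmer in self.fwd:
                return "+"
            if kmer in self.rev:
                return "-"
        return None


def _read_maps_over_locus(
    read_seq: str,
    ref: DoubledReference,
    min_identity_pct: float,
    k_edits: int,
    strand_hint: str = "+",
) -> bool:
    # a read matches at most one strand near-perfectly, so the first
    # orientation that clears the gate settles the read
    rc = reverse_complement(read_seq)
    ordered = (read_seq, rc) if strand_hint == "+" else (rc, read_seq)
    for oriented in ordered:
        res = edlib.align(
            oriented, ref.seq.seq, mode="HW", task="locations", k=k_edits
        )
        d = res["editDistance"]
        if d < 0:
            continue
        identity = 100.0 * (1.0 - d / len(read_seq))
        if identity <= min_identity_pct:
            continue
        t0, t1 = res["locations"][0]
        span = Interval(t0, t1 + 1)
        if span.overlaps(ref.loci[0]) or span.overlaps(ref.loci[1]):
            return True
    return False


def count_rdna_reads(
    reads: list[NucSeq],
    ref: DoubledReference,
    min_identity_pct: float = 99.0,
) -> int:
    """Reads mapping over the ORF locus at over ``min_identity_pct``.

    Each read counts at most once even when it spans both locus copies
    of the doubled reference: reads, not loci, are the counting unit.
    The edit budget passed to the aligner is just above the identity
    gate: reads that cannot clear the gate are rejected early.
    """
    index = _SeedIndex(ref.seq.seq)
    # a pass requires editDistance < (100 - gate)% of the read length;
    # the aligner budget sits just above that bound
    slack = max(0.005, 1.05 * (100.0 - min_identity_pct) / 100.0)
    count = 0
    for read in reads:
        hint = index.strand_hint(read.seq)
        if hint is None:
            continue
        k_edits = int(slack * len(read.seq)) + 10
        if _read_maps_over_locus(
            read.seq, ref, min_identity_pct, k_edits, strand_hint=hint
        ):
            count += 1
    return count


def count_rdna_reads_minimap2(
    reads: list[NucSeq],
    ref: DoubledReference,
    min_identity_pct: float = 99.0,
) -> int:
    """minimap2-based count of locus-overlapping high-identity reads.

    Reads are mapped with the HiFi preset and base-level alignment;
    the primary mapping's identity (matches / alignment block length)
    must exceed the gate and its target span must overlap the ORF
    locus in either copy of the doubled reference.
    """
    if shutil.which("minimap2") is None:
        raise RuntimeError("minimap2 executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        ref_fa = Path(tmp) / "ref.fa"
        reads_fa = Path(tmp) / "reads.fa"
        write_fasta([ref.seq], ref_fa)
        write_fasta(reads, reads_fa, width=10_000)
        proc = subprocess.run(
            [
                "minimap2", "-c", "-x", "map-hifi", "--secondary=no",
                "-t", "1", str(ref_fa), str(reads_fa),
            ],
            capture_output=True, text=True, check=True,
        )
    best: dict[str, tuple[float, int, int]] = {}
    for line in proc.stdout.splitlines():
        f = line.split("\t")
        read_id, matches, block = f[0], int(f[9]), int(f[10])
        t0, t1 = int(f[7]), int(f[8])
        identity = 100.0 * matches / block if block else 0.0
        prev = best.get(read_id)
        if prev is None or identity > prev[0]:
            best[read_id] = (identity, t0, t1)
    count = 0
    for identity, t0, t1 in best.values():
        if identity <= min_identity_pct:
            continue
        span = Interval(t0, t1)
        if span.overlaps(ref.loci[0]) or span.overlaps(ref.loci[1]):
            count += 1
    return count


def estimate_rdna_copies(
    reads: list[NucSeq],
    canonical_unit: NucSeq,
    orf_locus: Interval,
    cov: CoverageEstimate,
    min_identity_pct: float = 99.0,
    engine: str = "minimap2",
) -> float:
    """Coverage-normalized count of high-identity locus-overlapping reads."""
    ref = build_doubled_reference(canonical_unit, orf_locus)
    if engine == "minimap2":
        raw = count_rdna_reads_minimap2(reads, ref, min_identity_pct)
    elif engine == "edlib":
        raw = count_rdna_reads(reads, ref, min_identity_pct)
    else:
        raise ValueError(f"unknown mapping engine {engine!r}")
    return normalize_count(raw, cov)


def orf_fraction(orf_copies: float, rdna_copies: float) -> float:
    """Percentage of rDNA copies carrying the ORF."""
    if rdna_copies <= 0:
        raise ValueError("rdna_copies must be positive to form a fraction")
    return 100.0 * orf_copies / rdna_copies


def copy_number_pipeline(
    reads: list[NucSeq],
    ref_protein,
    ref_nt: NucSeq,
    canonical_unit: NucSeq,
    orf_locus: Interval,
    genome_size_bp: float,
    scan_config=None,
    min_rdna_identity_pct: float = 99.0,
    mapping_engine: str = "minimap2",
) -> dict:
    """End-to-end survey of one read set: ORF copies, rDNA copies, fraction.

    ``genome_size_bp`` must be the (simulated or real) haploid genome
    size the reads were drawn from; the 3.1 Gbp human default is only
    meaningful for human-scale read sets.
    """
    from .reads import count_orf_reads

    cov = haploid_coverage(reads, genome_size_bp)
    if cov.coverage_x <= 0:
        raise ValueError("zero coverage: empty read set")
    orf_raw, _hits, scan_summary = count_orf_reads(
        reads, ref_protein, ref_nt, scan_config
    )
    orf_copies = normalize_count(orf_raw, cov)
    rdna_copies = estimate_rdna_copies(
        reads, canonical_unit, orf_locus, cov, min_rdna_identity_pct,
        engine=mapping_engine,
    )
    est = CopyNumberEstimate(orf_copies=orf_copies, rdna_copies=rdna_copies)
    return {
        "coverage_x": round(cov.coverage_x, 4),
        "total_bases": cov.total_bases,
        "orf_reads": orf_raw,
        "orf_copies": round(orf_copies, 3),
        "rdna_copies": round(rdna_copies, 3),
        "orf_fraction_pct": (
            round(est.orf_fraction_pct, 3) if rdna_copies > 0 else None
        ),
        "scan_summary": scan_summary,
    }
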