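"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the study system: a human-like rDNA tandem array
whose ~tens-of-kb repeat units carry, antisense within the intergenic
spacer, a 573-nt ORF encoding a 190-residue protein. A configurable
subset of units carries the complete ORF; the rest carry 5-bp deletions,
5- or 10-bp insertions (frameshift, premature termination), or a 15-bp
in-frame insertion adding one unit of the hydrophobic pentapeptide
repeat, plus point substitutions at designated ORF positions. Reads are
HiFi-like: long, low error rate, with indel errors biased into
homopolymer runs.

The reference protein is engineered, not arbitrary: residues 1-10 and
110-190 are hydrophobic, the core (11-109, the Alu-derived region in the
real protein) holds 13 of 18 positive and 3 of 6 negative charges, three
I[VL]LY[CR] motif units sit in the C-terminal arm, and the neutral
filler composition is solved so the overall scaled Kyte-Doolittle index
lands on a configurable target (default 0.708). Methionine occurs only
at position 1 and codon choice is re-drawn until the 573-nt construct
contains exactly one ORF at the 180-nt threshold on either strand, so
ORF-discovery results on synthetic data are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .protein import KD_MAX, KD_MIN, KD_SCALE
from .seqcore import NucSeq, ProtSeq, find_orfs, reverse_complement, translate

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    CODONS_BY_AA.setdefault(aa, []).append(codon)
STOP_CODON = "TAG"

#: one codon-level unit of the hydrophobic pentapeptide repeat (IVLYC)
IVLYC_NT = "ATTGTGCTGTATTGT"

#: ORF positions (1-based) carrying recurrent substitutions in the
#: two-or-more-change allele class of the simulated population.
SPECTRUM_POSITIONS = (320, 374, 385, 389, 501, 511, 549)

#: modal single substitution of the one-change class: G>C at ORF nt 385
MODAL_SUB_POS = 385
MODAL_SUB_ALT = "C"

#: default frameshift edit position (0-based), mid-ORF so premature
#: stops fall downstream of the core, and the in-frame insertion point
#: (after codon 144, i.e. right after the first pentapeptide unit)
FRAMESHIFT_EDIT_POS = 349
INFRAME_INSERT_POS = 432

EXPECTED_STATUS = {
    "COMPLETE": "COMPLETE",
    "DEL5": "FRAMESHIFT",
    "INS5": "FRAMESHIFT",
    "INS10": "FRAMESHIFT",
    "INS15_INFRAME": "FRAME_PRESERVING_INDEL",
}

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Reference ORF design
# ---------------------------------------------------------------------------

def _design_protein(length_aa: int, rng: np.random.Generator,
                    target_index: float) -> str:
    """Amino-acid sequence with the tripartite amphipathic architecture."""
    if length_aa < 120:
        # short fallback: plain hydrophobic-leaning sequence, no layout
        pool = "IVLAFMGST"
        return "M" + "".join(rng.choice(list(pool), size=length_aa - 1))
    core_lo, core_hi = 11, length_aa - 81  # 1-based inclusive core bounds
    seq: list[str | None] = [None] * length_aa
    seq[0] = "M"
    nterm_fill = ["I", "V", "L", "I", "V", "L", "F", "I", "V"]
    for i, aa in enumerate(nterm_fill, start=1):
        seq[i] = aa
    seq[10] = "L"  # position 11; codon fixed so nt 32 is T (L>S target)

    # C-terminal arm: three pentapeptide motif units + fixed V129/L134
    motif_starts = {length_aa - 51: "IVLYC", length_aa - 41: "IVLYR",
                    length_aa - 31: "ILLYC"}
    for start, motif in motif_starts.items():
        for k, aa in enumerate(motif):
            seq[start - 1 + k] = aa
    seq[128] = "V"  # position 129; codon GTG puts G at nt 385
    seq[133] = "L"  # position 134; codon CTG puts C at nt 400 (L>V target)

    def _free(lo: int, hi: int) -> list[int]:
        return [i for i in range(lo - 1, hi) if seq[i] is None]

    # charges: 13 of 18 positives and 3 of 6 negatives in the core
    # (IVLYR already contributes one positive to the C-terminal arm)
    core_free = _free(core_lo + 1, core_hi)
    pos_core = rng.choice(core_free, size=13, replace=False)
    for i in pos_core:
        seq[i] = "R"
    core_free = _free(core_lo + 1, core_hi)
    neg_core = rng.choice(core_free, size=3, replace=False)
    for i in neg_core:
        seq[i] = "E"
    arm_free = _free(core_hi + 1, length_aa)
    charged_arm = rng.choice(arm_free, size=7, replace=False)
    for j, i in enumerate(sorted(charged_arm)):
        seq[i] = ["R", "R", "E", "R", "E", "R", "E"][j]

    # hydrophobic filler in the C-terminal arm
    arm_free = _free(core_hi + 1, length_aa)
    cycle = ["I", "V", "L"]
    for j, i in enumerate(arm_free):
        seq[i] = cycle[j % 3]

    # solve the core filler composition so the overall mean
    # Kyte-Doolittle value hits the target scaled index. Two diverse
    # residue palettes (mildly hydrophobic vs hydrophilic) are mixed;
    # sequence complexity matters because a low-complexity core would
    # blur the frameshift signal every downstream stage relies on
    core_free = _free(core_lo, core_hi)
    target_sum = (target_index * (KD_MAX - KD_MIN) + KD_MIN) * length_aa
    fixed_sum = sum(KD_SCALE[a] for a in seq if a is not None)
    need = target_sum - fixed_sum
    n_fill = len(core_free)
    phobic = ["A", "C", "V", "F"]
    philic = ["S", "T", "G", "W", "N", "P"]

    def _mix(n_h: int) -> list[str]:
        return [phobic[j % len(phobic)] for j in range(n_h)] + [
            philic[j % len(philic)] for j in range(n_fill - n_h)
        ]

    best_mix = min(
        (abs(sum(KD_SCALE[a] for a in _mix(n_h)) - need), n_h)
        for n_h in range(n_fill + 1)
    )
    filler = _mix(best_mix[1])
    rng.shuffle(filler)
    for i, aa in zip(core_free, filler):
        seq[i] = aa
    return "".join(seq)  # type: ignore[arg-type]


#: codons fixed so designated ORF nucleotide positions carry the bases
#: that the planted substitution spectrum mutates (nt 32 T, 385 G, 400 C)
_FIXED_CODONS = {1: "ATG", 11: "TTG", 129: "GTG", 134: "CTG"}


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for i, aa in enumerate(protein, start=1):
        if i in _FIXED_CODONS and len(protein) >= 134:
            codons.append(_FIXED_CODONS[i])
        elif aa == "M":
            codons.append("ATG")
        else:
            options = CODONS_BY_AA[aa]
            codons.append(options[rng.integers(0, len(options))])
    codons.append(STOP_CODON)
    return "".join(codons)


def make_reference_orf(
    length_aa: int = 190,
    seed: int = 0,
    target_index: float = 0.708,
    max_tries: int = 200,
) -> tuple[NucSeq, ProtSeq]:
    """Design the synthetic reference ORF (nt + protein).

    The emitted nucleotide sequence spans ``3 * (length_aa + 1)`` bases
    (ATG through stop). Codon choice is seeded-random but re-drawn until
    the construct contains exactly one ORF of >= 180 nt on either
    strand, so that ORF discovery on derived data has a unique answer.
    """
    if length_aa < 20:
        raise ValueError("length_aa must be >= 20")
    rng = np.random.default_rng(seed)
    protein = _design_protein(length_aa, rng, target_index)
    for _ in range(max_tries):
        nt = _back_translate(protein, rng)
        rec = NucSeq("ref_orf", nt)
        calls = find_orfs(rec, min_len_nt=min(180, 3 * (length_aa + 1)),
                          both_strands=True)
        if not (len(calls) == 1 and calls[0].length_nt == len(nt)):
            continue
        if len(nt) > FRAMESHIFT_EDIT_POS + 120 and not _early_shift_stops(nt):
            continue
        return rec, ProtSeq("ref_orf_protein", protein + "*")
    raise RuntimeError("could not design a clean single-ORF construct")


def _early_shift_stops(nt: str, within_codons: int = 65) -> bool:
    """True when both shifted frames downstream of the frameshift edit
    point stop within ``within_codons`` codons, so frameshift alleles
    are guaranteed the premature termination they emulate."""
    # relative to the edit point (original position 349, phase 1), a
    # net -5/+10 shift reads downstream bases in frame 1 of nt[349:]
    # and a net +5 shift reads them in frame 0; frame 2 is the original
    # (stop-free) reading frame
    downstream = nt[FRAMESHIFT_EDIT_POS:]
    return all(
        "*" in translate(downstream, frame)[:within_codons]
        for frame in (0, 1)
    )


# ---------------------------------------------------------------------------
# Allele plans and arrays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitAllele:
    """The planted state of one unit's ORF locus."""

    kind: str  # COMPLETE | DEL5 | INS5 | INS10 | INS15_INFRAME
    subs: tuple[tuple[int, str], ...] = ()  # (pos_1based, alt_base)

    def __post_init__(self) -> None:
        if self.kind not in EXPECTED_STATUS:
            raise ValueError(f"unknown allele kind {self.kind!r}")

    @property
    def expected_status(self) -> str:
        return EXPECTED_STATUS[self.kind]


@dataclass
class AllelePlan:
    """Planted allele per (chromosome, array index), plus the seed."""

    entries: list[tuple[str, int, UnitAllele]]
    seed: int = 0

    def __post_init__(self) -> None:
        keys = [(c, i) for c, i, _ in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, index) entries in plan")

    @property
    def n_units(self) -> int:
        return len(self.entries)

    def count_status(self, status: str) -> int:
        return sum(
            1 for _, _, a in self.entries if a.expected_status == status
        )

    @property
    def n_complete(self) -> int:
        return self.count_status("COMPLETE")

    def chroms(self) -> list[str]:
        seen: list[str] = []
        for c, _, _ in self.entries:
            if c not in seen:
                seen.append(c)
        return seen


#: the L>V variant carried by most complete units: C>G at ORF nt 400
LV_SUB = (400, "G")
#: the L>S variant of the in-frame-insertion unit: T>C at ORF nt 32
LS_SUB = (32, "C")


def default_plan(seed: int = 0) -> AllelePlan:
    """A 219-unit, 5-chromosome plan emulating the published census.

    43 units carry the complete ORF (39 consecutive on chr21, two on
    chr14, one each on chr13 and chr22); one chr15 unit carries the
    15-bp in-frame insertion (an extra pentapeptide unit) and is counted
    separately from the complete class; the remainder are frameshifted
    by 5-bp deletions or 5/10-bp insertions. Complete units carry the
    L>V point substitution except the chr22 copy.
    """
    entries: list[tuple[str, int, UnitAllele]] = []
    complete_lv = UnitAllele("COMPLETE", (LV_SUB,))

    for i in range(1, 77):  # chr13: 76 units, one complete near centromere
        allele = complete_lv if i == 74 else UnitAllele("DEL5")
        entries.append(("chr13", i, allele))
    for i in range(1, 17):  # chr14: 16 units, complete at 14 and 16
        allele = complete_lv if i in (14, 16) else UnitAllele("INS5")
        entries.append(("chr14", i, allele))
    for i in range(1, 51):  # chr15: 50 units, in-frame insertion at 50
        if i == 50:
            allele = UnitAllele("INS15_INFRAME", (LS_SUB, LV_SUB))
        else:
            allele = UnitAllele("DEL5")
        entries.append(("chr15", i, allele))
    for i in range(1, 57):  # chr21: 56 units, complete block 17-55
        if 17 <= i <= 55:
            allele = complete_lv
        elif i == 56:
            allele = UnitAllele("INS10")
        else:
            allele = UnitAllele("DEL5")
        entries.append(("chr21", i, allele))
    for i in range(1, 22):  # chr22: 21 units, complete at 18 (no L>V)
        allele = UnitAllele("COMPLETE") if i == 18 else UnitAllele("INS5")
        entries.append(("chr22", i, allele))
    return AllelePlan(entries=entries, seed=seed)


def demo_plan(seed: int = 0) -> AllelePlan:
    """A 12-unit two-chromosome plan exercising every allele kind."""
    lv = (LV_SUB,)
    entries = [
        ("chrA", 1, UnitAllele("DEL5")),
        ("chrA", 2, UnitAllele("COMPLETE", lv)),
        ("chrA", 3, UnitAllele("INS5")),
        ("chrA", 4, UnitAllele("COMPLETE", lv)),
        ("chrA", 5, UnitAllele("INS15_INFRAME", (LS_SUB,))),
        ("chrB", 1, UnitAllele("COMPLETE")),
        ("chrB", 2, UnitAllele("DEL5")),
        ("chrB", 3, UnitAllele("INS10")),
        ("chrB", 4, UnitAllele("COMPLETE", lv)),
        ("chrB", 5, UnitAllele("INS5")),
        ("chrB", 6, UnitAllele("DEL5")),
        ("chrB", 7, UnitAllele("COMPLETE", lv)),
    ]
    return AllelePlan(entries=entries, seed=seed)


def apply_allele(orf_nt: str, allele: UnitAllele,
                 rng: np.random.Generator) -> str:
    """Apply planted substitutions and the allele's indel to the ORF."""
    s = list(orf_nt)
    for pos, alt in allele.subs:
        if not 1 <= pos <= len(s):
            raise ValueError(f"substitution position {pos} outside ORF")
        s[pos - 1] = alt
    seq = "".join(s)
    if allele.kind == "COMPLETE":
        return seq
    if allele.kind == "DEL5":
        return seq[:FRAMESHIFT_EDIT_POS] + seq[FRAMESHIFT_EDIT_POS + 5:]
    if allele.kind in ("INS5", "INS10"):
        n = 5 if allele.kind == "INS5" else 10
        ins = "".join(_BASES[rng.integers(0, 4)] for _ in range(n))
        return seq[:FRAMESHIFT_EDIT_POS] + ins + seq[FRAMESHIFT_EDIT_POS:]
    if allele.kind == "INS15_INFRAME":
        return seq[:INFRAME_INSERT_POS] + IVLYC_NT + seq[INFRAME_INSERT_POS:]
    raise AssertionError(allele.kind)


def _random_spacer(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def make_canonical_unit(
    reference_orf: NucSeq,
    unit_len_bp: int = 20_000,
    seed: int = 0,
    orf_offset_frac: float = 0.3,
) -> tuple[NucSeq, "LocusInterval"]:
    """One canonical repeat unit with the ORF embedded antisense.

    Returns the unit and the ORF locus interval on the unit's forward
    (45S-sense) strand. All array units share this backbone, mirroring
    the >99% identity of real repeat units.
    """
    from .seqcore import Interval

    orf = reference_orf.seq
    if unit_len_bp < len(orf) + 200:
        raise ValueError("unit_len_bp too small for the ORF plus flanks")
    rng = np.random.default_rng(seed)
    offset = int(orf_offset_frac * (unit_len_bp - len(orf)))
    left = _random_spacer(offset, rng)
    right = _random_spacer(unit_len_bp - offset - len(orf), rng)
    unit = NucSeq("canonical_unit", left + reverse_complement(orf) + right)
    locus = Interval(offset, offset + len(orf), "-")
    return unit, locus


# re-export type for annotations without a circular import at top level
from .seqcore import Interval as LocusInterval  # noqa: E402


@dataclass
class SyntheticTruth:
    """The planted plan and bookkeeping behind a simulated dataset."""

    plan: AllelePlan
    unit_len_bp: int
    genome_size_bp: int = 0
    true_rdna_units: int = 0
    true_complete_units: int = 0
    true_orf_capable_units: int = 0  # complete + in-frame-indel units
    unit_rows: list[dict] = field(default_factory=list)
    genome_loci: list[dict] = field(default_factory=list)
    read_params: dict = field(default_factory=dict)


def make_array(
    plan: AllelePlan,
    reference_orf: NucSeq,
    unit_len_bp: int = 20_000,
    seed: int | None = None,
) -> tuple[list[NucSeq], SyntheticTruth]:
    """Per-chromosome repeat units with the planted alleles applied.

    Units are emitted as separate records with headers ``chrom|index``
    (assembly-like). All units share one seeded-random spacer backbone;
    only the ORF locus differs between units, per the plan.
    """
    seed = plan.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    unit_tpl, locus = make_canonical_unit(reference_orf, unit_len_bp, seed)
    left = unit_tpl.seq[: locus.start]
    right = unit_tpl.seq[locus.end:]
    units: list[NucSeq] = []
    truth = SyntheticTruth(
        plan=plan,
        unit_len_bp=unit_len_bp,
        true_rdna_units=plan.n_units,
        true_complete_units=plan.n_complete,
        true_orf_capable_units=plan.n_complete
        + plan.count_status("FRAME_PRESERVING_INDEL"),
    )
    for chrom, index, allele in plan.entries:
        allele_nt = apply_allele(reference_orf.seq, allele, rng)
        seq = left + reverse_complement(allele_nt) + right
        rec = NucSeq(f"{chrom}|{index}", seq)
        units.append(rec)
        truth.unit_rows.append(
            {
                "unit_id": rec.id,
                "chrom": chrom,
                "index": index,
                "allele": allele.kind,
                "expected_status": allele.expected_status,
                "subs": ";".join(f"{p}{a}" for p, a in allele.subs),
                "locus_start_in_unit": len(left),
                "locus_len": len(allele_nt),
            }
        )
    return units, truth


def make_genome(
    units: list[NucSeq],
    truth: SyntheticTruth,
    background_bp: int = 310_000,
    seed: int = 0,
) -> NucSeq:
    """Concatenated genome: background + tandem array + background.

    Records each unit's ORF locus in genome coordinates into
    ``truth.genome_loci`` and sets ``truth.genome_size_bp``.
    """
    rng = np.random.default_rng(seed + 7)
    parts = [_random_spacer(background_bp, rng)]
    offset = background_bp
    for rec, row in zip(units, truth.unit_rows):
        parts.append(rec.seq)
        row["genome_start"] = offset
        row["genome_end"] = offset + len(rec.seq)
        locus_start = offset + row["locus_start_in_unit"]
        truth.genome_loci.append(
            {
                "unit_id": rec.id,
                "start": locus_start,
                "end": locus_start + row["locus_len"],
                "strand": "-",
                "allele": row["allele"],
            }
        )
        offset += len(rec.seq)
    parts.append(_random_spacer(background_bp, rng))
    genome = NucSeq("synthetic_genome", "".join(parts))
    truth.genome_size_bp = len(genome.seq)
    return genome


# ---------------------------------------------------------------------------
# HiFi-like read simulation
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
_DECODE = np.frombuffer("ACGT".encode(), dtype=np.uint8)


def _homopolymer_mask(arr: np.ndarray) -> np.ndarray:
    """True at positions inside a homopolymer run of length >= 3."""
    mask = np.zeros(arr.shape[0], dtype=bool)
    if arr.shape[0] < 3:
        return mask
    eq = arr[1:] == arr[:-1]
    inrun = eq[1:] & eq[:-1]  # position i (2..n-1) ends a run of 3
    mask[2:] |= inrun
    mask[1:-1] |= inrun
    mask[:-2] |= inrun
    return mask


def simulate_reads(
    genome: NucSeq,
    coverage: float = 20.0,
    mean_len: int = 15_000,
    sub_rate: float = 0.0005,
    indel_rate: float = 0.0002,
    homopolymer_bias: float = 5.0,
    seed: int = 0,
    min_len: int = 1_000,
    max_len: int = 32_000,
    len_sigma: float = 0.2,
) -> tuple[list[NucSeq], list[dict]]:
    """HiFi-like reads: long, accurate, homopolymer-biased indel errors.

    Read lengths are log-normal around ``mean_len`` (truncated to
    ``[min_len, max_len]`` and the genome length); starts are uniform;
    strands are random. Substitutions occur at ``sub_rate`` per base;
    indel errors occur at ``indel_rate`` per base, multiplied by
    ``homopolymer_bias`` inside homopolymer runs of length >= 3, and are
    single-base insertions (base duplication) or deletions with equal
    probability. Returns the reads plus a truth table of origins.
    """
    if not 0 <= sub_rate <= 0.05 or not 0 <= indel_rate <= 0.05:
        raise ValueError("error rates must be within [0, 0.05]")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    g_arr = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    g_codes = _CODE[g_arr]
    hp_mask = _homopolymer_mask(g_arr)
    n_genome = g_arr.shape[0]
    target_bases = int(coverage * n_genome)
    reads: list[NucSeq] = []
    truth: list[dict] = []
    total = 0
    i = 0
    mu = np.log(mean_len) - 0.5 * len_sigma**2
    while total < target_bases:
        length = int(rng.lognormal(mu, len_sigma))
        length = max(min_len, min(max_len, length, n_genome))
        start = int(rng.integers(0, n_genome - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        codes = g_codes[start : start + length].copy()

        sub_idx = np.nonzero(rng.random(length) < sub_rate)[0]
        if sub_idx.size:
            shift = rng.integers(1, 4, size=sub_idx.size).astype(np.uint8)
            codes[sub_idx] = (codes[sub_idx] + shift) % 4
        seq = _DECODE[codes].tobytes().decode()

        p = np.where(
            hp_mask[start : start + length], indel_rate * homopolymer_bias,
            indel_rate,
        )
        indel_idx = np.nonzero(rng.random(length) < p)[0]
        n_ins = n_del = 0
        if indel_idx.size:
            parts = []
            prev = 0
            for pos in indel_idx:
                pos = int(pos)
                if rng.random() < 0.5:  # deletion
                    parts.append(seq[prev:pos])
                    n_del += 1
                else:  # insertion: duplicate the base (homopolymer slip)
                    parts.append(seq[prev : pos + 1] + seq[pos])
                    n_ins += 1
                prev = pos + 1
            parts.append(seq[prev:])
            seq = "".join(parts)
        if strand == "-":
            seq = reverse_complement(seq)
        rid = f"read{i:06d}"
        reads.append(NucSeq(rid, seq, quality="B" * len(seq)))
        truth.append(
            {
                "read_id": rid,
                "start": start,
                "end": start + length,
                "strand": strand,
                "n_subs": int(sub_idx.size),
                "n_ins": n_ins,
                "n_del": n_del,
            }
        )
        total += len(seq)
        i += 1
    return reads, truth


# ---------------------------------------------------------------------------
# ORF allele samples (read-extracted-ORF emulation)
# ---------------------------------------------------------------------------

def _safe_alt(orf_nt: str, pos1: int, rng: np.random.Generator,
              prefer: str | None = None) -> str:
    """An alternative base at pos1 that creates neither a stop nor ATG."""
    ref = orf_nt[pos1 - 1]
    codon_start = (pos1 - 1) // 3 * 3
    candidates = [prefer] if prefer else []
    candidates += [b for b in _BASES if b != ref and b != prefer]
    for alt in candidates:
        if alt is None or alt == ref:
            continue
        codon = list(orf_nt[codon_start : codon_start + 3])
        codon[(pos1 - 1) % 3] = alt
        mutated = "".join(codon)
        if mutated not in ("TAA", "TAG", "TGA", "ATG"):
            return alt
    raise RuntimeError(f"no safe substitution at position {pos1}")


def _homopolymer_positions(seq: str) -> list[int]:
    out = []
    for i in range(2, len(seq) - 3):
        if seq[i] == seq[i - 1] == seq[i - 2]:
            out.append(i + 1)  # 1-based
    return out


def make_allele_sample(
    reference_orf: NucSeq,
    n: int = 200,
    seed: int = 0,
    frac_exact: float = 0.13,
    frac_one_change: float = 0.25,
    frac_two_plus: float = 0.19,
    frac_frame_preserving: float = 0.43,
    modal_frac: float = 0.96,
    n_error_indels: int = 4,
) -> tuple[list[NucSeq], list[dict]]:
    """A population of extracted ORF alleles with planted classes.

    Class proportions default to the surveyed population structure:
    13% exact, 25% one-change (with the modal G>C substitution at ORF
    position 385 in ``modal_frac`` of them, the rest carrying one
    substitution in a homopolymer), 19% with two or more substitutions
    drawn from a fixed recurrent-position spectrum, and 43% carrying the
    15-bp in-frame pentapeptide insertion. ``n_error_indels`` records
    additionally carry a rare single-base homopolymer indel emulating
    residual sequencing error (planted on exact-class records; their
    true class is still 'exact' once rare indels are filtered).
    """
    fracs = frac_exact + frac_one_change + frac_two_plus + frac_frame_preserving
    if abs(fracs - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(seed)
    ref = reference_orf.seq
    n_one = int(round(frac_one_change * n))
    n_two = int(round(frac_two_plus * n))
    n_fpi = int(round(frac_frame_preserving * n))
    n_exact = n - n_one - n_two - n_fpi
    if min(n_exact, n_one, n_two, n_fpi) < 0:
        raise ValueError("class fractions inconsistent with n")
    hp_pos = [p for p in _homopolymer_positions(ref) if p > 3]

    specs: list[tuple[str, list[tuple[int, str]], bool]] = []
    for _ in range(n_exact):
        specs.append(("exact", [], False))
    n_modal = int(round(modal_frac * n_one))
    for j in range(n_one):
        if j < n_modal:
            subs = [(MODAL_SUB_POS, _safe_alt(ref, MODAL_SUB_POS, rng,
                                              prefer=MODAL_SUB_ALT))]
        else:
            pos = int(rng.choice(hp_pos))
            subs = [(pos, _safe_alt(ref, pos, rng))]
        specs.append(("one_change", subs, False))
    for _ in range(n_two):
        k = int(rng.integers(2, 5))
        positions = rng.choice(SPECTRUM_POSITIONS, size=k, replace=False)
        subs = [(int(p), _safe_alt(ref, int(p), rng,
                                   prefer=MODAL_SUB_ALT if p == MODAL_SUB_POS
                                   else None))
                for p in sorted(positions)]
        specs.append(("two_plus_change", subs, False))
    for j in range(n_fpi):
        subs = [(MODAL_SUB_POS, MODAL_SUB_ALT)] if j % 2 == 0 else []
        specs.append(("frame_preserving_indel", subs, True))

    order = rng.permutation(len(specs))
    alleles: list[NucSeq] = []
    truth: list[dict] = []
    error_targets = {
        int(order[k]) for k in range(len(order))
        if specs[order[k]][0] == "exact"
    }
    error_targets = set(sorted(error_targets)[:n_error_indels])
    for out_idx, spec_idx in enumerate(order):
        cls, subs, has_ins15 = specs[spec_idx]
        seq = list(ref)
        for pos, alt in subs:
            seq[pos - 1] = alt
        seq_s = "".join(seq)
        if has_ins15:
            seq_s = (seq_s[:INFRAME_INSERT_POS] + IVLYC_NT
                     + seq_s[INFRAME_INSERT_POS:])
        err_indel = 0
        if int(spec_idx) in error_targets:
            pos = int(rng.choice(hp_pos))
            if rng.random() < 0.5:
                seq_s = seq_s[: pos - 1] + seq_s[pos:]
                err_indel = -1
            else:
                seq_s = seq_s[:pos] + seq_s[pos - 1] + seq_s[pos:]
                err_indel = 1
        rid = f"hifi_orf_{out_idx:04d}"
        alleles.append(NucSeq(rid, seq_s))
        truth.append(
            {
                "id": rid,
                "class": cls,
                "n_subs": len(subs),
                "subs": ";".join(f"{p}{a}" for p, a in subs),
                "error_indel_nt": err_indel,
            }
        )
    return alleles, truth
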