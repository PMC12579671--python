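import numpy as np
import pytest

import helpers
from rdnascan.reads import (
    ReadScanConfig,
    check_orf,
    count_orf_reads,
    scan_read,
    six_frame_best,
)
from rdnascan.seqcore import NucSeq, find_orfs, reverse_complement
from rdnascan.simulate import UnitAllele, apply_allele, make_canonical_unit


@pytest.fixture(scope="module")
def locus_read(ref_nt, canonical_3kb):
    """A 2.2-kb read fully containing the antisense locus plus flanks."""
    unit, locus = canonical_3kb
    start = max(0, locus.start - 800)
    return NucSeq("full", unit.seq[start : locus.end + 800])


@pytest.fixture(scope="module")
def partial_reads(ref_nt, canonical_3kb):
    """Reads covering a controlled amount of the 573-nt locus."""
    unit, locus = canonical_3kb

    def cover(n_nt: int) -> NucSeq:
        # locus is antisense: its reference-start sits at locus.end
        return NucSeq(
            f"cover{n_nt}",
            unit.seq[locus.end - n_nt - 0 : locus.end + 600],
        )

    return cover


class TestStages:
    def test_exact_locus_read_passes_all_gates(self, locus_read, ref_nt, ref_prot):
        hit = scan_read(locus_read, ref_prot, ref_nt)
        assert hit.stage1_pass and hit.stage2_pass and hit.orf_found
        assert hit.prot_identity_pct == 100.0
        assert hit.nt_identity_pct == 100.0
        assert hit.matched_len_nt == 573
        assert hit.orf_len_nt == 573
        assert hit.counted

    def test_antisense_read_region_in_reference_orientation(
        self, locus_read, ref_nt, ref_prot
    ):
        flipped = NucSeq("rc", reverse_complement(locus_read.seq))
        hit = scan_read(flipped, ref_prot, ref_nt)
        assert hit.counted
        assert hit.orf_nt.seq == ref_nt.seq

    def test_frameshift_locus_fails_protein_gate(self, ref_nt, ref_prot):
        rng = np.random.default_rng(3)
        mutant = apply_allele(ref_nt.seq, UnitAllele("DEL5"), rng)
        read = NucSeq("del5", "ACGT" * 50 + reverse_complement(mutant) + "TGCA" * 50)
        hit = scan_read(read, ref_prot, ref_nt)
        assert hit.prescan_hit
        assert not hit.stage1_pass
        assert hit.prot_aln_len_aa < 150

    def test_short_read_skipped(self, ref_prot, ref_nt):
        hit = scan_read(NucSeq("tiny", "ACGT" * 30), ref_prot, ref_nt)
        assert not hit.prescan_hit and not hit.counted

    def test_background_read_rejected(self, ref_prot, ref_nt):
        rng = np.random.default_rng(4)
        noise = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        hit = scan_read(NucSeq("bg", noise), ref_prot, ref_nt)
        assert not hit.stage1_pass and not hit.counted

    def test_partial_coverage_passes_stage1_fails_span_gate(
        self, partial_reads, ref_nt, ref_prot
    ):
        # ~520 nt of locus: >150 aa of protein match but <550 nt span
        hit = scan_read(partial_reads(520), ref_prot, ref_nt)
        assert hit.stage1_pass
        assert hit.matched_len_nt < 550
        assert not hit.stage2_pass

    def test_540_nt_span_boundary(self, partial_reads, ref_nt, ref_prot):
        hit = scan_read(partial_reads(540), ref_prot, ref_nt)
        assert hit.matched_len_nt < 550
        assert not hit.stage2_pass

    def test_555_nt_span_passes(self, partial_reads, ref_nt, ref_prot):
        hit = scan_read(partial_reads(560), ref_prot, ref_nt)
        assert hit.matched_len_nt >= 550
        assert hit.stage2_pass


class TestGateConventions:
    def test_protein_identity_gate_is_strict(self, locus_read, ref_nt, ref_prot):
        hit = scan_read(locus_read, ref_prot, ref_nt)  # identity 100, 190 cols
        at_value = ReadScanConfig(min_prot_identity_pct=100.0)
        below = ReadScanConfig(min_prot_identity_pct=99.9)
        assert not scan_read(locus_read, ref_prot, ref_nt, at_value).stage1_pass
        assert scan_read(locus_read, ref_prot, ref_nt, below).stage1_pass
        assert hit.prot_identity_pct == 100.0

    def test_protein_length_gate_is_strict(self, locus_read, ref_nt, ref_prot):
        at_value = ReadScanConfig(min_prot_len_aa=190)
        below = ReadScanConfig(min_prot_len_aa=189)
        assert not scan_read(locus_read, ref_prot, ref_nt, at_value).stage1_pass
        assert scan_read(locus_read, ref_prot, ref_nt, below).stage1_pass

    def test_nt_span_gate_is_inclusive(self, locus_read, ref_nt, ref_prot):
        at_value = ReadScanConfig(min_nt_span=573)
        above = ReadScanConfig(min_nt_span=574)
        assert scan_read(locus_read, ref_prot, ref_nt, at_value).stage2_pass
        assert not scan_read(locus_read, ref_prot, ref_nt, above).stage2_pass

    def test_orf_gate_is_inclusive(self, locus_read, ref_nt, ref_prot):
        at_value = ReadScanConfig(min_orf_nt=573)
        above = ReadScanConfig(min_orf_nt=574)
        assert scan_read(locus_read, ref_prot, ref_nt, at_value).orf_found
        assert not scan_read(locus_read, ref_prot, ref_nt, above).orf_found


@pytest.fixture(scope="module")
def mixed_reads(ref_nt, canonical_3kb):
    """Locus-bearing, partial, frameshift-locus and background reads."""
    unit, locus = canonical_3kb
    rng = np.random.default_rng(5)
    reads = []
    for i in range(4):  # full locus, error-free
        start = locus.start - 150 - 40 * i
        reads.append(NucSeq(f"full{i}", unit.seq[start : locus.end + 150 + 30 * i]))
    for i in range(2):  # antisense orientation
        reads.append(NucSeq(f"rc{i}", reverse_complement(reads[i].seq)))
    for n in (460, 520, 555):  # partial coverage
        reads.append(NucSeq(f"part{n}", unit.seq[locus.end - n : locus.end + 600]))
    mutant = apply_allele(ref_nt.seq, UnitAllele("DEL5"), rng)
    reads.append(NucSeq("fs", "AC" * 100 + reverse_complement(mutant) + "GT" * 100))
    for i in range(3):  # background
        noise = "".join("ACGT"[j] for j in rng.integers(0, 4, size=1500))
        reads.append(NucSeq(f"bg{i}", noise))
    return reads


class TestCounting:
    def test_empty_read_set(self, ref_nt, ref_prot):
        count, hits, summary = count_orf_reads([], ref_prot, ref_nt)
        assert count == 0 and hits == [] and summary["reads_in"] == 0

    def test_mixed_set_counts(self, mixed_reads, ref_nt, ref_prot):
        count, hits, summary = count_orf_reads(mixed_reads, ref_prot, ref_nt)
        counted = {h.read_id for h in hits if h.counted}
        # only reads containing the ORF end-to-end count: a 555-nt
        # partial region clears the span gate but lacks the stop codon,
        # and stop-less ATG runs are never reported as ORFs
        assert counted == {"full0", "full1", "full2", "full3", "rc0", "rc1"}
        by_id = {h.read_id: h for h in hits}
        assert by_id["part555"].stage2_pass and not by_id["part555"].orf_found
        assert summary["orf_reads"] == 6

    def test_strand_symmetry(self, mixed_reads, ref_nt, ref_prot):
        flipped = [
            NucSeq(r.id, reverse_complement(r.seq)) for r in mixed_reads
        ]
        c1, _, _ = count_orf_reads(mixed_reads, ref_prot, ref_nt)
        c2, _, _ = count_orf_reads(flipped, ref_prot, ref_nt)
        assert c1 == c2

    def test_doubling_reads_doubles_count(self, mixed_reads, ref_nt, ref_prot):
        c1, _, _ = count_orf_reads(mixed_reads, ref_prot, ref_nt)
        doubled = mixed_reads + [
            NucSeq(r.id + "_dup", r.seq) for r in mixed_reads
        ]
        c2, _, _ = count_orf_reads(doubled, ref_prot, ref_nt)
        assert c2 == 2 * c1

    def test_gate_monotonicity(self, mixed_reads, ref_nt, ref_prot):
        grids = [
            ReadScanConfig(),
            ReadScanConfig(min_prot_identity_pct=90),
            ReadScanConfig(min_prot_identity_pct=90, min_prot_len_aa=170),
            ReadScanConfig(min_prot_identity_pct=90, min_prot_len_aa=170,
                           min_nt_span=560),
            ReadScanConfig(min_prot_identity_pct=95, min_prot_len_aa=180,
                           min_nt_span=570, min_orf_nt=500),
        ]
        retained = []
        for cfg in grids:
            _, hits, _ = count_orf_reads(mixed_reads, ref_prot, ref_nt, cfg)
            retained.append({h.read_id for h in hits if h.counted})
        for looser, stricter in zip(retained, retained[1:]):
            assert stricter <= looser


class TestCheckOrf:
    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(6)
        n_found = 0
        for _ in range(50):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=600))
            found, orf = check_orf(NucSeq("r", seq), min_len_nt=180)
            oracle = helpers.brute_force_orfs(seq, 180)
            assert found == bool(oracle)
            if found:
                n_found += 1
                assert orf.length_nt == max(e - s for s, e, _ in oracle)
        assert n_found < 25  # random 600-mers mostly lack a 180-nt ORF

    def test_longest_reported(self, ref_nt):
        found, orf = check_orf(ref_nt, min_len_nt=6)
        assert found and orf.length_nt == 573
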