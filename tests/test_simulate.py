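import numpy as np
import pytest

from rdnascan.seqcore import NucSeq, find_orfs, reverse_complement, translate
from rdnascan.simulate import (
    AllelePlan,
    IVLYC_NT,
    INFRAME_INSERT_POS,
    UnitAllele,
    apply_allele,
    default_plan,
    demo_plan,
    make_allele_sample,
    make_array,
    make_canonical_unit,
    make_genome,
    make_reference_orf,
    simulate_reads,
)


class TestReferenceOrf:
    def test_deterministic(self):
        a = make_reference_orf(seed=5)
        b = make_reference_orf(seed=5)
        assert a[0].seq == b[0].seq and a[1].seq == b[1].seq

    def test_arithmetic(self, ref_nt, ref_prot):
        assert len(ref_nt.seq) == 3 * (190 + 1) == 573
        assert len(ref_prot.residues) == 190
        assert ref_nt.seq.startswith("ATG")
        assert ref_nt.seq[-3:] in ("TAA", "TAG", "TGA")
        assert translate(ref_nt.seq) == ref_prot.seq

    def test_single_orf_postcondition(self, ref_nt):
        calls = find_orfs(ref_nt, min_len_nt=180, both_strands=True)
        assert len(calls) == 1 and calls[0].length_nt == 573

    def test_length_validation(self):
        with pytest.raises(ValueError):
            make_reference_orf(length_aa=10)


class TestAlleles:
    def test_edit_lengths(self, ref_nt):
        rng = np.random.default_rng(0)
        assert len(apply_allele(ref_nt.seq, UnitAllele("DEL5"), rng)) == 568
        assert len(apply_allele(ref_nt.seq, UnitAllele("INS5"), rng)) == 578
        assert len(apply_allele(ref_nt.seq, UnitAllele("INS10"), rng)) == 583
        ins15 = apply_allele(ref_nt.seq, UnitAllele("INS15_INFRAME"), rng)
        assert len(ins15) == 588
        assert ins15[INFRAME_INSERT_POS : INFRAME_INSERT_POS + 15] == IVLYC_NT

    def test_substitutions_applied(self, ref_nt):
        rng = np.random.default_rng(0)
        out = apply_allele(
            ref_nt.seq, UnitAllele("COMPLETE", ((400, "G"),)), rng
        )
        assert out[399] == "G" and out[:399] == ref_nt.seq[:399]

    def test_in_frame_insertion_extends_product(self, ref_nt):
        rng = np.random.default_rng(0)
        ins15 = apply_allele(ref_nt.seq, UnitAllele("INS15_INFRAME"), rng)
        prot = translate(ins15)
        assert prot.endswith("*") and prot.count("*") == 1
        assert len(prot) - 1 == 195

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            UnitAllele("DEL7")


class TestPlans:
    def test_default_plan_counts(self):
        plan = default_plan()
        assert plan.n_units == 219
        assert plan.n_complete == 43
        assert plan.count_status("FRAME_PRESERVING_INDEL") == 1
        per_chrom = {c: 0 for c in plan.chroms()}
        complete_chr = {c: 0 for c in plan.chroms()}
        for chrom, _, allele in plan.entries:
            per_chrom[chrom] += 1
            complete_chr[chrom] += allele.expected_status == "COMPLETE"
        assert per_chrom == {
            "chr13": 76, "chr14": 16, "chr15": 50, "chr21": 56, "chr22": 21
        }
        assert complete_chr == {
            "chr13": 1, "chr14": 2, "chr15": 0, "chr21": 39, "chr22": 1
        }

    def test_duplicate_entries_rejected(self):
        with pytest.raises(ValueError):
            AllelePlan(
                entries=[
                    ("chrA", 1, UnitAllele("COMPLETE")),
                    ("chrA", 1, UnitAllele("DEL5")),
                ]
            )


class TestArrayAndGenome:
    def test_array_deterministic(self, ref_nt):
        plan = demo_plan(seed=3)
        a, _ = make_array(plan, ref_nt, unit_len_bp=3000, seed=3)
        b, _ = make_array(plan, ref_nt, unit_len_bp=3000, seed=3)
        assert [r.seq for r in a] == [r.seq for r in b]

    def test_headers_and_truth(self, demo_array):
        plan, units, truth = demo_array
        assert [u.id for u in units] == [
            f"{c}|{i}" for c, i, _ in plan.entries
        ]
        assert truth.true_rdna_units == 12
        assert truth.true_complete_units == 5
        assert truth.true_orf_capable_units == 6

    def test_planted_locus_is_antisense_copy(self, ref_nt, demo_array):
        plan, units, truth = demo_array
        for rec, row in zip(units, truth.unit_rows):
            if row["allele"] != "COMPLETE" or row["subs"]:
                continue
            start = row["locus_start_in_unit"]
            segment = rec.seq[start : start + row["locus_len"]]
            assert reverse_complement(segment) == ref_nt.seq

    def test_empty_plan(self, ref_nt):
        units, truth = make_array(
            AllelePlan(entries=[]), ref_nt, unit_len_bp=3000
        )
        assert units == [] and truth.true_rdna_units == 0

    def test_unit_too_small_rejected(self, ref_nt):
        with pytest.raises(ValueError):
            make_canonical_unit(ref_nt, unit_len_bp=600)

    def test_genome_coordinates(self, ref_nt, demo_array):
        plan, units, truth = demo_array
        genome = make_genome(units, truth, background_bp=2000, seed=3)
        assert truth.genome_size_bp == len(genome.seq)
        assert truth.genome_size_bp == 2 * 2000 + sum(len(u.seq) for u in units)
        for locus in truth.genome_loci:
            seg = genome.seq[locus["start"] : locus["end"]]
            if locus["allele"] == "COMPLETE":
                assert reverse_complement(seg)[:3] == "ATG"


@pytest.fixture(scope="module")
def small_genome(ref_nt):
    plan = demo_plan(seed=2)
    units, truth = make_array(plan, ref_nt, unit_len_bp=3000, seed=2)
    return make_genome(units, truth, background_bp=5000, seed=2)


class TestReadSimulation:
    def test_error_free_reads_are_substrings(self, small_genome):
        reads, truth = simulate_reads(
            small_genome, coverage=3, mean_len=2000, sub_rate=0.0,
            indel_rate=0.0, seed=4, min_len=500, max_len=5000,
        )
        for read, row in zip(reads, truth):
            fragment = small_genome.seq[row["start"] : row["end"]]
            if row["strand"] == "-":
                fragment = reverse_complement(fragment)
            assert read.seq == fragment

    def test_deterministic(self, small_genome):
        a, _ = simulate_reads(small_genome, coverage=2, mean_len=2000, seed=9)
        b, _ = simulate_reads(small_genome, coverage=2, mean_len=2000, seed=9)
        assert [r.seq for r in a] == [r.seq for r in b]

    def test_coverage_bookkeeping(self, small_genome):
        reads, _ = simulate_reads(
            small_genome, coverage=10, mean_len=2000, seed=5
        )
        total = sum(len(r.seq) for r in reads)
        achieved = total / len(small_genome.seq)
        assert achieved == pytest.approx(10, rel=0.05)

    def test_error_counts_recorded(self, small_genome):
        reads, truth = simulate_reads(
            small_genome, coverage=2, mean_len=2000, sub_rate=0.01,
            indel_rate=0.005, seed=6,
        )
        assert sum(r["n_subs"] for r in truth) > 0
        assert sum(r["n_ins"] + r["n_del"] for r in truth) > 0

    def test_rate_validation(self, small_genome):
        with pytest.raises(ValueError):
            simulate_reads(small_genome, coverage=1, sub_rate=0.2)
        with pytest.raises(ValueError):
            simulate_reads(small_genome, coverage=0)


class TestAlleleSample:
    def test_class_counts_and_determinism(self, ref_nt):
        alleles, truth = make_allele_sample(ref_nt, n=200, seed=7)
        counts = {}
        for row in truth:
            counts[row["class"]] = counts.get(row["class"], 0) + 1
        assert counts == {
            "exact": 26,
            "one_change": 50,
            "two_plus_change": 38,
            "frame_preserving_indel": 86,
        }
        again, _ = make_allele_sample(ref_nt, n=200, seed=7)
        assert [a.seq for a in alleles] == [a.seq for a in again]

    def test_modal_substitution_planted(self, ref_nt):
        alleles, truth = make_allele_sample(ref_nt, n=200, seed=7)
        modal = [
            r for r in truth
            if r["class"] == "one_change" and r["subs"] == "385C"
        ]
        assert len(modal) == 48  # 96% of the 50 one-change records

    def test_invalid_fractions(self, ref_nt):
        with pytest.raises(ValueError):
            make_allele_sample(ref_nt, n=10, frac_exact=0.5)
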