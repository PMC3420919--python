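import numpy as np
import pytest

from apasnp.io_formats import GeneModel, ReadPlacement, SnpRecord
from apasnp.rnaseq_allelics import (
    AlleleCounts,
    build_allele_references,
    call_genotype,
    consensus_genotype,
    corrected_allelic_imbalance,
    count_alleles,
    imbalance_scan,
    imbalance_test,
    map_score,
)


def _counts(snp, a_w, b_w, apa="G", version="ref"):
    non = snp.alt_allele if apa == snp.ref_allele else snp.ref_allele
    return AlleleCounts("s", "x", version, weight={apa: a_w, non: b_w},
                        n_reads={apa: 1, non: 1})


@pytest.fixture
def snp():
    return SnpRecord("s", "c", 50, "A", "G", {"A": 0.5, "G": 0.5})


def _read(base, q_char, start=45, n_mm=0, length=11):
    seq = "C" * (50 - start) + base + "C" * (length - (50 - start) - 1)
    return ReadPlacement("r", "t", start, n_mm, seq, q_char * length)


class TestCountAlleles:
    def test_weight_is_accuracy_times_map_score(self, snp):
        # Q20 -> accuracy 0.99; perfect alignment -> map score 1
        counts = count_alleles([_read("A", "5")], snp, 50, "x", "ref")
        assert counts.weight["A"] == pytest.approx(0.99)
        assert counts.weight["G"] == 0.0

    def test_low_accuracy_read_dropped(self, snp):
        # Q3 -> accuracy ~0.5 < 0.9
        counts = count_alleles([_read("A", "$")], snp, 50, "x", "ref")
        assert counts.total() == 0.0

    def test_off_panel_base_dropped(self, snp):
        counts = count_alleles([_read("T", "I")], snp, 50, "x", "ref")
        assert counts.total() == 0.0

    def test_too_many_mismatches_dropped(self, snp):
        counts = count_alleles([_read("A", "I", n_mm=11)], snp, 50, "x", "ref")
        assert counts.total() == 0.0

    def test_mismatches_scale_map_score(self, snp):
        counts = count_alleles([_read("A", "I", n_mm=2, length=10)],
                               snp, 50, "x", "ref")
        acc = 1 - 10 ** -4
        assert counts.weight["A"] == pytest.approx(acc * 0.8)

    def test_monotone_in_added_reads(self, snp):
        one = count_alleles([_read("A", "I")], snp, 50, "x", "ref")
        two = count_alleles([_read("A", "I")] * 2, snp, 50, "x", "ref")
        assert two.weight["A"] >= one.weight["A"]


class TestGenotypeCall:
    def test_both_proportions_above_cutoff_is_het(self, snp):
        call = call_genotype(_counts(snp, 8.2, 1.8, apa="A"), snp)
        assert call.call == "het"

    def test_majority_hom(self, snp):
        call = call_genotype(_counts(snp, 9.5, 0.5, apa="A"), snp)
        assert call.call == "hom_ref"

    def test_boundary_proportion_is_hom(self, snp):
        call = call_genotype(_counts(snp, 8.5, 1.5, apa="A"), snp)
        assert call.call == "hom_ref"        # 0.15 exactly, strict >

    def test_zero_total_no_call(self, snp):
        call = call_genotype(_counts(snp, 0, 0, apa="A"), snp)
        assert call.call == "no_call"


class TestConsensus:
    def _call(self, snp, kind):
        from apasnp.rnaseq_allelics import GenotypeCall
        return GenotypeCall("s", "x", kind)

    def test_het_het(self, snp):
        cons = consensus_genotype(self._call(snp, "het"), self._call(snp, "het"),
                                  snp, "G")
        assert cons.call == "het" and cons.encoded == 1

    def test_het_hom_conflict(self, snp):
        cons = consensus_genotype(self._call(snp, "het"),
                                  self._call(snp, "hom_ref"), snp, "G")
        assert cons.call == "no_call" and cons.encoded is None

    def test_hom_agreement_encodes_apa_dosage(self, snp):
        cons = consensus_genotype(self._call(snp, "hom_alt"),
                                  self._call(snp, "hom_alt"), snp, "G")
        assert cons.encoded == 2
        cons = consensus_genotype(self._call(snp, "hom_ref"),
                                  self._call(snp, "hom_ref"), snp, "G")
        assert cons.encoded == 0


class TestCorrectedImbalance:
    def test_symmetric_counts(self, snp):
        rec = corrected_allelic_imbalance(
            _counts(snp, 20, 10, version="ref"), _counts(snp, 20, 10, version="alt"),
            snp, "G")
        assert rec.corrected_ai == pytest.approx(1.0)

    def test_asymmetric_counts(self, snp):
        rec = corrected_allelic_imbalance(
            _counts(snp, 30, 10, version="ref"), _counts(snp, 10, 10, version="alt"),
            snp, "G")
        assert rec.corrected_ai == pytest.approx(0.5 * np.log2(3), abs=1e-9)

    def test_bias_cancellation(self, snp):
        # rho=2, beta=1.5 applied oppositely in the two versions
        rho, beta, c = 2.0, 1.5, 30.0
        rec = corrected_allelic_imbalance(
            _counts(snp, rho * c / beta, c, version="ref"),
            _counts(snp, rho * c, c / beta, version="alt"),
            snp, "G")
        assert rec.corrected_ai == pytest.approx(1.0, abs=1e-12)

    def test_zero_weight_undefined(self, snp):
        rec = corrected_allelic_imbalance(
            _counts(snp, 0, 10), _counts(snp, 10, 10), snp, "G")
        assert rec is None

    def test_antisymmetry_under_allele_swap(self, snp, rng):
        for _ in range(50):
            w = rng.uniform(1, 50, size=4)
            fwd = corrected_allelic_imbalance(
                _counts(snp, w[0], w[1], version="ref"),
                _counts(snp, w[2], w[3], version="alt"), snp, "G")
            rev = corrected_allelic_imbalance(
                _counts(snp, w[1], w[0], apa="A", version="ref"),
                _counts(snp, w[3], w[2], apa="A", version="alt"), snp, "A")
            assert fwd.corrected_ai == pytest.approx(-rev.corrected_ai, abs=1e-12)


class TestImbalanceTest:
    def test_equal_counts_p_one(self, snp):
        rec = corrected_allelic_imbalance(
            _counts(snp, 10, 10), _counts(snp, 10, 10, version="alt"), snp, "G")
        rec = imbalance_test(rec, _counts(snp, 10, 10),
                             _counts(snp, 10, 10, version="alt"), snp, "G")
        assert rec.p_value == pytest.approx(1.0)

    def test_15_5_matches_closed_form(self, snp):
        a, b = _counts(snp, 15, 5), _counts(snp, 15, 5, version="alt")
        rec = corrected_allelic_imbalance(a, b, snp, "G")
        rec = imbalance_test(rec, a, b, snp, "G")
        assert rec.chi2_stat == pytest.approx(5.0)
        assert rec.p_value == pytest.approx(0.0253473187, abs=1e-9)

    def test_below_count_floor_skipped(self, snp):
        a, b = _counts(snp, 6, 3), _counts(snp, 6, 3, version="alt")
        rec = corrected_allelic_imbalance(a, b, snp, "G")
        rec = imbalance_test(rec, a, b, snp, "G")
        assert rec.p_value is None


class TestImbalanceScan:
    def test_single_test_q_equals_p(self, snp):
        a, b = _counts(snp, 15, 5), _counts(snp, 15, 5, version="alt")
        df = imbalance_scan([(a, b, snp, "G")])
        assert df.loc[0, "q_bh"] == pytest.approx(df.loc[0, "p"])
        assert df.loc[0, "q_bonf"] == pytest.approx(df.loc[0, "p"])


class TestAlleleReferences:
    def test_overlapping_utrs_merged_and_alt_substituted(self):
        chrom = "A" * 200
        g1 = GeneModel("g1", "c", "+", [(50, 100)], 50, [(50, 100)], 100)
        g2 = GeneModel("g2", "c", "+", [(120, 160)], 120, [(120, 160)], 160)
        snp = SnpRecord("s", "c", 70, "A", "G", {"A": 0.5, "G": 0.5})
        ref, alt, where = build_allele_references([g1, g2], {"c": chrom}, [snp])
        assert len(ref) == 1          # extension by 50 merges the two spans
        (name,) = ref
        region, off = where["s"]
        assert region == name
        assert ref[name][off] == "A" and alt[name][off] == "G"
        assert ref[name][:off] == alt[name][:off]

    def test_disjoint_utrs_preserved(self):
        chrom = "A" * 500
        g1 = GeneModel("g1", "c", "+", [(50, 100)], 50, [(50, 100)], 100)
        g2 = GeneModel("g2", "c", "+", [(300, 350)], 300, [(300, 350)], 350)
        snp = SnpRecord("s", "c", 70, "A", "G", {"A": 0.5, "G": 0.5})
        ref, _, _ = build_allele_references([g1, g2], {"c": chrom}, [snp])
        assert len(ref) == 2

    def test_snp_outside_regions_rejected(self):
        chrom = "A" * 500
        g1 = GeneModel("g1", "c", "+", [(50, 100)], 50, [(50, 100)], 100)
        snp = SnpRecord("s", "c", 400, "A", "G", {"A": 0.5, "G": 0.5})
        with pytest.raises(ValueError, match="outside"):
            build_allele_references([g1], {"c": chrom}, [snp])


def test_map_score_properties():
    assert map_score(36, 0) == 1.0
    assert map_score(36, 9) == 0.75
    with pytest.raises(ValueError):
        map_score(0, 0)
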