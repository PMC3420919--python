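import numpy as np
import pytest

from apasnp.io_formats import GeneModel, SnpRecord, reverse_complement
from apasnp.signal_scan import (
    HEXAMER_RANK,
    SIGNAL_HEXAMERS,
    classify_change,
    classify_strength,
    end_window_density,
    filter_candidates,
    hexamer_enrichment,
    hexamer_hits,
    intersect_polya_sites,
    scan_snps,
    snp_density_profile,
    snp_window,
)
from apasnp.synthetic_data import random_sequence


def test_signal_table_order():
    # the 13 known hexamers, strongest first
    assert SIGNAL_HEXAMERS[0] == "AATAAA"
    assert SIGNAL_HEXAMERS[-1] == "AATAGA"
    assert len(set(SIGNAL_HEXAMERS)) == 13


class TestSnpWindow:
    def test_center_construction(self):
        ref, alt = snp_window("CCTAATCAACCTT", 6, "C", "A")
        assert ref == "CCTAATCAACCTT"
        assert alt == "CCTAATAAACCTT"

    def test_short_utr_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            snp_window("A" * 12, 5, "A", "G")

    def test_window_clipped_near_utr_edge(self):
        ref, alt = snp_window("ACGTACGTACGTA", 1, "C", "G")
        assert ref == "ACGTACGT"       # offsets 0..7
        assert alt == "AGGTACGT"

    def test_mismatched_ref_allele_rejected(self):
        with pytest.raises(ValueError, match="reference allele"):
            snp_window("CCTAATCAACCTT", 6, "G", "A")


class TestClassifyChange:
    def test_created_signal(self):
        ch = classify_change("s", "CCTAATCAACCTT", "CCTAATAAACCTT", "C", "A")
        assert ch.change_kind == "created"
        assert ch.hexamer == "AATAAA" and ch.rank == 1
        assert ch.apa_allele == "A"
        assert ch.signal_start_offset == -3

    def test_disrupted_is_mirror_of_created(self):
        ch = classify_change("s", "CCTAATAAACCTT", "CCTAATCAACCTT", "A", "C")
        assert ch.change_kind == "disrupted"
        assert ch.apa_allele == "A"

    def test_signal_to_signal(self):
        ch = classify_change("s", "GGAATACATGGTC", "GGAATAAATGGTC", "C", "A")
        assert ch.change_kind == "signal_to_signal"

    def test_none_without_hexamer(self):
        ch = classify_change("s", "CCCCCCGCCCCCC", "CCCCCCACCCCCC", "G", "A")
        assert ch.change_kind == "none"

    def test_best_rank_reported_on_multiple_hits(self):
        # alt allele completes AATAAA at one offset and TTTAAA overlapping:
        # AATTTAAA around centre; build windows by brute force check
        ref = "CAATTCAAATCGC"
        alt = "CAATTTAAATCGC"        # TTTAAA at offset 3, ATTAAA at 2
        ch = classify_change("s", ref, alt, "C", "T")
        assert ch.change_kind == "created"
        assert ch.rank == min(
            HEXAMER_RANK[h] for _, h in hexamer_hits(alt)
        )

    def test_strand_symmetry(self, rng):
        # scanning a minus-strand gene equals scanning the revcomp as plus
        for _ in range(50):
            seq = random_sequence(rng, 61, (0.4, 0.1, 0.1, 0.4))
            off = 30
            ref = seq[off]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            snp_plus = SnpRecord("s", "c", off, ref, alt, {ref: 0.5, alt: 0.5})
            gene_plus = GeneModel("g", "c", "+", [(0, 61)], 0, [(0, 61)], 61)
            rc = reverse_complement(seq)
            gene_minus = GeneModel("g", "c", "-", [(0, 61)], 61, [(0, 61)], 0)
            ref_g = reverse_complement(ref)      # genomic-strand alleles
            alt_g = reverse_complement(alt)
            snp_minus = SnpRecord("s", "c", 60 - off, ref_g, alt_g,
                                  {ref_g: 0.5, alt_g: 0.5})
            (ch_p,), _, _, _ = scan_snps([snp_plus], [gene_plus], {"c": seq})
            (ch_m,), _, _, _ = scan_snps([snp_minus], [gene_minus], {"c": rc})
            assert ch_p.change_kind == ch_m.change_kind
            assert ch_p.hexamer == ch_m.hexamer


def _mk_filter_args(utr, off, ref, alt, maf):
    snp = SnpRecord("s", "c", off, ref, alt, {ref: 1 - maf, alt: maf})
    gene = GeneModel("g", "c", "+", [(0, len(utr))], 0, [(0, len(utr))],
                     len(utr))
    ref_win, alt_win = snp_window(utr, off, ref, alt)
    centre = off - max(0, off - 6)
    ch = classify_change("s", ref_win, alt_win, ref, alt, centre)
    return ch, {"s": snp}, {"g": gene}, {"s": "g"}, {"g": utr}, {"s": off}


class TestFilterCandidates:
    base = "C" * 30 + "CCTAATCAACCTT" + "C" * 30   # SNP at offset 36

    def test_clean_created_kept(self):
        args = _mk_filter_args(self.base, 36, "C", "A", 0.3)
        kept = filter_candidates([args[0]], *args[1:])
        assert len(kept) == 1
        assert kept[0].distance_to_annotated_end == len(self.base) - 37

    def test_second_signal_in_locus_discarded(self):
        utr = self.base[:48] + "AATAAA" + self.base[54:]   # 12 nt downstream
        args = _mk_filter_args(utr, 36, "C", "A", 0.3)
        assert filter_candidates([args[0]], *args[1:]) == []

    def test_mono_allelic_discarded(self):
        args = _mk_filter_args(self.base, 36, "C", "A", 0.0)
        assert filter_candidates([args[0]], *args[1:]) == []

    def test_signal_to_signal_discarded(self):
        utr = "C" * 30 + "GGAATACATGGTC" + "C" * 30
        args = _mk_filter_args(utr, 36, "C", "A", 0.3)
        assert args[0].change_kind == "signal_to_signal"
        assert filter_candidates([args[0]], *args[1:]) == []


@pytest.mark.parametrize("rank,cutoff,expected", [
    (1, 2, "strong"), (2, 2, "strong"), (3, 2, "weak"),
    (13, 2, "weak"), (5, 5, "strong"),
])
def test_classify_strength(rank, cutoff, expected):
    assert classify_strength(rank, cutoff) == expected


class TestPolyaSiteIntersection:
    def _candidate(self, utr_len=200, off=100, sig_end_offset=3):
        args = _mk_filter_args("C" * 94 + "CCTAATCAACCTT" + "C" * 93,
                               100, "C", "A", 0.3)
        (cand,) = filter_candidates([args[0]], *args[1:])
        return cand

    def test_site_30nt_downstream_matched(self):
        cand = self._candidate()
        sig_end = cand.utr_offset + cand.change.signal_end_offset
        pairs = intersect_polya_sites([cand], {"g": [sig_end + 30]})
        assert len(pairs) == 1

    def test_site_41nt_downstream_unmatched(self):
        cand = self._candidate()
        sig_end = cand.utr_offset + cand.change.signal_end_offset
        assert intersect_polya_sites([cand], {"g": [sig_end + 41]}) == []

    def test_candidate_near_utr_end_flagged(self):
        utr = "C" * 94 + "CCTAATCAACCTT" + "C" * 3   # 9 nt to the end
        args = _mk_filter_args(utr, 100, "C", "A", 0.3)
        (cand,) = filter_candidates([args[0]], *args[1:])
        intersect_polya_sites([cand], {})
        assert cand.near_utr_end


class TestHexamerEnrichment:
    def test_single_utr_single_motif(self):
        rows = hexamer_enrichment(["AATAAA"])
        by_hex = {r["hexamer"]: r for r in rows}
        assert by_hex["AATAAA"]["count"] == 1
        assert sum(r["count"] for r in rows) == 1
        assert by_hex["AATAAA"]["motif_freq"] == 1.0

    def test_ratio_invariant_to_duplication(self):
        utrs = ["AATAAACCCATTAAA", "TTTAAAGG"]
        r1 = hexamer_enrichment(utrs)
        r2 = hexamer_enrichment(utrs * 3)
        for a, b in zip(r1, r2):
            assert a["motif_freq"] == pytest.approx(b["motif_freq"])

    def test_counts_match_sliding_count(self, rng):
        seq = random_sequence(rng, 20000, (0.35, 0.15, 0.15, 0.35))
        rows = hexamer_enrichment([seq])
        for r in rows:
            brute = sum(
                1 for i in range(len(seq) - 5) if seq[i:i + 6] == r["hexamer"]
            )
            assert r["count"] == brute


class TestSnpDensity:
    def test_uniform_positions_near_flat(self, rng):
        dens = snp_density_profile(rng.random(20000), n_bins=10)
        assert np.allclose(dens, 1.0, atol=0.1)

    def test_depleted_bin_lowest(self, rng):
        pos = rng.random(5000)
        pos = pos[(pos < 0.8) | (pos > 0.9)]
        dens = snp_density_profile(pos, n_bins=10)
        assert dens.argmin() == 8

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            snp_density_profile([])

    def test_end_window_density_mean_one(self, rng):
        dens = end_window_density(rng.integers(0, 200, 2000), window=200)
        assert dens.mean() == pytest.approx(1.0)
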