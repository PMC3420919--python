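import numpy as np
import pandas as pd
import pytest

from apasnp.gu_content import gu_profile
from apasnp.io_formats import SnpRecord
from apasnp.signal_scan import filter_candidates, scan_snps
from apasnp.synthetic_data import (
    SimulationConfig,
    genotypes_from_panel,
    make_genome,
    plant_candidate_snp,
    simulate_expression,
    simulate_ests,
    simulate_haplotypes,
    simulate_mirna_profile,
    simulate_reads,
)


class TestMakeGenome:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=5, n_genes=5)
        s1, _ = make_genome(cfg)
        s2, _ = make_genome(cfg)
        assert s1 == s2

    def test_all_a_composition(self):
        cfg = SimulationConfig(seed=1, n_genes=3,
                               base_composition=(1.0, 0.0, 0.0, 0.0))
        seqs, genes = make_genome(cfg)
        for g in genes:
            s, e = g.utr3_intervals[0]
            assert set(seqs[g.chrom][s:e]) == {"A"}

    def test_gc_content_concentrates(self):
        cfg = SimulationConfig(seed=2, n_genes=40,
                               utr_length_range=(1000, 1000),
                               base_composition=(0.3, 0.2, 0.2, 0.3))
        seqs, genes = make_genome(cfg)
        allseq = "".join(seqs.values())
        gc = sum(1 for b in allseq if b in "GC") / len(allseq)
        assert abs(gc - 0.4) < 0.02

    def test_infeasible_range_rejected(self):
        with pytest.raises(ValueError):
            make_genome(SimulationConfig(utr_length_range=(10, 5)))


class TestPlantCandidate:
    def _plant(self, rank, gu_class, seed=3, kind="created"):
        cfg = SimulationConfig(seed=seed, n_genes=1,
                               utr_length_range=(500, 500))
        seqs, genes = make_genome(cfg)
        gene = genes[0]
        rng = cfg.rng("plant")
        snp, edited, truth = plant_candidate_snp(
            seqs[gene.chrom], gene, rank, gu_class, 120, 0.4, rng, kind=kind)
        return snp, edited, truth, gene

    @pytest.mark.parametrize("rank,gu_class", [(1, "rich"), (13, "poor")])
    def test_closed_loop_with_scanner(self, rank, gu_class):
        snp, edited, truth, gene = self._plant(rank, gu_class)
        changes, sg, so, utrs = scan_snps([snp], [gene],
                                          {gene.chrom: edited})
        (change,) = changes
        assert change.change_kind == "created"
        assert change.rank == rank
        kept = filter_candidates(changes, {snp.snp_id: snp},
                                 {gene.gene_id: gene}, sg, utrs, so)
        assert len(kept) == 1
        # GU class check via the profile downstream of the signal end
        utr = utrs[gene.gene_id]
        apa_utr = utr[:so[snp.snp_id]] + change.apa_allele \
            + utr[so[snp.snp_id] + 1:]
        sig_end = so[snp.snp_id] + change.signal_end_offset
        prof = gu_profile(apa_utr[sig_end + 1:])
        assert prof.gu_rich is (gu_class == "rich")

    def test_disrupted_kind(self):
        snp, edited, truth, gene = self._plant(2, "poor", kind="disrupted")
        changes, *_ = scan_snps([snp], [gene], {gene.chrom: edited})
        assert changes[0].change_kind == "disrupted"
        assert changes[0].apa_allele == snp.ref_allele

    def test_infeasible_distance_rejected(self):
        cfg = SimulationConfig(seed=3, n_genes=1, utr_length_range=(500, 500))
        seqs, genes = make_genome(cfg)
        with pytest.raises(ValueError, match="locus does not fit"):
            plant_candidate_snp(seqs[genes[0].chrom], genes[0], 1, "rich",
                                10, 0.4, cfg.rng("x"))


class TestHaplotypes:
    def _snps(self, n=10, freq=0.5):
        return [
            SnpRecord(f"s{i}", "c", i * 100, "A", "G",
                      {"A": 1 - freq, "G": freq})
            for i in range(n)
        ]

    def test_same_seed_identical(self):
        snps = self._snps()
        p1 = simulate_haplotypes(snps, 50, seed=9)
        p2 = simulate_haplotypes(snps, 50, seed=9)
        assert p1.equals(p2)

    def test_no_coupling_near_zero_r(self):
        snps = self._snps(2)
        panel = simulate_haplotypes(snps, 500, coupling=0.0, seed=1)
        a = (panel["s0"] == "G").astype(float)
        b = (panel["s1"] == "G").astype(float)
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.1

    def test_perfect_coupling_r_one(self):
        snps = self._snps(2)
        panel = simulate_haplotypes(snps, 200, coupling=1.0, seed=1)
        a = (panel["s0"] == "G").astype(float)
        b = (panel["s1"] == "G").astype(float)
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)

    def test_allele_frequency_matches_spec(self):
        snps = self._snps(1, freq=0.3)
        panel = simulate_haplotypes(snps, 2000, seed=4)
        f = (panel["s0"] == "G").mean()
        assert abs(f - 0.3) < 0.03

    def test_genotypes_from_panel_dosage(self):
        snps = self._snps(1)
        panel = simulate_haplotypes(snps, 100, seed=2)
        geno = genotypes_from_panel(panel, {"s0": "G"})
        manual = (panel["s0"] == "G").groupby(level="individual").sum()
        assert (geno.loc["s0"] == manual).all()


def _context(rng, length=80):
    from apasnp.synthetic_data import random_sequence
    seq = random_sequence(rng, length)
    off = length // 2
    ref = seq[off]
    alt = [b for b in "ACGT" if b != ref][0]
    alt_seq = seq[:off] + alt + seq[off + 1:]
    snp = SnpRecord("s", "c", off, ref, alt, {ref: 0.5, alt: 0.5})
    return seq, alt_seq, off, snp


class TestSimulateReads:
    def test_balanced_het_ratio_near_one(self, rng):
        ref_seq, alt_seq, off, snp = _context(rng)
        cfg = SimulationConfig(coverage=200, phred_error=0.0, ref_bias=1.0,
                               true_allelic_ratio=1.0)
        placements = simulate_reads(ref_seq, alt_seq, off, snp, 1, True,
                                    cfg, rng)
        bases = [p.sequence[off - p.start] for p in placements["ref"]]
        n_ref = sum(b == snp.ref_allele for b in bases)
        n_alt = sum(b == snp.alt_allele for b in bases)
        assert 1 / 1.3 < n_ref / n_alt < 1.3

    def test_homozygote_single_allele(self, rng):
        ref_seq, alt_seq, off, snp = _context(rng)
        cfg = SimulationConfig(coverage=50, phred_error=0.0, ref_bias=1.0)
        placements = simulate_reads(ref_seq, alt_seq, off, snp, 0, True,
                                    cfg, rng)
        bases = {p.sequence[off - p.start] for p in placements["ref"]}
        assert bases == {snp.ref_allele}

    def test_bias_depletes_mismatching_allele(self, rng):
        ref_seq, alt_seq, off, snp = _context(rng)
        cfg = SimulationConfig(coverage=400, phred_error=0.0, ref_bias=2.0,
                               true_allelic_ratio=1.0)
        placements = simulate_reads(ref_seq, alt_seq, off, snp, 1, True,
                                    cfg, rng)
        ref_bases = [p.sequence[off - p.start] for p in placements["ref"]]
        alt_bases = [p.sequence[off - p.start] for p in placements["alt"]]
        ratio_ref = sum(b == snp.ref_allele for b in ref_bases) / \
            sum(b == snp.alt_allele for b in ref_bases)
        ratio_alt = sum(b == snp.ref_allele for b in alt_bases) / \
            sum(b == snp.alt_allele for b in alt_bases)
        assert ratio_ref > 1.4        # ref-allele excess in the ref version
        assert ratio_alt < 1 / 1.4    # mirrored in the alt version

    def test_zero_coverage_rejected(self, rng):
        ref_seq, alt_seq, off, snp = _context(rng)
        cfg = SimulationConfig(coverage=10)
        cfg.coverage = 0
        with pytest.raises(ValueError):
            simulate_reads(ref_seq, alt_seq, off, snp, 1, True, cfg, rng)


class TestSimulateEsts:
    def test_full_usage_all_short(self):
        obs = simulate_ests("s", "A", "C", 500, 900, 100, usage_apa=1.0,
                            usage_non=0.0, seed=1)
        for o in obs:
            if o.called_alleles.get("s") == "A":
                assert abs(o.end_pos - 500) <= 10
            else:
                assert o.end_pos > 800

    def test_zero_usage_no_short(self):
        obs = simulate_ests("s", "A", "C", 500, 900, 100, usage_apa=0.0,
                            usage_non=0.0, seed=2)
        assert all(o.end_pos > 800 for o in obs)

    def test_partial_usage_fraction(self):
        obs = simulate_ests("s", "A", "C", 500, 900, 400, usage_apa=0.7,
                            usage_non=0.0, seed=3)
        apa = [o for o in obs if o.called_alleles.get("s") == "A"]
        short = sum(abs(o.end_pos - 500) <= 10 for o in apa)
        frac = short / len(apa)
        assert abs(frac - 0.7) < 3 * np.sqrt(0.7 * 0.3 / len(apa))


class TestSimulateExpression:
    def _geno(self):
        return pd.DataFrame([[0, 1, 2]], index=["s0"],
                            columns=["i0", "i1", "i2"])

    def test_no_effect_no_noise_constant(self):
        expr = simulate_expression(self._geno(), 0.0, noise_sd=0.0, seed=1)
        assert expr.iloc[0].nunique() == 1

    def test_effect_without_noise_exact(self):
        expr = simulate_expression(self._geno(), 1.0, noise_sd=0.0, seed=1)
        assert expr.iloc[0, 2] - expr.iloc[0, 0] == pytest.approx(2.0)

    def test_parameter_recovery(self, rng):
        n = 270
        dosage = rng.binomial(2, 0.4, size=(1, n))
        geno = pd.DataFrame(dosage, index=["s0"],
                            columns=[f"i{j}" for j in range(n)])
        expr = simulate_expression(geno, 0.5, noise_sd=0.5, seed=2)
        slope = np.polyfit(dosage[0], expr.iloc[0].to_numpy(), 1)[0]
        assert abs(slope - 0.5) < 0.15


class TestMirnaProfile:
    def test_proportions_and_determinism(self):
        t1 = simulate_mirna_profile(15, seed=8)
        t2 = simulate_mirna_profile(15, seed=8)
        assert t1.equals(t2)
        assert len(t1) == 15
        props = t1["expression"] / t1["expression"].sum()
        assert props.sum() == pytest.approx(1.0)

    def test_seed_column_matches_mature(self):
        t = simulate_mirna_profile(10, seed=3)
        for row in t.itertuples(index=False):
            assert row.seed7 == row.mature_seq[1:8]
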