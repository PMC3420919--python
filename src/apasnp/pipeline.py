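"""End-to-end orchestration over a bundle directory of pipeline inputs.

A bundle is a directory of plain-text inputs (genome.fasta, genes.bed,
snps.tsv, haplotypes.tsv, mirna.tsv, expression.tsv, gwas.tsv, ests.tsv,
placements.tsv, exons.tsv) as produced by :func:`generate_bundle`, or by
the user's own exports from real data in the same layout.  ``run_all``
executes the requested stages in dependency order, each stage writing one
TSV to the output directory with a provenance header (version, seed,
config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import synthetic_data as synth
from .assoc_stats import genotype_expression_scan
from .est_pipeline import EstObservation, run_est_stage
from .gu_content import annotate_candidates
from .gwas_linkage import aggregate, binomial_predicate_test, ld_map, PREDICATES
from .io_formats import (
    ReadPlacement,
    read_expression_table,
    read_fasta,
    read_gene_models_bed,
    read_gwas_table,
    read_haplotype_table,
    read_mirna_table,
    read_snp_table,
    write_fasta,
    write_gene_models_bed,
    write_snp_table,
    write_haplotype_table,
)
from .mirna_scoring import classify_mirna_score, prepare_profile_sum_by_seed, \
    score_candidate
from .rnaseq_allelics import call_genotype, consensus_genotype, count_alleles, \
    imbalance_scan
from .signal_scan import classify_strength, filter_candidates, scan_snps
from .transcript_end import assign_exons, estimate_end

ALL_STAGES = ("scan", "gu", "est", "genotype", "imbalance", "ends",
              "mirna-score", "assoc", "gwas-map")


@dataclass
class RunConfig:
    bundle_dir: str = "."
    out_dir: str = "results"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    strong_max_rank: int = 2
    gu_threshold: float = 0.55
    est_half_width: int = 30
    het_min_proportion: float = 0.15
    min_total_weight: float = 10.0
    ld_threshold: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {ALL_STAGES}")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded: the same
        analysis on the same inputs hashes identically wherever it runs)."""
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("bundle_dir", "out_dir")}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# apasnp {__version__} seed={config.seed} "
            f"config={config.config_hash()}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def _load_candidates(bundle: Path, config: RunConfig):
    chrom_seqs = read_fasta(bundle / "genome.fasta")
    genes = read_gene_models_bed(bundle / "genes.bed")
    snps = read_snp_table(bundle / "snps.tsv")
    changes, snp_gene, snp_off, utr_seqs = scan_snps(snps, genes, chrom_seqs)
    candidates = filter_candidates(
        changes, {s.snp_id: s for s in snps},
        {g.gene_id: g for g in genes}, snp_gene, utr_seqs, snp_off,
    )
    for c in candidates:
        c.strength_class = classify_strength(c.rank, config.strong_max_rank)
    annotate_candidates(candidates, utr_seqs, config.gu_threshold)
    return chrom_seqs, genes, snps, candidates, utr_seqs


def _candidates_frame(candidates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                snp_id=c.snp_id, gene_id=c.gene_id,
                change_kind=c.change.change_kind, hexamer=c.change.hexamer,
                rank=c.rank, apa_allele=c.apa_allele,
                strength=c.strength_class,
                utr_offset=c.utr_offset,
                distance_to_end=c.distance_to_annotated_end,
                local_gu=c.local_gu_level, gu_rich=c.gu_rich,
                global_gu=c.global_gu_level,
            )
            for c in candidates
        ]
    )


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run the requested stages; returns the map of stage -> output path."""
    bundle = Path(config.bundle_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    chrom_seqs, genes, snps, candidates, utr_seqs = _load_candidates(bundle, config)
    snp_map = {s.snp_id: s for s in snps}
    cand_df = _candidates_frame(candidates)

    if "scan" in config.stages:
        outputs["scan"] = out_dir / "candidates.tsv"
        _write_tsv(cand_df.drop(columns=["local_gu", "gu_rich", "global_gu"]),
                   outputs["scan"], config)
    if "gu" in config.stages:
        outputs["gu"] = out_dir / "gu.tsv"
        _write_tsv(cand_df, outputs["gu"], config)

    if "est" in config.stages:
        ests = pd.read_csv(bundle / "ests.tsv", sep="\t", comment="#")
        gene_obs: dict[str, list[EstObservation]] = {}
        for row in ests.itertuples(index=False):
            called = {} if pd.isna(row.allele) else {row.snp_id: row.allele}
            gene_obs.setdefault(row.gene_id, []).append(
                EstObservation(row.est_id, int(row.end_pos), called,
                               bool(row.imputed), bool(row.has_polya_tail))
            )
        by_gene = {c.gene_id: c for c in candidates}
        meta = ests.drop_duplicates("gene_id").set_index("gene_id")
        usable = [g for g in gene_obs if g in by_gene]
        est_df = run_est_stage(
            {g: gene_obs[g] for g in usable},
            {g: by_gene[g].snp_id for g in usable},
            {g: by_gene[g].apa_allele for g in usable},
            {g: int(meta.loc[g, "apa_site_pos"]) for g in usable},
            half_width=config.est_half_width,
        )
        outputs["est"] = out_dir / "est_results.tsv"
        _write_tsv(est_df, outputs["est"], config)

    per_het = []
    genotype_rows = []
    if "genotype" in config.stages or "imbalance" in config.stages:
        pl = pd.read_csv(bundle / "placements.tsv", sep="\t", comment="#")
        cand_by_id = {c.snp_id: c for c in candidates}
        for (snp_id, sample_id), grp in pl.groupby(["snp_id", "sample_id"]):
            if snp_id not in cand_by_id:
                continue
            snp = snp_map[snp_id]
            counts = {}
            for version in ("ref", "alt"):
                sub = grp[grp["version"] == version]
                placements = [
                    ReadPlacement(r.read_id, version, int(r.start),
                                  int(r.mismatches), r.sequence, r.qualities)
                    for r in sub.itertuples(index=False)
                ]
                counts[version] = count_alleles(
                    placements, snp, int(grp["snp_target_pos"].iloc[0]),
                    sample_id, version,
                )
            apa = cand_by_id[snp_id].apa_allele
            call_ref = call_genotype(counts["ref"], snp, config.het_min_proportion)
            call_alt = call_genotype(counts["alt"], snp, config.het_min_proportion)
            cons = consensus_genotype(call_ref, call_alt, snp, apa)
            genotype_rows.append(
                dict(snp_id=snp_id, sample_id=sample_id, call=cons.call,
                     dosage=cons.encoded)
            )
            if cons.call == "het":
                per_het.append((counts["ref"], counts["alt"], snp, apa))
    if "genotype" in config.stages:
        outputs["genotype"] = out_dir / "genotypes.tsv"
        _write_tsv(pd.DataFrame(genotype_rows), outputs["genotype"], config)
    if "imbalance" in config.stages:
        imb = imbalance_scan(per_het, config.min_total_weight)
        outputs["imbalance"] = out_dir / "imbalance.tsv"
        _write_tsv(imb, outputs["imbalance"], config)

    if "ends" in config.stages:
        exons = pd.read_csv(bundle / "exons.tsv", sep="\t", comment="#")
        rows = []
        for sample_id, grp in exons.groupby("sample_id"):
            triples = [(r.chrom, int(r.start), int(r.end))
                       for r in grp.itertuples(index=False)]
            assigned = assign_exons(triples, genes)
            for g in genes:
                est = estimate_end(g, assigned.get(g.gene_id, []), sample_id)
                if est is not None:
                    rows.append(
                        dict(gene_id=g.gene_id, sample_id=sample_id,
                             estimated_end=est.estimated_end, d=est.d,
                             response=est.response)
                    )
        outputs["ends"] = out_dir / "ends.tsv"
        _write_tsv(pd.DataFrame(rows), outputs["ends"], config)

    if "mirna-score" in config.stages:
        mirna = read_mirna_table(bundle / "mirna.tsv")
        profiles = prepare_profile_sum_by_seed(mirna)
        scores = [
            score_candidate(c.snp_id, utr_seqs[c.gene_id], c.utr_offset, profiles)
            for c in candidates
        ]
        diffs = np.array([s.score_diff for s in scores])
        classes = classify_mirna_score(diffs) if len(diffs) else np.array([])
        score_df = pd.DataFrame(
            [
                dict(snp_id=s.snp_id, score_short=s.score_short,
                     score_long=s.score_long, score_diff=s.score_diff,
                     mirna_class=cls)
                for s, cls in zip(scores, classes)
            ]
        )
        outputs["mirna-score"] = out_dir / "scores.tsv"
        _write_tsv(score_df, outputs["mirna-score"], config)

    if "assoc" in config.stages:
        expression = read_expression_table(bundle / "expression.tsv")
        panel = read_haplotype_table(bundle / "haplotypes.tsv")
        apa_alleles = {c.snp_id: c.apa_allele for c in candidates
                       if c.snp_id in panel.columns}
        genotypes = synth.genotypes_from_panel(panel, apa_alleles)
        genotypes = genotypes[[c for c in expression.columns
                               if c in genotypes.columns]]
        scan = genotype_expression_scan(
            genotypes, expression,
            {c.snp_id: c.gene_id for c in candidates},
        )
        outputs["assoc"] = out_dir / "assoc.tsv"
        _write_tsv(scan, outputs["assoc"], config)

    if "gwas-map" in config.stages:
        gwas = read_gwas_table(bundle / "gwas.tsv")
        panel = read_haplotype_table(bundle / "haplotypes.tsv")
        pairs = ld_map(
            [(c.snp_id, c.apa_allele) for c in candidates],
            gwas, panel, config.ld_threshold,
        )
        functional = set()
        if "assoc" in outputs:
            assoc_df = pd.read_csv(outputs["assoc"], sep="\t", comment="#")
            if len(assoc_df):
                functional = set(
                    assoc_df.loc[(assoc_df["q_bh"] < config.alpha)
                                 & (assoc_df["estimate"] > 0), "snp_id"]
                )
        aggs = aggregate(pairs, functional_ids=functional)
        pair_df = pd.DataFrame(
            [
                dict(apa_snp_id=p.apa_snp_id, gwas_snp_id=p.gwas_snp_id,
                     p_apa=p.p_apa, p_risk=p.p_risk, h=p.h, d=p.d, r=p.r,
                     population_class=p.population_class)
                for p in pairs
            ]
        )
        agg_df = pd.DataFrame(
            [
                dict(apa_snp_id=a.apa_snp_id, mean_r=a.mean_r,
                     mean_r2=a.mean_r2, n_pairs=a.n_pairs,
                     functional=a.is_candidate_functional)
                for a in aggs
            ]
        )
        binom_rows = []
        if any(a.is_candidate_functional for a in aggs):
            for name, pred in PREDICATES.items():
                res = binomial_predicate_test(aggs, pred)
                binom_rows.append(dict(predicate=name, **res))
        outputs["gwas-map"] = out_dir / "ld_pairs.tsv"
        _write_tsv(pair_df, outputs["gwas-map"], config)
        _write_tsv(agg_df, out_dir / "aggregates.tsv", config)
        _write_tsv(pd.DataFrame(binom_rows), out_dir / "binomial.tsv", config)

    return outputs


# ---------------------------------------------------------------------------
# bundle generation


def generate_bundle(
    outdir: str | Path,
    config: synth.SimulationConfig | None = None,
    n_functional: int = 10,
    n_decoys: int = 10,
    n_rnaseq_samples: int = 4,
    ests_per_gene: int = 40,
) -> Path:
    """Write a complete synthetic input bundle plus truth.tsv.

    Functional SNPs are planted with strong signals (rank <= 2), GU-rich
    downstream regions and an expression/imbalance effect; decoys get weak
    signals, GU-poor regions and no effect.  Every file is plain text in
    the layout ``run_all`` consumes.
    """
    config = config or synth.SimulationConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng("bundle")

    n_snps = n_functional + n_decoys
    cfg = synth.SimulationConfig(
        **{**asdict(config), "n_genes": max(config.n_genes, n_snps),
           "utr_length_range": (max(400, config.utr_length_range[0]),
                                max(2000, config.utr_length_range[1]))}
    )
    chrom_seqs, genes = synth.make_genome(cfg, rng)
    snps, truths = [], []
    for i in range(n_snps):
        functional = i < n_functional
        gene = genes[i]
        rank = int(rng.integers(1, 3)) if functional else int(rng.integers(3, 14))
        gu_class = "rich" if functional else "poor"
        snp, edited, truth = synth.plant_candidate_snp(
            chrom_seqs[gene.chrom], gene, rank, gu_class,
            distance_from_end=int(rng.integers(80, 200)),
            apa_allele_freq=0.5, rng=rng,
        )
        chrom_seqs[gene.chrom] = edited
        truth["is_functional_apa"] = functional
        snps.append(snp)
        truths.append(truth)

    write_fasta(chrom_seqs, outdir / "genome.fasta")
    write_gene_models_bed(genes, outdir / "genes.bed")
    write_snp_table(snps, outdir / "snps.tsv")

    panel = synth.simulate_haplotypes(snps, cfg.n_individuals,
                                      coupling=0.0, rng=rng)
    truth_by_id = {t["snp_id"]: t for t in truths}
    causal = [(s.snp_id, truth_by_id[s.snp_id]["apa_allele"])
              for s in snps[:n_functional]]
    panel, gwas = synth.simulate_gwas_catalog(
        panel, causal, [s.snp_id for s in snps[n_functional:]], rng=rng,
        coupling=0.9,
    )
    write_haplotype_table(panel, outdir / "haplotypes.tsv")
    gwas.to_csv(outdir / "gwas.tsv", sep="\t", index=False)

    apa_alleles = {s.snp_id: truth_by_id[s.snp_id]["apa_allele"] for s in snps}
    genotypes = synth.genotypes_from_panel(panel[ [s.snp_id for s in snps] ],
                                           apa_alleles)
    snp_gene = {t["snp_id"]: t["gene_id"] for t in truths}
    effects = pd.Series(
        {s.snp_id: (cfg.genotype_effect if truth_by_id[s.snp_id]["is_functional_apa"]
                    else 0.0) for s in snps}
    )
    expr_rows = {}
    for snp_id, dosage in genotypes.iterrows():
        mean = 8.0 + effects[snp_id] * dosage.to_numpy(dtype=float)
        expr_rows[snp_gene[snp_id]] = mean + rng.normal(
            0, cfg.noise_sd, len(dosage))
    expression = pd.DataFrame(expr_rows, index=genotypes.columns).T
    expression.index.name = "gene_id"
    expression.to_csv(outdir / "expression.tsv", sep="\t")

    mirna = synth.simulate_mirna_profile(cfg.mirna_n_seeds, rng=rng)
    mirna.to_csv(outdir / "mirna.tsv", sep="\t", index=False)

    # ESTs: usage driven by signal strength and GU class
    est_rows = []
    for t, snp in zip(truths, snps):
        usage = synth.default_usage_fn(t["signal_rank"], t["gu_class"] == "rich")
        gene = genes[[g.gene_id for g in genes].index(t["gene_id"])]
        site = t["utr_offset"] + t["signal_end_offset"] + 25
        non_apa = snp.ref_allele if t["apa_allele"] == snp.alt_allele \
            else snp.alt_allele
        obs = synth.simulate_ests(
            snp.snp_id, t["apa_allele"], non_apa, site, gene.utr3_length - 1,
            ests_per_gene, usage_apa=usage, usage_non=0.05, rng=rng,
        )
        for o in obs:
            est_rows.append(
                dict(est_id=o.est_id, gene_id=t["gene_id"], snp_id=snp.snp_id,
                     end_pos=o.end_pos,
                     allele=o.called_alleles.get(snp.snp_id, np.nan),
                     imputed=o.imputed, has_polya_tail=o.has_polya_tail,
                     apa_site_pos=site)
            )
    pd.DataFrame(est_rows).to_csv(outdir / "ests.tsv", sep="\t", index=False)

    # RNA-seq placements for the first samples
    place_rows = []
    sample_ids = list(genotypes.columns[:n_rnaseq_samples])
    for t, snp in zip(truths, snps):
        gene = genes[[g.gene_id for g in genes].index(t["gene_id"])]
        s, e = gene.utr3_intervals[0]
        target_ref = chrom_seqs[gene.chrom][s:e]
        target_alt = (target_ref[: snp.pos - s] + snp.alt_allele
                      + target_ref[snp.pos - s + 1:])
        rho = cfg.true_allelic_ratio if t["is_functional_apa"] else 1.0
        snp_cfg = synth.SimulationConfig(
            **{**asdict(cfg), "true_allelic_ratio": rho, "coverage": 50})
        for sample_id in sample_ids:
            dosage = int(genotypes.loc[snp.snp_id, sample_id])
            apa_is_alt = t["apa_allele"] == snp.alt_allele
            geno_alt = dosage if apa_is_alt else 2 - dosage
            placements = synth.simulate_reads(
                target_ref, target_alt, snp.pos - s, snp, geno_alt,
                apa_is_alt, snp_cfg, rng, sample_id,
            )
            for version, pls in placements.items():
                for p in pls:
                    place_rows.append(
                        dict(snp_id=snp.snp_id, sample_id=sample_id,
                             version=version, read_id=p.read_id,
                             start=p.start, mismatches=p.mismatches,
                             sequence=p.sequence, qualities=p.qualities,
                             snp_target_pos=snp.pos - s)
                    )
    pd.DataFrame(place_rows).to_csv(outdir / "placements.tsv", sep="\t",
                                    index=False)

    # expressed exons: functional APA homozygotes end near the planted site
    exon_rows = []
    for sample_id in sample_ids:
        for t, snp in zip(truths, snps):
            gene = genes[[g.gene_id for g in genes].index(t["gene_id"])]
            s, e = gene.utr3_intervals[0]
            dosage = int(genotypes.loc[snp.snp_id, sample_id])
            if t["is_functional_apa"] and dosage == 2:
                end = s + t["utr_offset"] + t["signal_end_offset"] + 25
            else:
                end = e - int(rng.integers(0, 30))
            exon_rows.append(dict(sample_id=sample_id, chrom=gene.chrom,
                                  start=s, end=end))
    pd.DataFrame(exon_rows).to_csv(outdir / "exons.tsv", sep="\t", index=False)

    pd.DataFrame(truths).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir
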