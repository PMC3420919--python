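"""Simulation-based calibration and recovery experiments.

Each function sets up a synthetic experiment with planted truth, runs the
relevant pipeline stage, and returns summary numbers (agreement rates,
sensitivity/FDR, CI coverage, ...).  They are the package's own evidence
that its statistics are calibrated and that planted effects are recovered
at the study's operating point; the test suite asserts on their outputs and
the reporting script re-runs them from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic_data as synth
from .assoc_stats import bootstrap_median_diff, correct_multiple, \
    genotype_expression_scan, regression_partial_r2
from .est_pipeline import apa_contingency_test
from .gwas_linkage import apa_risk_r, binomial_predicate_test
from .io_formats import GeneModel, SnpRecord
from .rnaseq_allelics import (
    AlleleCounts,
    call_genotype,
    consensus_genotype,
    corrected_allelic_imbalance,
    count_alleles,
    imbalance_scan,
    imbalance_test,
)
from .signal_scan import HEXAMER_RANK, classify_change, filter_candidates
from .synthetic_data import SimulationConfig, simulate_reads


# ---------------------------------------------------------------------------
# motif-scan agreement with brute force

def _brute_force_classify(ref_seq: str, alt_seq: str, snp_off: int) -> str:
    """Enumerate all hexamer placements overlapping the SNP on full sequences."""

    def covering_hexamers(seq: str) -> set[int]:
        out = set()
        for start in range(max(0, snp_off - 5), min(len(seq) - 5, snp_off + 1)):
            if seq[start:start + 6] in HEXAMER_RANK:
                out.add(start)
        return out

    ref_hits, alt_hits = covering_hexamers(ref_seq), covering_hexamers(alt_seq)
    if ref_hits and alt_hits:
        return "signal_to_signal"
    if alt_hits:
        return "created"
    if ref_hits:
        return "disrupted"
    return "none"


def _brute_force_keep(ref_seq: str, alt_seq: str, snp_off: int, maf: float) -> bool:
    kind = _brute_force_classify(ref_seq, alt_seq, snp_off)
    if kind not in ("created", "disrupted") or maf <= 0:
        return False
    signal_seq = alt_seq if kind == "created" else ref_seq
    other_seq = ref_seq if kind == "created" else alt_seq

    def locus_count(seq: str) -> int:
        lo, hi = max(0, snp_off - 20), min(len(seq), snp_off + 21)
        return sum(
            1 for i in range(lo, hi - 5) if seq[i:i + 6] in HEXAMER_RANK
        )

    return locus_count(signal_seq) == 1 and locus_count(other_seq) == 0


def motif_scan_agreement(n_contexts: int = 10_000, seed: int = 0) -> dict:
    """Agreement of the scanner and filter with brute-force enumeration.

    Random 61-nt A/T-heavy UTR contexts (hexamers arise often by chance)
    with a SNP at the centre; both the change classification and the
    keep/discard filter decision are compared.
    """
    rng = np.random.default_rng(seed)
    n_agree_kind = 0
    n_agree_filter = 0
    for _ in range(n_contexts):
        seq = synth.random_sequence(rng, 61, composition=(0.4, 0.1, 0.1, 0.4))
        off = 30
        ref = seq[off]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        alt_seq = seq[:off] + alt + seq[off + 1:]
        maf = float(rng.choice([0.0, 0.3]))

        win_lo = off - 6
        ref_win, alt_win = seq[win_lo:off + 7], alt_seq[win_lo:off + 7]
        change = classify_change("s", ref_win, alt_win, ref, alt, centre=6)
        if change.change_kind == _brute_force_classify(seq, alt_seq, off):
            n_agree_kind += 1

        snp = SnpRecord("s", "c", off, ref, alt, {ref: 1 - maf, alt: maf})
        gene = GeneModel("g", "c", "+", [(0, len(seq))], 0, [(0, len(seq))],
                         len(seq))
        kept = filter_candidates(
            [change], {"s": snp}, {"g": gene}, {"s": "g"}, {"g": seq},
            {"s": off},
        )
        if bool(kept) == _brute_force_keep(seq, alt_seq, off, maf):
            n_agree_filter += 1
    return dict(
        n=n_contexts,
        classify_agreement=n_agree_kind / n_contexts,
        filter_agreement=n_agree_filter / n_contexts,
    )


# ---------------------------------------------------------------------------
# bias cancellation

def _counts(snp: SnpRecord, version: str, a_w: float, b_w: float,
            apa: str) -> AlleleCounts:
    non = snp.alt_allele if apa == snp.ref_allele else snp.ref_allele
    return AlleleCounts("s", "x", version, weight={apa: a_w, non: b_w},
                        n_reads={apa: 1, non: 1})


def bias_cancellation_error(
    betas=(1.0, 1.25, 1.5, 2.0), rhos=(0.5, 1.0, 2.0, 4.0)
) -> dict:
    """Max |corrected AI - log2 rho| on noiseless biased counts.

    The APA allele is the non-reference allele, so the ref-version mapping
    retains APA reads with probability 1/beta and the alt-version retains
    non-APA reads with probability 1/beta; expectation-level counts are used
    directly.
    """
    snp = SnpRecord("s", "c", 0, "A", "G", {"A": 0.5, "G": 0.5})
    apa = "G"
    c = 100.0
    worst = 0.0
    for beta in betas:
        for rho in rhos:
            ref_counts = _counts(snp, "ref", rho * c / beta, c, apa)
            alt_counts = _counts(snp, "alt", rho * c, c / beta, apa)
            rec = corrected_allelic_imbalance(ref_counts, alt_counts, snp, apa)
            worst = max(worst, abs(rec.corrected_ai - np.log2(rho)))
    return dict(max_abs_error=worst, n=len(betas) * len(rhos))


# ---------------------------------------------------------------------------
# genotyping recovery

def _snp_context(rng, length: int = 80):
    """A random target pair differing at a central SNP."""
    seq = synth.random_sequence(rng, length)
    off = length // 2
    ref = seq[off]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    alt_seq = seq[:off] + alt + seq[off + 1:]
    snp = SnpRecord("s", "c", off, ref, alt, {ref: 0.5, alt: 0.5})
    return seq, alt_seq, off, snp


def genotyping_recovery(
    n_pairs: int = 1000,
    coverage: int = 20,
    phred_error: float = 0.01,
    ref_bias: float = 1.0,
    seed: int = 0,
) -> dict:
    """Consensus-genotype accuracy on simulated SNP/sample pairs.

    Reports overall accuracy among made calls and the false-heterozygote
    rate among truly homozygous pairs (the error mode the 0.15 proportion
    rule is designed to suppress).
    """
    rng = np.random.default_rng(seed)
    config = SimulationConfig(coverage=coverage, phred_error=phred_error,
                              ref_bias=ref_bias, true_allelic_ratio=1.0)
    n_correct = 0
    n_called = 0
    n_hom_truth = 0
    n_false_het = 0
    for i in range(n_pairs):
        ref_seq, alt_seq, off, snp = _snp_context(rng)
        truth = int(rng.integers(0, 3))
        placements = simulate_reads(ref_seq, alt_seq, off, snp, truth,
                                    apa_is_alt=True, config=config, rng=rng)
        calls = {}
        for version in ("ref", "alt"):
            counts = count_alleles(placements[version], snp, off, "x", version)
            calls[version] = call_genotype(counts, snp)
        cons = consensus_genotype(calls["ref"], calls["alt"], snp,
                                  apa_allele=snp.alt_allele)
        if truth in (0, 2):
            n_hom_truth += 1
            if cons.call == "het":
                n_false_het += 1
        if cons.call == "no_call":
            continue
        n_called += 1
        if cons.encoded == truth:
            n_correct += 1
    return dict(
        n=n_pairs,
        accuracy=n_correct / n_called if n_called else float("nan"),
        call_rate=n_called / n_pairs,
        false_het_rate=n_false_het / n_hom_truth if n_hom_truth else float("nan"),
    )


# ---------------------------------------------------------------------------
# end-to-end imbalance recovery

def imbalance_recovery(
    n_functional: int = 50,
    n_decoys: int = 200,
    replicates: int = 20,
    coverage: int = 100,
    rho: float = 2.0,
    ref_bias: float = 1.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Planted-imbalance recovery by the BH-corrected heterozygote scan.

    Functional SNPs carry a true APA:non-APA ratio of ``rho`` in a
    heterozygous sample; decoys are balanced (ratio 1).  A SNP is detected
    when its BH q-value passes ``alpha`` with positive corrected imbalance.
    Sensitivity and observed false-discovery proportion are averaged over
    replicates.
    """
    rng = np.random.default_rng(seed)
    config = SimulationConfig(coverage=coverage, phred_error=0.01,
                              ref_bias=ref_bias, true_allelic_ratio=rho)
    null_config = SimulationConfig(coverage=coverage, phred_error=0.01,
                                   ref_bias=ref_bias, true_allelic_ratio=1.0)
    sens, fdps = [], []
    for _ in range(replicates):
        per_het = []
        labels = []
        for j in range(n_functional + n_decoys):
            functional = j < n_functional
            ref_seq, alt_seq, off, snp = _snp_context(rng)
            cfg = config if functional else null_config
            placements = simulate_reads(ref_seq, alt_seq, off, snp, 1,
                                        apa_is_alt=True, config=cfg, rng=rng)
            counts = {
                v: count_alleles(placements[v], snp, off, "x", v)
                for v in ("ref", "alt")
            }
            snp.snp_id = f"s{j}"
            per_het.append((counts["ref"], counts["alt"], snp, snp.alt_allele))
            labels.append(functional)
        df = imbalance_scan(per_het)
        detected = (df["q_bh"] < alpha) & (df["corrected_ai"] > 0)
        truth = pd.Series(labels, index=df.index)
        n_det = int(detected.sum())
        tp = int((detected & truth).sum())
        sens.append(tp / n_functional)
        fdps.append((n_det - tp) / n_det if n_det else 0.0)
    return dict(
        replicates=replicates,
        sensitivity=float(np.mean(sens)),
        fdr=float(np.mean(fdps)),
    )


# ---------------------------------------------------------------------------
# closed-form statistic checks

def statistic_oracles() -> dict:
    """Pipeline statistics on hand-checkable inputs.

    * 1-df goodness-of-fit p for weighted counts (15, 5),
    * exact upper-tail binomial P(X >= 8 | n=9, p=0.5),
    * haplotype LD r for frequencies (0.4, 0.3) and joint frequency 0.2.
    """
    snp = SnpRecord("s", "c", 0, "A", "G", {"A": 0.5, "G": 0.5})
    ref_counts = _counts(snp, "ref", 15.0, 5.0, "G")
    alt_counts = _counts(snp, "alt", 15.0, 5.0, "G")
    rec = corrected_allelic_imbalance(ref_counts, alt_counts, snp, "G")
    rec = imbalance_test(rec, ref_counts, alt_counts, snp, "G")

    from .gwas_linkage import ApaSnpAggregate

    aggs = [ApaSnpAggregate(f"a{i}", 0.5, 0.25, 1, True) for i in range(8)]
    aggs.append(ApaSnpAggregate("a8", -0.5, 0.25, 1, True))
    binom = binomial_predicate_test(aggs, lambda a: a.mean_r > 0, p0=0.5)

    return dict(
        chi2_p_15_5=rec.p_value,
        binomial_p_8_of_9=binom["p_value"],
        ld_r_04_03_02=apa_risk_r(0.4, 0.3, 0.2),
    )


# ---------------------------------------------------------------------------
# bootstrap CI coverage

def bootstrap_coverage(
    n_datasets: int = 1000,
    n_per_group: int = 100,
    shift: float = 0.5,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Coverage of the 95% percentile bootstrap CI for a median difference.

    Groups are normal with a pure location shift, so the true median
    difference equals ``shift``.
    """
    rng = np.random.default_rng(seed)
    n_cover = 0
    for i in range(n_datasets):
        a = rng.normal(shift, 1.0, n_per_group)
        b = rng.normal(0.0, 1.0, n_per_group)
        ci = bootstrap_median_diff(a, b, n_boot=n_boot,
                                   seed=int(rng.integers(2 ** 31)))
        if ci.ci_low <= shift <= ci.ci_high:
            n_cover += 1
    return dict(n=n_datasets, coverage=n_cover / n_datasets)


# ---------------------------------------------------------------------------
# genotype-expression scan recovery

def expression_scan_recovery(
    n_planted: int = 50,
    n_null: int = 150,
    n_individuals: int = 270,
    effect: float = 0.5,
    noise_sd: float = 1.0,
    replicates: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of planted per-allele expression effects by the SNP scan.

    Also runs the strength/GU/miRNA multiple regression twice per
    replicate — once with a planted miRNA-loss contribution to the
    response, once without — and reports the mean incremental R-squared of
    the miRNA variable in each scenario.
    """
    rng = np.random.default_rng(seed)
    recovery, mirna_r2_planted, mirna_r2_null = [], [], []
    for _ in range(replicates):
        snp_ids = [f"s{i}" for i in range(n_planted + n_null)]
        dosage = rng.binomial(2, 0.3, size=(len(snp_ids), n_individuals))
        genotypes = pd.DataFrame(
            dosage, index=snp_ids,
            columns=[f"ind{j}" for j in range(n_individuals)],
        )
        effects = np.where(np.arange(len(snp_ids)) < n_planted, effect, 0.0)
        expr_vals = 8.0 + effects[:, None] * dosage \
            + rng.normal(0, noise_sd, size=dosage.shape)
        expression = pd.DataFrame(
            expr_vals, index=[f"gene_{s}" for s in snp_ids],
            columns=genotypes.columns,
        )
        scan = genotype_expression_scan(
            genotypes, expression, {s: f"gene_{s}" for s in snp_ids},
            apply_filter=False,
        )
        hits = scan[(scan["q_bh"] < alpha) & (scan["estimate"] > 0)]
        recovery.append(
            sum(h in set(snp_ids[:n_planted]) for h in hits["snp_id"]) / n_planted
        )

        n = n_individuals
        rank = rng.integers(1, 14, n).astype(float)
        gu = rng.uniform(0.3, 0.8, n)
        mirna = rng.exponential(1.0, n)
        noise = rng.normal(0, 1.0, n)
        y_base = -0.1 * rank + 2.0 * gu + noise
        for y, sink in ((y_base + 1.0 * mirna, mirna_r2_planted),
                        (y_base, mirna_r2_null)):
            report = regression_partial_r2(
                y, {"rank": rank, "gu": gu, "mirna": mirna}
            )
            sink.append(report.partial_r2["mirna"])
    return dict(
        replicates=replicates,
        recovery=float(np.mean(recovery)),
        mirna_partial_r2_planted=float(np.mean(mirna_r2_planted)),
        mirna_partial_r2_null=float(np.mean(mirna_r2_null)),
    )


# ---------------------------------------------------------------------------
# EST-stage calibration

def est_calibration(
    n_null: int = 500,
    n_power: int = 200,
    n_per_allele: int = 20,
    null_depth: int = 60,
    seed: int = 0,
) -> dict:
    """Null uniformity and power of the allele-by-length contingency test.

    Null: proximal-site usage is identical for both alleles, drawn
    uniformly in (0.3, 0.7) per replicate, with per-gene EST depth Poisson
    around ``null_depth`` per allele — the depth of a well-covered gene,
    and enough counts that the test's discrete p-value distribution is
    close to its continuous uniform target.  Power: the APA allele always
    ends proximally, the other allele never does, at ``n_per_allele`` ESTs
    per allele.
    """
    rng = np.random.default_rng(seed)
    null_ps = []
    for _ in range(n_null):
        u = rng.uniform(0.3, 0.7)
        n_apa = max(5, rng.poisson(null_depth))
        n_non = max(5, rng.poisson(null_depth))
        apa_short = rng.binomial(n_apa, u)
        non_short = rng.binomial(n_non, u)
        res = apa_contingency_test(
            apa_short, n_apa - apa_short,
            non_short, n_non - non_short,
        )
        if res is not None:
            null_ps.append(res.p_value)
    ks_p = float(stats.kstest(null_ps, "uniform").pvalue)
    n_sig = 0
    for _ in range(n_power):
        res = apa_contingency_test(n_per_allele, 0, 0, n_per_allele)
        if res is not None and res.p_value < 0.01:
            n_sig += 1
    return dict(
        n_null=len(null_ps),
        ks_p=ks_p,
        power=n_sig / n_power,
    )
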