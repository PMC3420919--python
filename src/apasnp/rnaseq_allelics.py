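"""RNA-seq allele counting, genotyping and bias-corrected allelic imbalance.

Reads are mapped (upstream of this package) to two versions of the 3'UTR
reference: one carrying reference alleles at candidate SNPs and one carrying
the non-reference alleles.  Each retained read contributes a weight of
(base-call accuracy at the SNP) x (mapping score) to its allele.  Alignment
to a reference favours reads matching the reference base — the familiar
reference-mapping bias — so the allelic ratio is computed in both reference
versions and averaged on the log scale; under a multiplicative retention
bias the two biases cancel exactly, leaving the true allelic ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_stats import correct_multiple
from .io_formats import GeneModel, ReadPlacement, SnpRecord, phred_accuracy

DEFAULT_MIN_ACCURACY = 0.9
DEFAULT_MAX_MISMATCHES = 10
HET_MIN_PROPORTION = 0.15
MIN_TOTAL_WEIGHT = 10.0


@dataclass
class AlleleCounts:
    snp_id: str
    sample_id: str
    reference_version: str                 # "ref" | "alt"
    weight: dict[str, float] = field(default_factory=dict)
    n_reads: dict[str, int] = field(default_factory=dict)

    def total(self) -> float:
        return sum(self.weight.values())


@dataclass
class GenotypeCall:
    snp_id: str
    sample_id: str
    call: str                              # hom_ref | hom_alt | het | no_call
    encoded: int | None = None             # APA-allele dosage 0/1/2


@dataclass
class ImbalanceRecord:
    snp_id: str
    sample_id: str
    log_ar_ref: float
    log_ar_alt: float
    corrected_ai: float
    total_weight: float
    chi2_stat: float | None = None
    p_value: float | None = None


def map_score(aligned_length: int, mismatches: int) -> float:
    """Fraction of matching bases in the alignment, in [0, 1]."""
    if aligned_length <= 0:
        raise ValueError("aligned_length must be positive")
    return max(0.0, (aligned_length - mismatches) / aligned_length)


def count_alleles(
    placements: list[ReadPlacement],
    snp: SnpRecord,
    snp_target_pos: int,
    sample_id: str,
    reference_version: str,
    min_accuracy: float = DEFAULT_MIN_ACCURACY,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> AlleleCounts:
    """Quality- and mapping-weighted allele evidence at one SNP.

    ``snp_target_pos`` is the SNP's coordinate on the mapping target.  Reads
    not overlapping the SNP, reads above the mismatch cap, base calls below
    the accuracy cut, and bases matching neither panel allele are all
    dropped; everything else adds accuracy x map_score to its allele weight.
    """
    counts = AlleleCounts(
        snp.snp_id, sample_id, reference_version,
        weight={a: 0.0 for a in snp.alleles},
        n_reads={a: 0 for a in snp.alleles},
    )
    for pl in placements:
        if not (pl.start <= snp_target_pos < pl.end):
            continue
        if pl.mismatches > max_mismatches:
            continue
        offset = snp_target_pos - pl.start
        base = pl.sequence[offset]
        if base not in snp.alleles:
            continue
        acc = phred_accuracy(pl.qualities[offset])
        if acc < min_accuracy:
            continue
        counts.weight[base] += acc * map_score(len(pl.sequence), pl.mismatches)
        counts.n_reads[base] += 1
    return counts


def call_genotype(counts: AlleleCounts, snp: SnpRecord,
                  het_min_prop: float = HET_MIN_PROPORTION) -> GenotypeCall:
    """Heterozygous iff both allele weight proportions exceed the cutoff.

    With evidence for only one allele, or with one proportion at or below
    the cutoff, the call is homozygous for the majority allele.
    """
    total = counts.total()
    if total <= 0:
        return GenotypeCall(counts.snp_id, counts.sample_id, "no_call")
    props = {a: w / total for a, w in counts.weight.items()}
    ref, alt = snp.alleles
    if props[ref] > het_min_prop and props[alt] > het_min_prop:
        return GenotypeCall(counts.snp_id, counts.sample_id, "het")
    major = ref if props[ref] >= props[alt] else alt
    call = "hom_ref" if major == ref else "hom_alt"
    return GenotypeCall(counts.snp_id, counts.sample_id, call)


def consensus_genotype(call_ref: GenotypeCall, call_alt: GenotypeCall,
                       snp: SnpRecord, apa_allele: str) -> GenotypeCall:
    """Genotype agreed by both reference versions; disagreement -> no_call.

    The dosage encoding counts APA-allele copies: non-APA homozygote 0,
    heterozygote 1, APA homozygote 2.
    """
    if call_ref.call == call_alt.call and call_ref.call != "no_call":
        call = call_ref.call
    else:
        call = "no_call"
    encoded = None
    if call == "het":
        encoded = 1
    elif call in ("hom_ref", "hom_alt"):
        hom_allele = snp.ref_allele if call == "hom_ref" else snp.alt_allele
        encoded = 2 if hom_allele == apa_allele else 0
    return GenotypeCall(call_ref.snp_id, call_ref.sample_id, call, encoded)


def corrected_allelic_imbalance(
    counts_ref: AlleleCounts, counts_alt: AlleleCounts, snp: SnpRecord,
    apa_allele: str,
) -> ImbalanceRecord | None:
    """Mean of the log2 allelic ratios from the two reference versions.

    AI = ((log2(a_ref / b_ref) + log2(a_alt / b_alt)) / 2 where a are
    APA-allele weights and b non-APA weights.  A zero weight anywhere makes
    the record undefined (None).
    """
    non_apa = snp.alt_allele if apa_allele == snp.ref_allele else snp.ref_allele
    a_ref, b_ref = counts_ref.weight[apa_allele], counts_ref.weight[non_apa]
    a_alt, b_alt = counts_alt.weight[apa_allele], counts_alt.weight[non_apa]
    if min(a_ref, b_ref, a_alt, b_alt) <= 0:
        return None
    log_ar_ref = float(np.log2(a_ref / b_ref))
    log_ar_alt = float(np.log2(a_alt / b_alt))
    total = (a_ref + b_ref + a_alt + b_alt) / 2.0
    return ImbalanceRecord(
        snp_id=snp.snp_id,
        sample_id=counts_ref.sample_id,
        log_ar_ref=log_ar_ref,
        log_ar_alt=log_ar_alt,
        corrected_ai=(log_ar_ref + log_ar_alt) / 2.0,
        total_weight=total,
    )


def imbalance_test(record: ImbalanceRecord, counts_ref: AlleleCounts,
                   counts_alt: AlleleCounts, snp: SnpRecord, apa_allele: str,
                   min_total: float = MIN_TOTAL_WEIGHT) -> ImbalanceRecord:
    """1-df chi-square goodness of fit against equal allele proportions.

    Computed on the version-averaged weighted counts (the package's counting
    unit is the weight, so no rounding is applied); heterozygotes with fewer
    than ``min_total`` total counts are skipped (stat and p left missing).
    """
    non_apa = snp.alt_allele if apa_allele == snp.ref_allele else snp.ref_allele
    a = (counts_ref.weight[apa_allele] + counts_alt.weight[apa_allele]) / 2.0
    b = (counts_ref.weight[non_apa] + counts_alt.weight[non_apa]) / 2.0
    if a + b < min_total:
        return record
    m = (a + b) / 2.0
    chi2 = (a - m) ** 2 / m + (b - m) ** 2 / m
    record.chi2_stat = float(chi2)
    record.p_value = float(stats.chi2.sf(chi2, df=1))
    return record


def imbalance_scan(
    per_het: list[tuple[AlleleCounts, AlleleCounts, SnpRecord, str]],
    min_total: float = MIN_TOTAL_WEIGHT,
) -> pd.DataFrame:
    """Test every heterozygote and attach BH and Bonferroni q-values.

    ``per_het`` holds (ref-version counts, alt-version counts, snp,
    apa_allele) per heterozygous SNP/sample.  Records with undefined AI or
    below the count floor appear with missing p.
    """
    rows = []
    for counts_ref, counts_alt, snp, apa in per_het:
        rec = corrected_allelic_imbalance(counts_ref, counts_alt, snp, apa)
        if rec is None:
            continue
        rec = imbalance_test(rec, counts_ref, counts_alt, snp, apa, min_total)
        rows.append(
            dict(
                snp_id=rec.snp_id, sample_id=rec.sample_id,
                log_ar_ref=rec.log_ar_ref, log_ar_alt=rec.log_ar_alt,
                corrected_ai=rec.corrected_ai, total_weight=rec.total_weight,
                chi2=rec.chi2_stat, p=rec.p_value,
            )
        )
    df = pd.DataFrame(rows)
    if len(df):
        tested = df["p"].notna().to_numpy()
        for name, method in (("q_bh", "bh"), ("q_bonf", "bonferroni")):
            q = np.full(len(df), np.nan)
            if tested.any():
                q[tested] = correct_multiple(df.loc[tested, "p"].to_numpy(), method)
            df[name] = q
    return df


def build_allele_references(
    genes: list[GeneModel],
    chrom_seqs: dict[str, str],
    snps: list[SnpRecord],
    extension: int = 50,
) -> tuple[dict[str, str], dict[str, str], dict[str, tuple[str, int]]]:
    """Dual mapping references over extended, merged 3'UTR regions.

    Each gene's 3'UTR span (introns included) is extended ``extension`` nt
    both ways on its chromosome; overlapping regions are merged.  The second
    set is identical except that candidate-SNP reference alleles are
    replaced by the non-reference alleles.  Returns (ref set, alt set,
    snp -> (region name, offset within region)).
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        ivals = sorted(g.utr3_intervals)
        start = max(0, ivals[0][0] - extension)
        end = min(len(chrom_seqs[g.chrom]), ivals[-1][1] + extension)
        spans.setdefault(g.chrom, []).append((start, end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivals in spans.items():
        ivals.sort()
        out = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]

    ref_set: dict[str, str] = {}
    alt_set: dict[str, str] = {}
    snp_region: dict[str, tuple[str, int]] = {}
    for chrom, ivals in merged.items():
        for s, e in ivals:
            name = f"{chrom}:{s}-{e}"
            seq = chrom_seqs[chrom][s:e]
            alt_seq = list(seq)
            for snp in snps:
                if snp.chrom == chrom and s <= snp.pos < e:
                    off = snp.pos - s
                    if seq[off] != snp.ref_allele:
                        raise ValueError(
                            f"{snp.snp_id}: reference base {seq[off]} != {snp.ref_allele}"
                        )
                    alt_seq[off] = snp.alt_allele
                    snp_region[snp.snp_id] = (name, off)
            ref_set[name] = seq
            alt_set[name] = "".join(alt_seq)
    unplaced = [s.snp_id for s in snps if s.snp_id not in snp_region]
    if unplaced:
        raise ValueError(f"SNPs outside every reference region: {unplaced}")
    return ref_set, alt_set, snp_region
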