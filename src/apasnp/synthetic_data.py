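"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators embody the causal model the pipeline is built to detect: an
APA allele completes a polyA-signal hexamer, supports a proximal cleavage
site (the more so the stronger the signal and the richer the downstream GU
element), shortens the 3'UTR, loses miRNA target sites, and raises the
expression of transcripts carrying it.  Every generator is a pure function
of its arguments and a seed, and each planted SNP is recorded in a truth
table so recovery can be scored.

Planted candidate loci are built on a C/G-only filler: none of the 13
signal hexamers can occur inside, or straddle the edge of, a C/G stretch,
which guarantees the planted hexamer is the locus's only signal placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .est_pipeline import EstObservation
from .io_formats import FastqRead, GeneModel, ReadPlacement, SnpRecord, \
    accuracy_to_phred_char, reverse_complement
from .signal_scan import SIGNAL_HEXAMERS, hexamer_hits

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the data the pipeline targets: short-read RNA-seq
    (36 nt, ~1% base error), a modest reference-mapping bias, a two-fold
    abundance advantage for the APA-allele transcript at functional sites,
    and a HapMap-sized panel of diploid individuals.
    """

    seed: int = 0
    n_genes: int = 50
    utr_length_range: tuple[int, int] = (300, 2000)
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    n_individuals: int = 60
    coverage: int = 100               # read depth per chromosome copy at the SNP
    read_length: int = 36
    phred_error: float = 0.01
    ref_bias: float = 1.5
    true_allelic_ratio: float = 2.0
    genotype_effect: float = 0.5
    noise_sd: float = 1.0
    mirna_n_seeds: int = 20
    ld_decay: float = 0.9            # copula coupling between adjacent SNPs
    polya_tail_len: int = 12

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if self.true_allelic_ratio <= 0:
            raise ValueError("true_allelic_ratio must be positive")
        if not (0 <= self.phred_error < 1):
            raise ValueError("phred_error must be in [0, 1)")
        if self.ref_bias < 1:
            raise ValueError("ref_bias must be >= 1")

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-local generator derived from the master seed."""
        import zlib

        ss = np.random.SeedSequence(
            [self.seed, zlib.crc32(stage.encode()) % (2 ** 31)]
        )
        return np.random.default_rng(ss)


def random_sequence(rng: np.random.Generator, length: int,
                    composition=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(BASES, size=length, p=np.asarray(composition)))


# ---------------------------------------------------------------------------
# genome and planted candidate SNPs

UPSTREAM_PAD = 60     # genomic padding either side of the UTR
DOWNSTREAM_PAD = 60


def make_genome(config: SimulationConfig,
                rng: np.random.Generator | None = None
                ) -> tuple[dict[str, str], list[GeneModel]]:
    """One plus-strand gene per synthetic chromosome.

    Each chromosome is upstream pad + 3'UTR + downstream pad; the UTR length
    is uniform in ``utr_length_range`` and its composition follows
    ``base_composition``.
    """
    rng = rng if rng is not None else config.rng("genome")
    lo, hi = config.utr_length_range
    if lo > hi or lo < 13:
        raise ValueError("infeasible UTR length range")
    chrom_seqs: dict[str, str] = {}
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        gid = f"g{i:04d}"
        utr_len = int(rng.integers(lo, hi + 1))
        seq = random_sequence(
            rng, UPSTREAM_PAD + utr_len + DOWNSTREAM_PAD, config.base_composition
        )
        chrom = f"chr_{gid}"
        chrom_seqs[chrom] = seq
        utr = (UPSTREAM_PAD, UPSTREAM_PAD + utr_len)
        genes.append(
            GeneModel(
                gene_id=gid, chrom=chrom, strand="+",
                transcript_intervals=[utr], cds_end=utr[0],
                utr3_intervals=[utr], annotated_end=utr[1],
            )
        )
    return chrom_seqs, genes


def _cg_filler(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(["C", "G"], size=length))


GU_RICH_PROB = 0.80      # per-base G/T probability planted downstream
GU_POOR_PROB = 0.30


def plant_candidate_snp(
    chrom_seq: str,
    gene: GeneModel,
    signal_rank: int,
    gu_class: str,
    distance_from_end: int,
    apa_allele_freq: float,
    rng: np.random.Generator,
    kind: str = "created",
    snp_id: str | None = None,
) -> tuple[SnpRecord, str, dict]:
    """Edit a gene's 3'UTR so one allele completes a chosen signal hexamer.

    The SNP lands ``distance_from_end`` nt upstream of the annotated end.
    The 41-nt locus around it is rewritten on C/G filler, the hexamer of
    ``signal_rank`` is placed over the SNP, and the non-signal allele is a C
    or G that leaves the locus signal-free.  The 25 nt spanning downstream
    offsets 25-49 after the signal end are resampled to match ``gu_class``
    (G/T fraction strictly above 0.55 for "rich", below for "poor").  Only
    plus-strand genes are edited here (the scanner itself is strand-aware).

    Returns the SNP record, the edited chromosome, and a truth dict.
    """
    if gene.strand != "+":
        raise ValueError("planting is implemented on plus-strand genes")
    if kind not in ("created", "disrupted"):
        raise ValueError(f"unknown change kind {kind!r}")
    utr_start, utr_end = gene.utr3_intervals[0]
    utr_len = utr_end - utr_start
    off = utr_len - 1 - distance_from_end          # spliced-UTR offset
    hexamer = SIGNAL_HEXAMERS[signal_rank - 1]

    utr0 = list(chrom_seq[utr_start:utr_end])
    # signal-free bed for the 41-nt locus
    lo, hi = off - 20, off + 21
    if lo - 6 < 0 or off + 55 >= utr_len:
        raise ValueError(
            "locus does not fit: need >= 26 nt upstream and >= 55 nt "
            "downstream of the SNP inside the UTR"
        )
    utr0[lo:hi] = list(_cg_filler(rng, hi - lo))
    if hexamer_hits("".join(utr0[lo - 5:min(utr_len, hi + 5)])):
        # an existing signal straddles the locus edge: caller must pick
        # another position
        raise ValueError("cannot clear the locus without clashing with an "
                         "existing signal")
    # pick a SNP position inside the hexamer and a broken base such that the
    # non-signal allele's locus holds no signal at all (e.g. ATTAAA -> ACTAAA
    # would re-create a signal and must be avoided)
    for snp_in_hex in rng.permutation(6):
        snp_in_hex = int(snp_in_hex)
        hex_start = off - snp_in_hex
        trial = list(utr0)
        trial[hex_start:hex_start + 6] = list(hexamer)
        signal_base = hexamer[snp_in_hex]
        choice = None
        for broken in ("C", "G"):
            if broken == signal_base:
                continue
            trial[off] = broken
            if not hexamer_hits("".join(trial[lo:hi])):
                choice = broken
                break
        if choice is not None:
            break
    else:
        raise ValueError("no SNP placement breaks the signal cleanly")
    utr = list(utr0)
    utr[hex_start:hex_start + 6] = list(hexamer)
    broken_base = choice
    gu_lo = hex_start + 5 + 25
    gu_hi = hex_start + 5 + 49
    # GU class region: downstream offsets 25..49 after the signal end
    gu_p = GU_RICH_PROB if gu_class == "rich" else GU_POOR_PROB
    for _ in range(100):
        region = [
            ("G" if rng.random() < gu_p / 2 else "T") if rng.random() < gu_p
            else ("A" if rng.random() < 0.5 else "C")
            for _ in range(gu_hi - gu_lo + 1)
        ]
        frac = sum(1 for b in region if b in "GT") / len(region)
        if (gu_class == "rich") == (frac > 0.55) and frac != 0.55:
            break
    else:
        raise ValueError("could not realise the requested GU class")
    utr[gu_lo:gu_hi + 1] = region

    if kind == "created":
        ref_base, alt_base = broken_base, signal_base
    else:
        ref_base, alt_base = signal_base, broken_base
    utr[off] = ref_base
    edited = chrom_seq[:utr_start] + "".join(utr) + chrom_seq[utr_end:]
    pos = utr_start + off
    snp_id = snp_id or f"snp_{gene.gene_id}"
    snp = SnpRecord(
        snp_id=snp_id, chrom=gene.chrom, pos=pos,
        ref_allele=ref_base, alt_allele=alt_base,
        allele_freqs={
            alt_base: apa_allele_freq if kind == "created" else 1 - apa_allele_freq,
            ref_base: 1 - apa_allele_freq if kind == "created" else apa_allele_freq,
        },
    )
    truth = dict(
        snp_id=snp_id, gene_id=gene.gene_id, kind=kind, hexamer=hexamer,
        signal_rank=signal_rank, gu_class=gu_class, utr_offset=off,
        apa_allele=signal_base, signal_end_offset=5 - snp_in_hex,
        realized_gu=frac,
    )
    return snp, edited, truth


# ---------------------------------------------------------------------------
# haplotypes

def simulate_haplotypes(
    snps: list[SnpRecord],
    n_individuals: int,
    coupling: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Phased panel of 2 x n haplotypes with tunable adjacent-SNP LD.

    A Gaussian-free copula scheme: each haplotype carries one latent uniform
    per SNP, copied from the previous SNP's uniform with probability
    ``coupling`` and redrawn otherwise; the allele is alt iff the uniform
    falls below the alt-allele frequency.  With equal allele frequencies the
    expected pairwise r between adjacent SNPs equals ``coupling``;
    ``coupling=1`` gives perfectly coupled haplotypes.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    cols: dict[str, np.ndarray] = {}
    u = rng.random(n_hap)
    for i, snp in enumerate(snps):
        if i > 0:
            redraw = rng.random(n_hap) >= coupling
            u = np.where(redraw, rng.random(n_hap), u)
        f_alt = snp.allele_freqs[snp.alt_allele]
        alleles = np.where(u < f_alt, snp.alt_allele, snp.ref_allele)
        cols[snp.snp_id] = alleles
    index = pd.MultiIndex.from_tuples(
        [(f"ind{i:03d}", ph) for i in range(n_individuals) for ph in (0, 1)],
        names=["individual", "phase"],
    )
    return pd.DataFrame(cols, index=index)


def genotypes_from_panel(panel: pd.DataFrame, snp_allele: dict[str, str]
                         ) -> pd.DataFrame:
    """Per-individual dosage (0/1/2) of a designated allele per SNP."""
    rows = {}
    for snp_id, allele in snp_allele.items():
        ind = (panel[snp_id] == allele).astype(int)
        rows[snp_id] = ind.groupby(level="individual").sum()
    return pd.DataFrame(rows).T      # rows = SNPs, columns = individuals


# ---------------------------------------------------------------------------
# RNA-seq reads

def _error_chars(rng, n):
    return rng.integers(0, 4, size=n)


def simulate_reads(
    target_ref: str,
    target_alt: str,
    snp_target_pos: int,
    snp: SnpRecord,
    genotype: int,
    apa_is_alt: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "s0",
) -> dict[str, list[ReadPlacement]]:
    """Reads over one SNP, placed against both reference versions.

    ``genotype`` counts alt-allele copies (0/1/2).  For heterozygotes the
    chance a read carries the APA allele is rho / (1 + rho) with
    rho = ``true_allelic_ratio``, matching an APA:non-APA transcript
    abundance of rho.  Base miscalls occur at ``phred_error`` per base with
    Phred strings to match.  Mapping bias: a read whose (observed) base at
    the SNP mismatches the version's allele is retained with probability
    1 / ref_bias, the simplest retention mechanism a version-averaged log
    ratio provably cancels.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    L = config.read_length
    # coverage is per chromosome copy: a diploid locus accrues reads from
    # both homologues
    n = 2 * config.coverage
    if genotype == 1:
        rho = config.true_allelic_ratio
        p_apa = rho / (1.0 + rho)
        p_alt = p_apa if apa_is_alt else 1.0 - p_apa
    else:
        p_alt = 1.0 if genotype == 2 else 0.0
    is_alt = rng.random(n) < p_alt
    lo = max(0, snp_target_pos - L + 1)
    hi = min(snp_target_pos, len(target_ref) - L)
    starts = rng.integers(lo, hi + 1, size=n)
    q_char = accuracy_to_phred_char(1.0 - config.phred_error) \
        if config.phred_error > 0 else accuracy_to_phred_char(1.0)
    out: dict[str, list[ReadPlacement]] = {"ref": [], "alt": []}
    keep_prob = 1.0 / config.ref_bias
    for i in range(n):
        src = target_alt if is_alt[i] else target_ref
        start = int(starts[i])
        bases = list(src[start:start + L])
        err = rng.random(L) < config.phred_error
        for j in np.nonzero(err)[0]:
            bases[j] = BASES[(np.searchsorted(BASES, bases[j]) +
                              1 + int(rng.integers(0, 3))) % 4]
        seq = "".join(bases)
        quals = q_char * L
        for version, target in (("ref", target_ref), ("alt", target_alt)):
            mismatches = sum(
                1 for a, b in zip(seq, target[start:start + L]) if a != b
            )
            obs_base = seq[snp_target_pos - start]
            version_allele = snp.ref_allele if version == "ref" else snp.alt_allele
            if obs_base != version_allele and rng.random() >= keep_prob:
                continue
            out[version].append(
                ReadPlacement(
                    read_id=f"{sample_id}_{snp.snp_id}_r{i}",
                    target=version,
                    start=start,
                    mismatches=mismatches,
                    sequence=seq,
                    qualities=quals,
                )
            )
    return out


def reads_to_fastq(placements: list[ReadPlacement]) -> list[FastqRead]:
    return [FastqRead(p.read_id, p.sequence, p.qualities) for p in placements]


# ---------------------------------------------------------------------------
# ESTs

def default_usage_fn(signal_rank: int, gu_rich: bool) -> float:
    """Proximal-site usage of the APA allele: strong signal + GU-rich -> high."""
    base = 0.9 if signal_rank <= 2 else 0.4
    return base if gu_rich else base * 0.4


def simulate_ests(
    snp_id: str,
    apa_allele: str,
    non_apa_allele: str,
    apa_site_pos: int,
    distal_end_pos: int,
    n_ests: int,
    usage_apa: float,
    usage_non: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    apa_allele_freq: float = 0.5,
    end_jitter: int = 10,
    call_prob: float = 1.0,
    tail_len: int = 12,
) -> list[EstObservation]:
    """ESTs whose 3' ends depend on allele and proximal-site usage.

    Each EST draws an allele; APA-allele ESTs end at the proximal site
    (within ``end_jitter`` nt) with probability ``usage_apa`` and at the
    distal end otherwise; non-APA ESTs use ``usage_non``.  Cleaved ESTs are
    flagged as carrying a polyA tail of ``tail_len`` A's.  With
    ``call_prob < 1`` some alleles are left uncalled, to exercise
    imputation.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = []
    for i in range(n_ests):
        is_apa = rng.random() < apa_allele_freq
        allele = apa_allele if is_apa else non_apa_allele
        usage = usage_apa if is_apa else usage_non
        proximal = rng.random() < usage
        jitter = int(rng.integers(-end_jitter, end_jitter + 1))
        end = apa_site_pos + jitter if proximal else distal_end_pos - abs(jitter)
        called = {snp_id: allele} if rng.random() < call_prob else {}
        out.append(
            EstObservation(
                est_id=f"est_{snp_id}_{i}",
                end_pos=end,
                called_alleles=called,
                imputed=False,
                has_polya_tail=proximal and tail_len >= 8,
            )
        )
    return out


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    genotypes: pd.DataFrame,
    genotype_effect: float,
    gene_gu: dict[str, float] | None = None,
    snp_gene: dict[str, str] | None = None,
    gu_confounder_slope: float = 0.0,
    noise_sd: float = 1.0,
    baseline: float = 8.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression matrix with E[expr] = baseline + effect x dosage + slope x GU.

    Rows follow the SNP->gene map (one gene per SNP); columns are the
    individuals of the genotype matrix.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    snp_gene = snp_gene or {s: f"gene_of_{s}" for s in genotypes.index}
    rows = {}
    for snp_id, dosage in genotypes.iterrows():
        gene = snp_gene[snp_id]
        gu = (gene_gu or {}).get(gene, 0.0)
        mean = baseline + genotype_effect * dosage.to_numpy(dtype=float) \
            + gu_confounder_slope * gu
        rows[gene] = mean + (rng.normal(0, noise_sd, size=len(dosage))
                             if noise_sd > 0 else 0.0)
    return pd.DataFrame(rows, index=genotypes.columns).T


# ---------------------------------------------------------------------------
# miRNA profiles and planted target sites

def simulate_mirna_profile(
    n_seeds: int,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mature miRNA table with exponential expression across random seeds."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    seen: set[str] = set()
    while len(seen) < n_seeds:
        mature = random_sequence(rng, 21)
        s7 = mature[1:8]
        if s7 in seen:
            continue
        seen.add(s7)
        rows.append(
            dict(
                mature_id=f"mir{len(seen):03d}",
                seed7=s7,
                mature_seq=mature,
                expression=float(rng.exponential(1.0)),
            )
        )
    return pd.DataFrame(rows)


def plant_seed_sites(seq: str, seed7: str, offsets: list[int]) -> str:
    """Write 8mer target sites (revcomp of the seed + A) at given offsets."""
    site = reverse_complement(seed7) + "A"
    out = list(seq)
    for off in offsets:
        if off + len(site) > len(seq):
            raise ValueError("site does not fit at the requested offset")
        out[off:off + len(site)] = list(site)
    return "".join(out)


# ---------------------------------------------------------------------------
# GWAS catalog

def simulate_gwas_catalog(
    panel: pd.DataFrame,
    causal: list[tuple[str, str]],
    decoys: list[str],
    rng: np.random.Generator | None = None,
    seed: int = 0,
    coupling: float = 1.0,
    population_class: str = "CEU",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partner GWAS SNPs whose risk allele rides on the APA haplotype.

    For each causal (apa_snp, apa_allele) a partner column is appended to
    the panel: with probability ``coupling`` a haplotype's partner allele
    mirrors its APA-allele indicator (risk allele iff APA allele), otherwise
    it is drawn at random.  Decoy APA-SNPs get partners in the same LD but
    with the risk allele tied to a randomly chosen allele of the SNP, so the
    sign of the APA-allele/risk-allele correlation is random.
    Returns (augmented panel, GWAS catalog table).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    panel = panel.copy()
    rows = []
    for i, (apa_id, apa_allele) in enumerate(causal):
        partner = f"gwas_{apa_id}"
        ind = (panel[apa_id] == apa_allele).to_numpy()
        mirror = rng.random(len(panel)) < coupling
        random_alleles = rng.random(len(panel)) < ind.mean()
        carries = np.where(mirror, ind, random_alleles)
        panel[partner] = np.where(carries, "T", "A")
        rows.append(dict(snp_id=partner, risk_allele="T",
                         population_class=population_class,
                         trait=f"trait{i}"))
    for i, apa_id in enumerate(decoys):
        partner = f"gwas_{apa_id}"
        alleles = sorted(set(panel[apa_id]))
        chosen = str(rng.choice(alleles))        # random sign w.r.t. APA allele
        ind = (panel[apa_id] == chosen).to_numpy()
        mirror = rng.random(len(panel)) < coupling
        random_alleles = rng.random(len(panel)) < ind.mean()
        carries = np.where(mirror, ind, random_alleles)
        panel[partner] = np.where(carries, "T", "A")
        rows.append(dict(snp_id=partner, risk_allele="T",
                         population_class=population_class,
                         trait=f"decoy_trait{i}"))
    return panel, pd.DataFrame(rows)
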