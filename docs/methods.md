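# Methods

This note documents the models, conventions and numerical choices behind
`apasnp`, in the order the pipeline runs.

## Coordinates, alphabets, qualities

All intervals are 0-based half-open; BED is native, GTF-style inputs are
converted on read. Sequences are folded to uppercase DNA with U→T, so the
thirteen polyA-signal hexamers are stored and matched as DNA (AATAAA, …)
against genomic FASTA. Minus-strand genes are analysed on the
reverse-complemented spliced sequence; alleles supplied in genomic-strand
coordinates are complemented into transcript orientation before scanning.
FASTQ qualities are Sanger Phred+33; a base with quality character *c*
carries accuracy 1 − 10^(−(c−33)/10).

## Signal scan

The scan window is the SNP plus 6 nt of flank on each side (13 nt) on the
spliced 3'UTR. All eight hexamer placements covering the SNP are tested on
both alleles; placements not covering the SNP are identical in both
alleles and carry no allelic information. A SNP is *created* if only the
alternate allele yields a hit, *disrupted* if only the reference does,
*signal-to-signal* if both do (at any offsets); the strongest (lowest
rank) hexamer is reported when one allele hits several. Candidate filters:
the signal-bearing allele's 41-nt locus (SNP ± 20 nt, symmetric reading of
"around") must contain exactly one signal placement and the other
allele's locus none — i.e. the locus goes from no signal to one signal —
and the SNP must be polymorphic. Counting on **both** alleles is the
stricter of the two possible readings and is what the brute-force oracle
in the acceptance checks implements too.

Signal strength ranks follow the canonical ordered hexamer list; the
frequency column of the built-in table is a literature-typical occurrence
profile used only for reporting (nothing downstream consumes it — only
ranks matter). "Strong" means rank ≤ 2 (AATAAA, ATTAAA) by default;
the cutoff is configurable.

Signal-position convention: `signal_end` is the offset of the hexamer's
last base; downstream distances are measured from `signal_end + 1`.
Annotated cleavage sites match a candidate when they fall within
(signal_end, signal_end + 40] in transcript orientation; candidates within
the last 20 nt of the reference 3'UTR are flagged for exclusion, since an
APA site there is indistinguishable from the annotated end.

## GU profile

Window *i* (1-based) covers downstream offsets [i, i+4] after the signal
end; 66 windows span the 70-nt region. The local GU level is the
arithmetic mean of windows 25–45, the region where genuine polyA sites
show elevated GU content; GU-rich means strictly > 0.55 (genomic
background is ≈ 0.5). Windows are anchored at the signal **end**, which
avoids counting the signal's own (A-rich) bases. Records with fewer than
29 nt of downstream sequence (window 25 incomplete) get a missing local
level rather than a padded value; a truncated tail (29–49 nt) averages
the windows present and is flagged.

## EST stage

ESTs covering the SNP are called directly (a base matching neither panel
allele is treated as a sequencing error: unknown, not discarded).
Otherwise the allele is imputed: panel haplotypes consistent with every
allele identified on the EST are selected, and the focal allele is
returned only when it is identical across all of them; ESTs identifying
zero panel alleles are not imputable. An EST is *short* when its 3' end
falls within ±30 nt of the candidate site (cleavage is heterogeneous and
sites sit 10–30 nt downstream of signals, so ±30 covers the spread),
*long* when it ends further downstream, and excluded when it ends more
than 30 nt upstream (an uninformative truncation). PolyA tails are
flagged when the terminal 8 bases contain at most one non-A. The 2×2
allele × length table uses χ² (1 df, no continuity correction) when all
four expected counts exceed 5 and two-sided Fisher's exact test
otherwise; per-gene p-values are BH-adjusted across genes, separately for
the direct-only and direct+imputed modes.

## RNA-seq allele counting and corrected imbalance

Reads are mapped upstream of this package; placements are consumed from
BED-like tables against two reference versions: the extended (±50 nt),
merged 3'UTR regions with reference alleles, and the same regions with
alternate alleles substituted at candidate SNPs. Each read overlapping a
SNP contributes accuracy × map score to its allele's weight, where
map score = (aligned length − mismatches)/aligned length; reads with more
than 10 mismatches, base accuracy < 0.9 at the SNP, or an off-panel base
are dropped. These two thresholds are configurable defaults chosen to
admit ordinary short-read data while excluding unreliable calls.

Genotype per version: heterozygous iff both allele weight proportions are
strictly above 0.15; otherwise homozygous for the majority allele; the
consensus requires both versions to agree (disagreement → no call). The
0.15 rule deliberately trades missed extreme imbalance for a low
false-heterozygote rate. Dosage encodes APA-allele copies: 0/1/2.

Mapping bias is modelled as retention: a read whose base at the SNP
mismatches the mapping reference is kept with probability 1/β (β ≥ 1).
The corrected imbalance AI = ½[log₂(a₁/b₁) + log₂(a₂/b₂)] cancels this
bias exactly — in the reference version the APA (non-reference) allele is
depleted by β, in the alternate version the non-APA allele is, and the
two log-ratios average to log₂ ρ identically. This algebraic identity is
property-tested over β ∈ {1, 1.25, 1.5, 2} × ρ ∈ {0.5, 1, 2, 4}. Log
base 2 is used for every allelic ratio.

Heterozygotes with at least 10 total (version-averaged, weighted) counts
are tested with χ² = (a−m)²/m + (b−m)²/m, m = (a+b)/2, on the continuous
weights (weights are the counting unit; no rounding). Both BH and
Bonferroni columns are reported; the direction claim (APA allele higher)
requires AI > 0.

## Transcript ends

Expressed exons are assigned to genes by overlap; exons touching several
genes are discarded along with every gene they touched. The most
downstream (strand-aware) exon 3' end estimates the transcript end; the
signed distance d to the annotated end is truncated at 29 and transformed
to −log₁₀(30 − d_trunc) — a monotone negative-log distance that handles
arbitrarily short transcripts and maps d ≥ 29 to 0. Any monotone
alternative can be substituted behind the same interface. For the
genotype–length analysis, one candidate per gene is required (shared
genes dropped) and the SNP must lie ≥ 1500 nt upstream of the annotated
end, so genuine shortening is separable from end-estimation noise.

## miRNA scoring

Two profile preparations: (i) sum mature-miRNA expression by 7-nt seed
(positions 2–8) and normalise to proportions; (ii) the probe pipeline —
per-probe mean over samples, drop probes below the mean of means, map to
seeds, sum base^value per seed (log base 2 by default, the common array
convention), renormalise, and drop seeds with no reference mature
sequence. The built-in scorer replaces an external predictor with
canonical seed matching: reverse-complement core match of seed positions
2–7, upgraded by a position-8 match and/or a 3' A to 8mer (1.0),
7mer-m8 (0.75), 7mer-A1 (0.5) or 6mer (0.25); any callable
`(utr, mature) → float` can be plugged in. Scores are normalised per
kilobase (identity optional), averaged per seed over matures, weighted by
seed expression proportion, and averaged over transcript models per gene.
The score difference long − short (short = stop codon to SNP inclusive,
both spliced) is non-negative for additive scorers with identity
normalisation and zero when the SNP sits at the UTR end. High/low
classification splits at the run median by default (ties → low); the
cutoff is a package choice, exposed as a parameter.

## Association statistics

Pearson correlation is the default for the per-SNP genotype–expression
scan (Spearman available); genes whose maximum expression is below the
overall median are removed first; monomorphic SNPs are skipped; BH and
Bonferroni columns are attached. "Partial explained variance" is
incremental (semipartial) R²: R²(full) − R²(full minus the variable).
Residualisation regresses the response on a confounder (e.g. global 3'UTR
GU content) and keeps OLS residuals. The bootstrap for median differences
resamples each group with replacement at its own size, 1000 replicates,
percentile 95% CI (plain percentile, matching the resampling scheme, not
BCa). Two-sided tests throughout, except the imbalance direction claim
above. Probe selection takes the maximum-variance probe per gene,
breaking ties lexicographically.

## GWAS linkage

For an APA-SNP/GWAS-SNP pair, r = (h − p·q)/√(p(1−p)q(1−q)) from phased
haplotypes, where p and q are the APA- and risk-allele frequencies and h
the joint haplotype frequency; this equals the Pearson correlation of the
allele indicator variables (tested to 1e-12). Pairs require a single
unambiguous risk allele and panel r² ≥ 0.5 (configurable; the mapping
threshold is a tunable neighbourhood definition). Per APA-SNP, r is
averaged over partners; mean r² is kept as a secondary aggregate. The
enrichment test is an exact one-sided binomial: successes = functional
candidates satisfying the predicate (r̄ > 0, or r̄ > 0.2; an |r̄| > 0.2
variant is provided since the operand convention is a modelling choice),
null probability = the predicate's proportion among all paired APA-SNPs.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed); the pipeline's
orchestrator derives one generator per stage from the master seed.
Defaults describe the targeted study conditions: 36-nt reads with 1%
base-call error, reference-mapping bias β = 1.5, true allelic ratio
ρ = 2 at functional sites, a genotype effect of 0.5 expression units per
APA-allele copy with unit noise, and cohorts of tens-to-hundreds of
diploid individuals.

* **Genomes**: one plus-strand, single-exon-UTR gene per synthetic
  chromosome, UTR length uniform in range, i.i.d. base composition.
* **Planted candidates**: the 41-nt locus is rewritten on C/G-only filler
  — no signal hexamer can occur inside or straddle a C/G stretch, which
  guarantees the planted hexamer is the locus's only placement — and the
  SNP position within the hexamer and the broken base are chosen so the
  non-signal allele's locus is signal-free (naive breaking can re-create
  a signal, e.g. ATTAAA → ACTAAA). Downstream offsets 25–49 after the
  signal end are resampled at per-base G/T probability 0.8 (rich) or 0.3
  (poor), resampling until the realised class is unambiguous.
* **Haplotypes**: a latent-uniform copy scheme; each SNP's uniform is
  copied from the previous SNP's with probability λ, giving pairwise
  r ≈ λ at equal allele frequencies and perfect coupling at λ = 1.
* **Reads**: `coverage` is the expected depth per chromosome copy, so a
  diploid locus receives 2 × coverage reads; at a heterozygote the
  probability a read carries the APA allele is ρ/(1+ρ). Base miscalls at
  the configured rate with matching Phred strings; retention bias 1/β
  applied to the version-mismatching observed base.
* **ESTs**: allele drawn at the panel frequency; APA-allele ESTs end at
  the proximal site (± jitter) with the configured usage, non-APA ESTs
  at the distal end; cleaved ESTs carry a poly-A tail flag (pure A runs,
  default 12).
* **Expression**: baseline + effect × dosage + slope × GU + Gaussian
  noise.
* **GWAS catalog**: causal APA-SNPs get partner SNPs whose risk allele
  mirrors the APA-allele haplotype at the chosen coupling; decoys get
  partners in the same LD but tied to a randomly chosen allele, so the
  correlation sign is random.

Not emulated: splicing and multi-exon UTR structure in reads, indels,
paired-end fragment geometry, PCR duplicates, population structure, and
expression covariance between genes. Passing tests therefore demonstrate
correctness of the statistics and recovery under the stated generative
model, not robustness to every artefact of real libraries. An optional
3'-coverage ramp mimicking cDNA-fragmentation bias exists but is off by
default.

## Calibration experiments and problem sizes

The calibration module runs each experiment at sizes chosen to give tight
Monte-Carlo error on one CPU in seconds-to-tens-of-seconds: 10,000 random
loci for scanner/filter brute-force agreement; 1,000 SNP/sample pairs at
per-copy coverage 20 and 1% error for genotyping (observed: 100% accuracy,
0 false heterozygotes); 50 planted (rank ≤ 2, GU-rich, ρ = 2, coverage
100) among 200 decoys × 20 replicates for the imbalance scan (observed
sensitivity ≈ 0.96 at observed FDR < 0.01 with BH 0.05 and AI > 0);
1,000 datasets × 1,000 bootstrap replicates for CI coverage (observed
≈ 96%); 50 planted expression effects among 200 SNPs at n = 270 × 20
replicates (observed recovery ≈ 100%, miRNA incremental R² ≈ 0.45 planted
vs ≈ 0.003 null); 500 null EST replicates for uniformity and 200 for
power. The null-uniformity check uses per-gene EST depth ~ Poisson(60)
per allele with usage drawn in (0.3, 0.7): at 20 ESTs/allele the discrete
2×2 p-value has a ≈ 0.14 probability atom at p = 1, which no continuous
uniformity test tolerates; at depth ≈ 60 the discreteness is negligible
while the null (usage independent of allele) is unchanged. The power
scenario keeps 20 ESTs per allele. Type-I error of the contingency test
is separately verified to be ≤ nominal at 20 ESTs/allele.

## Known limitations

* The scanner assumes bi-allelic substitution SNPs; indels in signals are
  out of scope.
* EST library/tissue heterogeneity is not modelled; real EST tests should
  be read as association, not mechanism.
* The imbalance test treats reads as independent; fragment-level
  duplicates would inflate the χ².
* The seed-match miRNA scorer ignores site context, conservation and 3'
  supplementary pairing; only the short-vs-long *difference* is used
  downstream, which is robust to the scorer's absolute scale.
* The GWAS mapping threshold and the strong/weak rank cutoff are
  conventions, exposed as parameters and stamped into output provenance
  headers.
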