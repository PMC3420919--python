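"""Scan for SNPs that create or disrupt polyadenylation-signal hexamers.

Thirteen hexamers are known to act as polyA signals in human genes.  They are
held here in DNA alphabet, ordered by strength rank (1 = strongest, i.e. the
hexamer most frequently found upstream of real cleavage sites).  A SNP whose
two alleles differ in whether a 13-nt window centred on the SNP contains one
of these hexamers is a candidate APA-SNP: the allele carrying the signal is
the "APA allele", expected to support a proximal cleavage site and hence a
shorter 3'UTR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneModel, SnpRecord

# hexamer, strength rank, approximate frequency among signal-bearing human
# polyA sites (strongest first; used for ordering and reporting only)
SIGNAL_TABLE: list[tuple[str, int, float]] = [
    ("AATAAA", 1, 0.532),
    ("ATTAAA", 2, 0.169),
    ("TATAAA", 3, 0.032),
    ("AGTAAA", 4, 0.028),
    ("AAGAAA", 5, 0.027),
    ("AATATA", 6, 0.017),
    ("AATACA", 7, 0.016),
    ("CATAAA", 8, 0.013),
    ("GATAAA", 9, 0.012),
    ("AATGAA", 10, 0.011),
    ("TTTAAA", 11, 0.009),
    ("ACTAAA", 12, 0.008),
    ("AATAGA", 13, 0.007),
]

SIGNAL_HEXAMERS: list[str] = [h for h, _, _ in SIGNAL_TABLE]
HEXAMER_RANK: dict[str, int] = {h: r for h, r, _ in SIGNAL_TABLE}
HEXAMER_FREQ: dict[str, float] = {h: f for h, _, f in SIGNAL_TABLE}

WINDOW_FLANK = 6          # nt of flank either side of the SNP in the scan window
WINDOW_LEN = 2 * WINDOW_FLANK + 1
LOCUS_FLANK = 20          # "40 nt around the SNP" single-signal-locus filter


@dataclass
class SignalChange:
    """How a SNP's two alleles differ in polyA-signal content."""

    snp_id: str
    change_kind: str              # created | disrupted | signal_to_signal | none
    hexamer: str | None = None
    rank: int | None = None
    apa_allele: str | None = None
    signal_start_offset: int | None = None   # hexamer start relative to the SNP

    @property
    def signal_end_offset(self) -> int | None:
        """Offset of the hexamer's last base relative to the SNP."""
        if self.signal_start_offset is None:
            return None
        return self.signal_start_offset + 5


@dataclass
class CandidateApaSnp:
    """A SNP passing all candidate filters, with its locus annotations."""

    snp_id: str
    gene_id: str
    change: SignalChange
    utr_offset: int                       # spliced-UTR offset of the SNP
    distance_to_annotated_end: int        # nt from SNP to UTR 3' end
    local_gu_level: float | None = None
    gu_rich: bool | None = None
    global_gu_level: float | None = None
    strength_class: str | None = None
    near_utr_end: bool = False

    @property
    def rank(self) -> int:
        assert self.change.rank is not None
        return self.change.rank

    @property
    def apa_allele(self) -> str:
        assert self.change.apa_allele is not None
        return self.change.apa_allele


def hexamer_hits(seq: str) -> list[tuple[int, str]]:
    """All (start, hexamer) signal placements in ``seq``."""
    return [
        (i, seq[i : i + 6])
        for i in range(len(seq) - 5)
        if seq[i : i + 6] in HEXAMER_RANK
    ]


def snp_window(utr_seq: str, utr_offset: int, ref: str, alt: str) -> tuple[str, str]:
    """13-nt windows around a SNP on the spliced UTR, one per allele.

    The SNP sits at the window centre.  Near the UTR ends the window is
    clipped to the available sequence (hexamer placements falling off the end
    simply cannot match); a UTR shorter than 13 nt is rejected.
    """
    if len(utr_seq) < WINDOW_LEN:
        raise ValueError(f"3'UTR shorter than {WINDOW_LEN} nt")
    if not (0 <= utr_offset < len(utr_seq)):
        raise ValueError("SNP offset outside the UTR")
    if utr_seq[utr_offset] != ref:
        raise ValueError(
            f"UTR base {utr_seq[utr_offset]} at offset {utr_offset} "
            f"does not match the reference allele {ref}"
        )
    lo = max(0, utr_offset - WINDOW_FLANK)
    hi = min(len(utr_seq), utr_offset + WINDOW_FLANK + 1)
    ref_win = utr_seq[lo:hi]
    centre = utr_offset - lo
    alt_win = ref_win[:centre] + alt + ref_win[centre + 1 :]
    return ref_win, alt_win


def _snp_covering_hits(window: str, centre: int) -> list[tuple[int, str]]:
    """Signal placements in a window whose hexamer covers the SNP position."""
    return [
        (start, hexa)
        for start, hexa in hexamer_hits(window)
        if start <= centre <= start + 5
    ]


def classify_change(
    snp_id: str,
    ref_window: str,
    alt_window: str,
    ref_allele: str,
    alt_allele: str,
    centre: int | None = None,
) -> SignalChange:
    """Classify a SNP by the signal hexamers overlapping it on each allele.

    Only hexamer placements covering the SNP itself count: a placement not
    covering the SNP is identical on both alleles and carries no allelic
    information.  If one allele yields several distinct hits, the strongest
    (lowest rank) is reported.
    """
    if len(ref_window) != len(alt_window):
        raise ValueError("allele windows differ in length")
    if centre is None:
        centre = len(ref_window) // 2
    ref_hits = _snp_covering_hits(ref_window, centre)
    alt_hits = _snp_covering_hits(alt_window, centre)

    def best(hits: list[tuple[int, str]]) -> tuple[int, str]:
        return min(hits, key=lambda h: HEXAMER_RANK[h[1]])

    if ref_hits and alt_hits:
        return SignalChange(snp_id, "signal_to_signal")
    if alt_hits and not ref_hits:
        start, hexa = best(alt_hits)
        return SignalChange(snp_id, "created", hexa, HEXAMER_RANK[hexa],
                            alt_allele, start - centre)
    if ref_hits and not alt_hits:
        start, hexa = best(ref_hits)
        return SignalChange(snp_id, "disrupted", hexa, HEXAMER_RANK[hexa],
                            ref_allele, start - centre)
    return SignalChange(snp_id, "none")


def locus_signal_count(utr_seq: str, utr_offset: int, allele: str,
                       flank: int = LOCUS_FLANK) -> int:
    """Distinct signal placements in the SNP +/- ``flank`` locus for one allele."""
    seq = utr_seq[:utr_offset] + allele + utr_seq[utr_offset + 1 :]
    lo = max(0, utr_offset - flank)
    hi = min(len(seq), utr_offset + flank + 1)
    return len(hexamer_hits(seq[lo:hi]))


def filter_candidates(
    changes: Iterable[SignalChange],
    snps: Mapping[str, SnpRecord],
    genes: Mapping[str, GeneModel],
    snp_gene: Mapping[str, str],
    utr_seqs: Mapping[str, str],
    snp_utr_offset: Mapping[str, int],
) -> list[CandidateApaSnp]:
    """Apply the three candidate filters to classified SNPs.

    A SNP is kept iff (i) its change is a clean creation or disruption (not
    signal-to-signal, not none), (ii) the signal-bearing allele's 41-nt locus
    around the SNP holds exactly one signal placement and the other allele's
    locus holds none — i.e. the locus goes from no signal to one signal — and
    (iii) the SNP is polymorphic (minor allele frequency > 0).
    """
    out = []
    for change in changes:
        if change.change_kind not in ("created", "disrupted"):
            continue
        snp = snps[change.snp_id]
        if snp.minor_allele_freq <= 0:
            continue
        gene_id = snp_gene[change.snp_id]
        utr = utr_seqs[gene_id]
        off = snp_utr_offset[change.snp_id]
        apa = change.apa_allele
        other = snp.alt_allele if apa == snp.ref_allele else snp.ref_allele
        if locus_signal_count(utr, off, apa) != 1:
            continue
        if locus_signal_count(utr, off, other) != 0:
            continue
        out.append(
            CandidateApaSnp(
                snp_id=change.snp_id,
                gene_id=gene_id,
                change=change,
                utr_offset=off,
                distance_to_annotated_end=len(utr) - 1 - off,
            )
        )
    return out


def classify_strength(rank: int, strong_max_rank: int = 2) -> str:
    """Strong iff the signal rank is at or below the cutoff (default top 2)."""
    return "strong" if rank <= strong_max_rank else "weak"


def scan_snps(
    snps: Sequence[SnpRecord],
    genes: Sequence[GeneModel],
    chrom_seqs: Mapping[str, str],
) -> tuple[list[SignalChange], dict[str, str], dict[str, int], dict[str, str]]:
    """Classify every SNP lying in a gene's 3'UTR.

    Returns (changes, snp->gene map, snp->spliced-UTR offset map,
    gene->spliced UTR sequence map).  SNPs outside any 3'UTR are skipped.
    Minus-strand genes are scanned on the reverse complement, so alleles are
    complemented into transcript orientation first.
    """
    from .io_formats import COMPLEMENT

    changes: list[SignalChange] = []
    snp_gene: dict[str, str] = {}
    snp_off: dict[str, int] = {}
    utr_seqs: dict[str, str] = {}
    gene_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.chrom, []).append(g)
        utr_seqs[g.gene_id] = g.spliced_utr3(chrom_seqs[g.chrom])
    for snp in snps:
        for g in gene_by_chrom.get(snp.chrom, []):
            if not any(s <= snp.pos < e for s, e in g.utr3_intervals):
                continue
            off = g.genomic_to_utr_offset(snp.pos)
            if g.strand == "+":
                ref, alt = snp.ref_allele, snp.alt_allele
            else:
                ref = snp.ref_allele.translate(COMPLEMENT)
                alt = snp.alt_allele.translate(COMPLEMENT)
            utr = utr_seqs[g.gene_id]
            ref_win, alt_win = snp_window(utr, off, ref, alt)
            centre = off - max(0, off - WINDOW_FLANK)
            changes.append(
                classify_change(snp.snp_id, ref_win, alt_win, ref, alt, centre)
            )
            snp_gene[snp.snp_id] = g.gene_id
            snp_off[snp.snp_id] = off
            break
    return changes, snp_gene, snp_off, utr_seqs


def intersect_polya_sites(
    candidates: Sequence[CandidateApaSnp],
    site_positions: Mapping[str, Sequence[int]],
    max_downstream: int = 40,
    end_exclusion: int = 20,
) -> list[tuple[CandidateApaSnp, int]]:
    """Match candidates to annotated cleavage sites just downstream.

    ``site_positions`` maps gene id to cleavage positions given as spliced-UTR
    offsets.  A site matches a candidate iff it lies in
    ``(signal_end, signal_end + max_downstream]`` in transcript orientation.
    Candidates within the last ``end_exclusion`` nt of the reference 3'UTR
    are flagged (``near_utr_end``): an APA site there is indistinguishable
    from the annotated end and is excluded from downstream analyses.
    """
    pairs = []
    for cand in candidates:
        if cand.distance_to_annotated_end < end_exclusion:
            cand.near_utr_end = True
        sig_end = cand.utr_offset + (cand.change.signal_end_offset or 0)
        for site in site_positions.get(cand.gene_id, ()):
            if sig_end < site <= sig_end + max_downstream:
                pairs.append((cand, site))
    return pairs


def hexamer_enrichment(utr_seqs: Iterable[str]) -> "np.ndarray":
    """Per-hexamer motif counts, relative frequencies, and PAS/motif ratios.

    Returns a structured array-like list of dicts with keys hexamer, rank,
    count, motif_freq (relative frequency among the 13 hexamers across all
    UTRs) and ratio (signal-site frequency / motif frequency): the ratio is
    high for hexamers that cause polyadenylation more often than their raw
    abundance predicts.
    """
    counts = {h: 0 for h in SIGNAL_HEXAMERS}
    for seq in utr_seqs:
        for _, hexa in hexamer_hits(seq):
            counts[hexa] += 1
    total = sum(counts.values())
    rows = []
    for hexa, rank, pas_freq in SIGNAL_TABLE:
        motif_freq = counts[hexa] / total if total else float("nan")
        ratio = pas_freq / motif_freq if total and motif_freq > 0 else float("nan")
        rows.append(
            dict(hexamer=hexa, rank=rank, count=counts[hexa],
                 motif_freq=motif_freq, pas_freq=pas_freq, ratio=ratio)
        )
    return rows


def snp_density_profile(
    snp_rel_positions: Sequence[float], n_bins: int = 20
) -> np.ndarray:
    """Histogram of SNP density over relative 3'UTR position, mean-normalised.

    ``snp_rel_positions`` are SNP positions scaled to [0, 1] along their
    UTRs (0 = stop codon, 1 = annotated transcript end).  Densities are
    normalised so a uniform distribution gives 1 in every bin.
    """
    pos = np.asarray(snp_rel_positions, dtype=float)
    if pos.size == 0:
        raise ValueError("empty SNP set")
    if pos.min() < 0 or pos.max() > 1:
        raise ValueError("relative positions must lie in [0, 1]")
    counts, _ = np.histogram(pos, bins=n_bins, range=(0.0, 1.0))
    return counts / counts.mean()


def end_window_density(
    snp_end_distances: Sequence[int], window: int = 200, n_bins: int = 20
) -> np.ndarray:
    """Density over distance upstream of the transcript end, mean-normalised."""
    d = np.asarray(snp_end_distances, dtype=float)
    d = d[(d >= 0) & (d < window)]
    if d.size == 0:
        raise ValueError("no SNPs within the end window")
    counts, _ = np.histogram(d, bins=n_bins, range=(0, window))
    return counts / counts.mean()
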