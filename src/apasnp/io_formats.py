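"""Readers and writers for the external formats the pipeline touches.

Conventions enforced throughout the package:

* all genomic intervals are 0-based, half-open (BED native; GTF converted
  on read);
* sequences are folded to uppercase DNA (``T`` canonical, ``U`` accepted on
  input and converted), so polyadenylation-signal hexamers are stored and
  matched as e.g. ``AATAAA``;
* FASTQ qualities are Sanger Phred+33, decoded to per-base accuracy
  ``p = 1 - 10 ** (-(ascii - 33) / 10)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and canonicalise U to T."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain records


@dataclass
class GeneModel:
    """A gene with its 3'UTR structure in genomic coordinates.

    ``utr3_intervals`` are 0-based half-open genomic intervals, stored sorted
    5'->3' in transcript orientation (descending genomic start on the minus
    strand).  ``annotated_end`` is the strand-aware 3'-most coordinate of the
    transcript (for ``+`` the end of the last interval, for ``-`` its start).
    """

    gene_id: str
    chrom: str
    strand: str
    transcript_intervals: list[tuple[int, int]] = field(default_factory=list)
    cds_end: int = 0
    utr3_intervals: list[tuple[int, int]] = field(default_factory=list)
    annotated_end: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for start, end in self.utr3_intervals:
            if start >= end:
                raise ValueError(f"empty interval ({start}, {end})")

    def spliced_utr3(self, chrom_seq: str) -> str:
        """Spliced 3'UTR sequence in transcript orientation (5'->3')."""
        ivals = sorted(self.utr3_intervals)
        seq = "".join(chrom_seq[s:e] for s, e in ivals)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return normalize_sequence(seq)

    def genomic_to_utr_offset(self, pos: int) -> int:
        """Map a genomic position inside the 3'UTR to a spliced-UTR offset."""
        ivals = sorted(self.utr3_intervals)
        total = sum(e - s for s, e in ivals)
        off = 0
        for s, e in ivals:
            if s <= pos < e:
                plus_off = off + (pos - s)
                return plus_off if self.strand == "+" else total - 1 - plus_off
            off += e - s
        raise ValueError(f"position {pos} not inside the 3'UTR of {self.gene_id}")

    @property
    def utr3_length(self) -> int:
        return sum(e - s for s, e in self.utr3_intervals)


@dataclass
class SnpRecord:
    """A bi-allelic SNP with population allele frequencies."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    allele_freqs: dict[str, float]

    def __post_init__(self) -> None:
        for a in (self.ref_allele, self.alt_allele):
            if a not in "ACGT" or len(a) != 1:
                raise ValueError(f"allele must be a single A/C/G/T base, got {a!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("SNP must be bi-allelic")
        if set(self.allele_freqs) != {self.ref_allele, self.alt_allele}:
            raise ValueError("allele_freqs keys must be exactly the two alleles")
        if abs(sum(self.allele_freqs.values()) - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.alt_allele)

    @property
    def minor_allele_freq(self) -> float:
        return min(self.allele_freqs.values())


@dataclass
class ReadPlacement:
    """One read aligned to one target sequence (no realignment is done here)."""

    read_id: str
    target: str
    start: int
    mismatches: int
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and quality strings differ in length")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: uppercase sequence}`` map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r}")
        out[rec.id] = normalize_sequence(str(rec.seq))
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(normalize_sequence(s)), id=name, description="")
        for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# FASTQ


def phred_accuracy(qual_char: str) -> float:
    """Probability that a base call is correct, from its Phred+33 character."""
    q = ord(qual_char) - 33
    if q < 0:
        raise ValueError(f"quality character {qual_char!r} below Phred+33 range")
    return 1.0 - 10.0 ** (-q / 10.0)


def accuracy_to_phred_char(accuracy: float, max_q: int = 60) -> str:
    """Inverse of :func:`phred_accuracy`, rounded to the nearest integer Q."""
    import math

    if accuracy >= 1.0:
        q = max_q
    else:
        q = min(max_q, max(0, round(-10.0 * math.log10(1.0 - accuracy))))
    return chr(q + 33)


@dataclass
class FastqRead:
    read_id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence/quality length mismatch"
            )

    @property
    def accuracies(self) -> list[float]:
        return [phred_accuracy(c) for c in self.qualities]


def read_fastq(path: str | Path) -> list[FastqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(FastqRead(rec.id, normalize_sequence(str(rec.seq)), quals))
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[BedRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\s+", line.strip())
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else 0.0
            strand = fields[5] if len(fields) > 5 else "+"
            try:
                out.append(BedRecord(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# typed TSV tables

SNP_TABLE_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "freq_ref", "freq_alt"]
MIRNA_TABLE_COLUMNS = ["mature_id", "seed7", "mature_seq", "expression"]
GWAS_TABLE_COLUMNS = ["snp_id", "risk_allele", "population_class", "trait"]


def read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    """Read a headered TSV and validate that the required columns exist."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    df = read_table(path, SNP_TABLE_COLUMNS)
    snps = []
    for row in df.itertuples(index=False):
        snps.append(
            SnpRecord(
                snp_id=row.snp_id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref_allele=row.ref,
                alt_allele=row.alt,
                allele_freqs={row.ref: float(row.freq_ref), row.alt: float(row.freq_alt)},
            )
        )
    return snps


def write_snp_table(snps: Iterable[SnpRecord], path: str | Path) -> None:
    rows = [
        dict(
            snp_id=s.snp_id,
            chrom=s.chrom,
            pos=s.pos,
            ref=s.ref_allele,
            alt=s.alt_allele,
            freq_ref=s.allele_freqs[s.ref_allele],
            freq_alt=s.allele_freqs[s.alt_allele],
        )
        for s in snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_haplotype_table(path: str | Path) -> pd.DataFrame:
    """Phased haplotype panel: columns individual, phase, then one per SNP.

    Returns a DataFrame indexed by (individual, phase) whose columns are SNP
    ids and whose values are single-base alleles.
    """
    df = read_table(path, ["individual", "phase"])
    df["phase"] = df["phase"].astype(int)
    df = df.set_index(["individual", "phase"])
    for col in df.columns:
        bad = set(df[col].astype(str)) - set("ACGT")
        if bad:
            raise ValueError(f"{path}: non-allele values {sorted(bad)} in column {col}")
    return df


def write_haplotype_table(panel: pd.DataFrame, path: str | Path) -> None:
    panel.reset_index().to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Expression matrix: first column gene/probe id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    mat = df.apply(pd.to_numeric, errors="coerce")
    if mat.isna().any().any():
        raise ValueError(f"{path}: unparseable numeric value in expression matrix")
    return mat


def read_mirna_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path, MIRNA_TABLE_COLUMNS)
    df["expression"] = pd.to_numeric(df["expression"])
    df["seed7"] = df["seed7"].map(normalize_sequence)
    df["mature_seq"] = df["mature_seq"].map(normalize_sequence)
    return df


def read_gwas_table(path: str | Path, drop_ambiguous: bool = True) -> pd.DataFrame:
    """GWAS catalog rows; rows without one unique risk allele are dropped.

    A row whose ``risk_allele`` is not a single A/C/G/T base (e.g. ``A/G`` or
    ``?``) has no usable risk allele and is excluded when
    ``drop_ambiguous`` is set.
    """
    df = read_table(path, GWAS_TABLE_COLUMNS)
    if drop_ambiguous:
        ok = df["risk_allele"].str.fullmatch("[ACGT]")
        df = df[ok.fillna(False)].reset_index(drop=True)
    return df


def read_gene_models_bed(path: str | Path) -> list[GeneModel]:
    """Gene models from a BED-like table with one row per 3'UTR exon.

    The ``name`` field carries the gene id; rows of one gene share chrom and
    strand.  ``cds_end``/``annotated_end`` derive from the interval extremes.
    """
    recs = read_bed(path)
    by_gene: dict[str, list[BedRecord]] = {}
    for r in recs:
        by_gene.setdefault(r.name, []).append(r)
    genes = []
    for gid, rows in by_gene.items():
        strand = rows[0].strand
        ivals = sorted((r.start, r.end) for r in rows)
        if strand == "+":
            annotated_end = ivals[-1][1]
            cds_end = ivals[0][0]
        else:
            annotated_end = ivals[0][0]
            cds_end = ivals[-1][1]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=rows[0].chrom,
                strand=strand,
                transcript_intervals=ivals,
                cds_end=cds_end,
                utr3_intervals=ivals,
                annotated_end=annotated_end,
            )
        )
    return genes


def write_gene_models_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    recs = [
        BedRecord(g.chrom, s, e, g.gene_id, 0, g.strand)
        for g in genes
        for s, e in sorted(g.utr3_intervals)
    ]
    write_bed(recs, path)
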