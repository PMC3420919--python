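"""Transcript 3'-end estimation from expressed exons.

For each gene and sample, the 3' end of the most-downstream expressed exon
estimates the transcript end.  The signed distance d = estimate - annotated
end (transcript orientation; negative means shorter than annotation) is
right-truncated at 29 — estimates past the annotation are rare and carry no
shortening information — and mapped to a negative log scale,
response = -log10(30 - d_trunc), which is monotone increasing in d and
defined for arbitrarily short transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc_stats import pearson, regression_partial_r2, residualize
from .io_formats import GeneModel

TRUNCATION = 29


@dataclass
class EndEstimate:
    gene_id: str
    sample_id: str
    estimated_end: int
    d: int
    d_trunc: int
    response: float


def distance_response(d: float) -> float:
    d_trunc = min(d, TRUNCATION)
    return float(-np.log10(30.0 - d_trunc))


def assign_exons(
    exons: list[tuple[str, int, int]],
    genes: list[GeneModel],
) -> dict[str, list[tuple[int, int]]]:
    """Assign expressed exons (chrom, start, end) to genes by overlap.

    Exons overlapping several genes are discarded, and every gene such an
    exon touched is dropped from the analysis entirely (its end estimate
    would be contaminated by the neighbour's transcription).
    """
    assigned: dict[str, list[tuple[int, int]]] = {}
    dropped_genes: set[str] = set()
    for chrom, start, end in exons:
        hits = [
            g.gene_id
            for g in genes
            if g.chrom == chrom
            and any(start < e and s < end for s, e in g.transcript_intervals)
        ]
        if len(hits) > 1:
            dropped_genes.update(hits)
        elif len(hits) == 1:
            assigned.setdefault(hits[0], []).append((start, end))
    for gid in dropped_genes:
        assigned.pop(gid, None)
    return assigned


def estimate_end(
    gene: GeneModel, exons: list[tuple[int, int]], sample_id: str
) -> EndEstimate | None:
    """Strand-aware most-downstream exon 3' end vs the annotated end."""
    if not exons:
        return None
    if gene.strand == "+":
        est = max(e for _, e in exons)
        d = est - gene.annotated_end
    else:
        est = min(s for s, _ in exons)
        d = gene.annotated_end - est
    return EndEstimate(
        gene_id=gene.gene_id,
        sample_id=sample_id,
        estimated_end=est,
        d=int(d),
        d_trunc=int(min(d, TRUNCATION)),
        response=distance_response(d),
    )


def filter_snps_for_length(
    candidates,
    genes: dict[str, GeneModel],
    min_upstream: int = 1500,
) -> list:
    """Length-analysis SNP set: one candidate per gene, far from the end.

    Candidates sharing a gene are all removed (their length signals would be
    confounded), and a candidate must lie at least ``min_upstream`` nt
    upstream of the annotated 3' end so that genuine shortening is
    distinguishable from end-estimation noise.
    """
    by_gene: dict[str, list] = {}
    for c in candidates:
        by_gene.setdefault(c.gene_id, []).append(c)
    out = []
    for gene_id, cands in by_gene.items():
        if len(cands) != 1:
            continue
        cand = cands[0]
        if cand.distance_to_annotated_end >= min_upstream:
            out.append(cand)
    return out


def genotype_length_correlation(
    data: pd.DataFrame,
    extra_predictors: list[str] | None = None,
    residualize_on: str | None = None,
) -> dict:
    """Correlations and multiple regression of the end-distance response.

    ``data`` needs columns ``response``, ``genotype`` (APA dosage 0/1/2) and
    ``proliferating`` (0/1); optional further predictors (signal strength,
    local/global GU) are named in ``extra_predictors``.  Reports Pearson
    correlations overall and within each proliferation group, plus the full
    multiple regression (optionally on the response residualised against a
    confounder column, e.g. global GU).
    """
    out: dict = {}
    y = data["response"].to_numpy(dtype=float)
    if residualize_on is not None:
        y = residualize(y, data[residualize_on].to_numpy(dtype=float))
    out["genotype"] = pearson(data["genotype"], y)
    out["proliferation"] = pearson(data["proliferating"], y)
    for label, grp in data.assign(_y=y).groupby("proliferating"):
        out[f"genotype_prolif_{int(label)}"] = pearson(grp["genotype"], grp["_y"])
    predictors = {
        "genotype": data["genotype"].to_numpy(dtype=float),
        "proliferating": data["proliferating"].to_numpy(dtype=float),
    }
    for name in extra_predictors or []:
        predictors[name] = data[name].to_numpy(dtype=float)
    out["regression"] = regression_partial_r2(y, predictors)
    return out
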