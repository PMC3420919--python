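"""LD-based linkage of APA alleles with GWAS risk alleles.

For an APA-SNP/GWAS-SNP pair, the correlation between the APA allele and
the risk allele on population haplotypes is

    r = D / sqrt(p_apa (1 - p_apa) p_risk (1 - p_risk)),   D = h - p_apa p_risk

where h is the joint "APA allele + risk allele" haplotype frequency.  A
positive r means the APA allele tends to ride on the same haplotype as the
risk allele, as expected if the APA-SNP itself drives the association
signal.  Per APA-SNP, r is averaged over its GWAS partners; enrichment of
positive / strong mean correlations among independently flagged functional
candidates is tested with one-sided binomial tests against the background
proportion among all paired APA-SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LdPairRecord:
    apa_snp_id: str
    gwas_snp_id: str
    p_apa: float
    p_risk: float
    h: float
    population_class: str = "other"

    @property
    def d(self) -> float:
        return self.h - self.p_apa * self.p_risk

    @property
    def r(self) -> float:
        return apa_risk_r(self.p_apa, self.p_risk, self.h)


@dataclass
class ApaSnpAggregate:
    apa_snp_id: str
    mean_r: float
    mean_r2: float
    n_pairs: int
    is_candidate_functional: bool = False


def apa_risk_r(p_apa: float, p_risk: float, h: float) -> float:
    """Haplotype correlation between APA allele and risk allele."""
    if not (0 < p_apa < 1 and 0 < p_risk < 1):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    if h > min(p_apa, p_risk) + 1e-12:
        raise ValueError("joint haplotype frequency exceeds a marginal frequency")
    d = h - p_apa * p_risk
    return float(d / np.sqrt(p_apa * (1 - p_apa) * p_risk * (1 - p_risk)))


def haplotype_r(panel: pd.DataFrame, snp_a: str, allele_a: str,
                snp_b: str, allele_b: str) -> float:
    """r estimated directly from a phased panel (rows = haplotypes)."""
    ind_a = (panel[snp_a].to_numpy() == allele_a).astype(float)
    ind_b = (panel[snp_b].to_numpy() == allele_b).astype(float)
    p_a, p_b = ind_a.mean(), ind_b.mean()
    h = (ind_a * ind_b).mean()
    return apa_risk_r(p_a, p_b, h)


def ld_map(
    apa_snps: list[tuple[str, str]],
    gwas: pd.DataFrame,
    panel: pd.DataFrame,
    ld_threshold: float = 0.5,
) -> list[LdPairRecord]:
    """Candidate APA-SNP/GWAS-SNP pairs with panel r-squared >= threshold.

    ``apa_snps`` holds (snp_id, apa_allele); ``gwas`` rows need snp_id,
    risk_allele and population_class, with ambiguous risk alleles already
    removed on read.  Pairing requires both SNPs phased in the panel.
    """
    out = []
    for apa_id, apa_allele in apa_snps:
        if apa_id not in panel.columns:
            continue
        for row in gwas.itertuples(index=False):
            if row.snp_id not in panel.columns or row.snp_id == apa_id:
                continue
            try:
                r = haplotype_r(panel, apa_id, apa_allele,
                                row.snp_id, row.risk_allele)
            except ValueError:       # monomorphic in this panel
                continue
            if r * r >= ld_threshold:
                ind_a = (panel[apa_id].to_numpy() == apa_allele).astype(float)
                ind_b = (panel[row.snp_id].to_numpy() == row.risk_allele).astype(float)
                out.append(
                    LdPairRecord(
                        apa_snp_id=apa_id,
                        gwas_snp_id=row.snp_id,
                        p_apa=float(ind_a.mean()),
                        p_risk=float(ind_b.mean()),
                        h=float((ind_a * ind_b).mean()),
                        population_class=row.population_class,
                    )
                )
    return out


def aggregate(
    pairs: list[LdPairRecord],
    functional_ids: set[str] | None = None,
    population_class: str | None = None,
) -> list[ApaSnpAggregate]:
    """Mean r (and mean r-squared) per APA-SNP over its GWAS partners."""
    functional_ids = functional_ids or set()
    by_snp: dict[str, list[LdPairRecord]] = {}
    for p in pairs:
        if population_class is not None and p.population_class != population_class:
            continue
        by_snp.setdefault(p.apa_snp_id, []).append(p)
    out = []
    for snp_id, snp_pairs in by_snp.items():
        rs = np.array([p.r for p in snp_pairs])
        out.append(
            ApaSnpAggregate(
                apa_snp_id=snp_id,
                mean_r=float(rs.mean()),
                mean_r2=float((rs ** 2).mean()),
                n_pairs=len(snp_pairs),
                is_candidate_functional=snp_id in functional_ids,
            )
        )
    return out


def binomial_predicate_test(
    aggregates: list[ApaSnpAggregate],
    predicate,
    p0: float | None = None,
) -> dict:
    """One-sided binomial test of a predicate among functional candidates.

    Success probability under the null defaults to the predicate's
    proportion among all paired APA-SNPs; the test asks whether the
    functional candidates satisfy it more often than that background, with
    p = P(X >= k | n, p0), the exact upper tail.
    """
    if p0 is None:
        if not aggregates:
            raise ValueError("no aggregates to derive the null proportion from")
        p0 = float(np.mean([predicate(a) for a in aggregates]))
    cands = [a for a in aggregates if a.is_candidate_functional]
    if not cands:
        raise ValueError("empty functional-candidate subset")
    n = len(cands)
    k = int(sum(predicate(a) for a in cands))
    if p0 in (0.0, 1.0):
        p_value = 1.0 if (p0 == 1.0 or k == 0) else 0.0
        degenerate = True
    else:
        p_value = float(stats.binom.sf(k - 1, n, p0))
        degenerate = False
    return dict(successes=k, trials=n, p0=p0, p_value=p_value,
                degenerate=degenerate)


PREDICATES = {
    "mean_r_positive": lambda a: a.mean_r > 0,
    "mean_r_gt_0.2": lambda a: a.mean_r > 0.2,
    "abs_mean_r_gt_0.2": lambda a: abs(a.mean_r) > 0.2,
}
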