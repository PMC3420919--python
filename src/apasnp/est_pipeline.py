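"""EST-based evidence for allele-dependent 3'UTR shortening.

ESTs are single-pass cDNA reads whose 3' ends mark cleavage sites.  For a
candidate APA-SNP this stage calls the SNP allele directly from the EST
sequence when the EST covers the SNP, imputes it from a phased haplotype
panel otherwise, classifies each EST as ending at the candidate site
("short") or further downstream ("long"), and tests the 2x2 allele-by-length
table: chi-square when all four expected counts exceed 5, Fisher's exact
test otherwise, following the usual small-count switch rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_stats import correct_multiple


@dataclass
class EstObservation:
    est_id: str
    end_pos: int                       # transcript-orientation 3'-most offset
    called_alleles: dict[str, str] = field(default_factory=dict)
    imputed: bool = False
    has_polya_tail: bool = False


@dataclass
class ContingencyResult:
    table: np.ndarray                  # rows: APA / non-APA, cols: short / long
    test_used: str                     # "chi-square" | "fisher"
    p_value: float


def call_est_allele(
    est_seq: str, est_start: int, snp_offset: int, alleles: tuple[str, str]
) -> str | None:
    """Base at the SNP if the EST covers it and matches a panel allele.

    ``est_start`` is the EST's alignment start on the spliced UTR.  A covered
    base matching neither allele is treated as a sequencing error and
    returned as unknown (None) rather than discarding the EST.
    """
    if not (est_start <= snp_offset < est_start + len(est_seq)):
        return None
    base = est_seq[snp_offset - est_start]
    return base if base in alleles else None


def impute_est_allele(
    est_alleles: dict[str, str],
    panel: pd.DataFrame,
    focal_snp: str,
) -> str | None:
    """Impute the focal-SNP allele from haplotypes consistent with the EST.

    ``est_alleles`` maps panel SNP ids to alleles observed on the EST
    (excluding the focal SNP).  Panel haplotypes (rows of ``panel``, columns
    = SNP ids) are filtered to those matching every observed allele; the
    focal allele is returned iff it is identical across all matching
    haplotypes.  ESTs with zero identified alleles are not imputable.
    """
    known = {s: a for s, a in est_alleles.items() if s != focal_snp and s in panel.columns}
    if not known:
        return None
    mask = np.ones(len(panel), dtype=bool)
    for snp_id, allele in known.items():
        mask &= (panel[snp_id].to_numpy() == allele)
    if not mask.any():
        return None
    focal = panel.loc[mask, focal_snp].unique()
    return str(focal[0]) if len(focal) == 1 else None


def classify_est_length(
    end_pos: int, apa_site_pos: int, half_width: int = 30
) -> str:
    """Short iff the EST ends within ``half_width`` nt of the candidate site.

    ESTs ending more than ``half_width`` nt downstream are "long"; ESTs
    truncated upstream of the site are uninformative and excluded.
    """
    if abs(end_pos - apa_site_pos) <= half_width:
        return "short"
    if end_pos > apa_site_pos + half_width:
        return "long"
    return "excluded"


def detect_polya_tail(est_3p_seq: str, min_run: int = 8, max_mismatch: int = 1) -> bool:
    """True iff the terminal ``min_run`` bases are A apart from ``max_mismatch``."""
    tail = est_3p_seq[-min_run:]
    if len(tail) < min_run:
        return False
    return tail.count("A") >= min_run - max_mismatch


def apa_contingency_test(
    n_apa_short: int, n_apa_long: int, n_non_short: int, n_non_long: int
) -> ContingencyResult | None:
    """Test allele-by-length association in a 2x2 table.

    Chi-square (1 df, no continuity correction) when all expected counts
    exceed 5; two-sided Fisher's exact test otherwise.  Tables with an empty
    margin carry no information and return None.
    """
    table = np.array([[n_apa_short, n_apa_long], [n_non_short, n_non_long]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return None
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected > 5).all():
        stat = ((table - expected) ** 2 / expected).sum()
        p = float(stats.chi2.sf(stat, df=1))
        return ContingencyResult(table, "chi-square", p)
    _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    return ContingencyResult(table, "fisher", float(p))


def _tabulate(observations, focal_snp, apa_allele, apa_site_pos, half_width,
              include_imputed):
    n = np.zeros((2, 2), dtype=int)
    for obs in observations:
        allele = obs.called_alleles.get(focal_snp)
        if allele is None or (obs.imputed and not include_imputed):
            continue
        length = classify_est_length(obs.end_pos, apa_site_pos, half_width)
        if length == "excluded":
            continue
        row = 0 if allele == apa_allele else 1
        col = 0 if length == "short" else 1
        n[row, col] += 1
    return n


def run_est_stage(
    gene_observations: dict[str, list[EstObservation]],
    gene_focal_snp: dict[str, str],
    gene_apa_allele: dict[str, str],
    gene_site_pos: dict[str, int],
    half_width: int = 30,
) -> pd.DataFrame:
    """Per-gene allele/length association with and without imputed alleles.

    Returns a DataFrame with raw p-values for each mode and their
    Benjamini-Hochberg adjusted versions across genes.
    """
    rows = []
    for gene_id, observations in gene_observations.items():
        focal = gene_focal_snp[gene_id]
        apa = gene_apa_allele[gene_id]
        site = gene_site_pos[gene_id]
        res_direct = apa_contingency_test(
            *_tabulate(observations, focal, apa, site, half_width, False).ravel()
        )
        res_imputed = apa_contingency_test(
            *_tabulate(observations, focal, apa, site, half_width, True).ravel()
        )
        rows.append(
            dict(
                gene_id=gene_id,
                p_no_imputation=res_direct.p_value if res_direct else np.nan,
                test_no_imputation=res_direct.test_used if res_direct else "",
                p_imputation=res_imputed.p_value if res_imputed else np.nan,
                test_imputation=res_imputed.test_used if res_imputed else "",
            )
        )
    df = pd.DataFrame(rows)
    for col in ("p_no_imputation", "p_imputation"):
        adj = np.full(len(df), np.nan)
        ok = df[col].notna().to_numpy()
        if ok.any():
            adj[ok] = correct_multiple(df.loc[ok, col].to_numpy(), method="bh")
        df[col.replace("p_", "q_bh_")] = adj
    return df
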