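"""Statistical battery shared by the association stages.

Plain wrappers around scipy/statsmodels primitives plus the package's own
composites: incremental (semipartial) R-squared reports, residualisation on
a confounder, percentile bootstrap of median differences, the per-SNP
genotype-expression scan, and multiple-testing corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm


@dataclass
class RegressionReport:
    coefficients: pd.DataFrame      # index: variable, columns: coef, p_value
    total_r2: float
    partial_r2: dict[str, float]    # incremental R^2 of each variable
    n: int
    collinear: bool = False


@dataclass
class BootstrapCI:
    statistic: float                # observed median difference (a - b)
    n_boot: int
    ci_low: float
    ci_high: float
    seed: int


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r, two-sided p, and n; (nan, nan, n) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def spearman(x, y) -> tuple[float, float, int]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    r, p = stats.spearmanr(x, y)
    return float(r), float(p), n


def group_compare(values, labels) -> dict[str, float]:
    """Two-sided Student t and Wilcoxon rank-sum p for a two-group split."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"group_compare needs exactly 2 groups, got {len(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t_p = float(stats.ttest_ind(a, b).pvalue)
    w_p = float(stats.ranksums(a, b).pvalue)
    return {"t_p": t_p, "wilcoxon_p": w_p, "mean_diff": float(a.mean() - b.mean())}


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(model.rsquared)


def regression_partial_r2(y, predictors: dict[str, np.ndarray]) -> RegressionReport:
    """OLS fit with incremental R-squared per predictor.

    The partial R^2 of variable v is R^2(full) - R^2(full without v): the
    variance uniquely explained by v on top of the other predictors.
    """
    y = np.asarray(y, dtype=float)
    names = list(predictors)
    X = np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
    full = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    total_r2 = float(full.rsquared)
    collinear = np.linalg.matrix_rank(X) < X.shape[1]
    partial = {}
    for i, name in enumerate(names):
        reduced = np.delete(X, i, axis=1)
        r2_without = _ols_r2(y, reduced) if reduced.shape[1] else 0.0
        partial[name] = total_r2 - r2_without
    coef = pd.DataFrame(
        {
            "coef": full.params[1:],
            "p_value": full.pvalues[1:],
        },
        index=names,
    )
    return RegressionReport(coef, total_r2, partial, len(y), collinear)


def residualize(y, x) -> np.ndarray:
    """Residuals of OLS y ~ 1 + x; centres y when x is constant."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return y - y.mean()
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return np.asarray(model.resid)


def bootstrap_median_diff(a, b, n_boot: int = 1000, seed: int = 0) -> BootstrapCI:
    """Percentile bootstrap 95% CI of median(a) - median(b).

    Each group is resampled with replacement at its own original size.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, len(a), size=(n_boot, len(a)))
    idx_b = rng.integers(0, len(b), size=(n_boot, len(b)))
    diffs = np.median(a[idx_a], axis=1) - np.median(b[idx_b], axis=1)
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapCI(
        statistic=float(np.median(a) - np.median(b)),
        n_boot=n_boot,
        ci_low=float(lo),
        ci_high=float(hi),
        seed=seed,
    )


def correct_multiple(pvals, method: str = "bh") -> np.ndarray:
    """BH step-up or Bonferroni adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if method.lower() in ("bh", "fdr_bh", "benjamini-hochberg"):
        return multipletests(pvals, method="fdr_bh")[1]
    if method.lower() == "bonferroni":
        return np.minimum(pvals * pvals.size, 1.0)
    raise ValueError(f"unknown correction method {method!r}")


def probe_select(probe_matrix: pd.DataFrame) -> str:
    """Pick the probe (row) with maximum variance across individuals.

    Ties break to the lexicographically first probe id.
    """
    variances = probe_matrix.var(axis=1, ddof=1)
    best = variances.max()
    winners = sorted(variances.index[variances == best])
    return str(winners[0])


def expression_filter(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop genes whose maximum expression is below the overall median.

    Removes genes that are essentially unexpressed in every individual
    before the per-SNP genotype-expression scan.
    """
    overall_median = float(np.median(expr.to_numpy()))
    keep = expr.max(axis=1) >= overall_median
    return expr.loc[keep]


def genotype_expression_scan(
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    snp_gene: dict[str, str],
    method: str = "pearson",
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Per-SNP correlation of APA-allele dosage (0/1/2) with gene expression.

    ``genotypes``: rows = SNP ids, columns = individuals, values 0/1/2
    (APA-allele copies).  ``expression``: rows = gene ids, columns matching
    individuals.  Monomorphic SNPs are skipped.  Returns estimates with BH
    and Bonferroni adjusted p-values.
    """
    corr = pearson if method == "pearson" else spearman
    expr = expression_filter(expression) if apply_filter else expression
    rows = []
    for snp_id, geno in genotypes.iterrows():
        gene = snp_gene.get(snp_id)
        if gene is None or gene not in expr.index:
            continue
        g = geno.to_numpy(dtype=float)
        e = expr.loc[gene, genotypes.columns].to_numpy(dtype=float)
        if np.ptp(g[~np.isnan(g)]) == 0:
            continue
        r, p, n = corr(g, e)
        rows.append(dict(snp_id=snp_id, gene_id=gene, estimate=r, p=p, n=n))
    df = pd.DataFrame(rows)
    if len(df):
        df["q_bh"] = correct_multiple(df["p"].to_numpy(), "bh")
        df["q_bonf"] = correct_multiple(df["p"].to_numpy(), "bonferroni")
    return df


def snp_expression_split(
    records: pd.DataFrame,
    group_cols: list[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median log SNP-expression difference, positive vs negative imbalance.

    ``records`` needs columns ``corrected_ai`` and ``log_expression`` (log of
    the summed APA + non-APA allele weights) plus the stratification columns
    in ``group_cols`` (e.g. gu_rich, strength_class, mirna_class).  Within
    each stratum, records with positive corrected imbalance are compared to
    those with negative imbalance by a bootstrap CI on the median
    difference.  Strata with an empty side are reported as missing.
    """
    rows = []
    for i, (key, grp) in enumerate(records.groupby(group_cols, dropna=False)):
        key = key if isinstance(key, tuple) else (key,)
        pos = grp.loc[grp["corrected_ai"] > 0, "log_expression"].to_numpy()
        neg = grp.loc[grp["corrected_ai"] < 0, "log_expression"].to_numpy()
        base = dict(zip(group_cols, key))
        base.update(n_pos=len(pos), n_neg=len(neg))
        if len(pos) == 0 or len(neg) == 0:
            base.update(median_diff=np.nan, ci_low=np.nan, ci_high=np.nan)
        else:
            ci = bootstrap_median_diff(pos, neg, n_boot=n_boot, seed=seed + i)
            base.update(median_diff=ci.statistic, ci_low=ci.ci_low, ci_high=ci.ci_high)
        rows.append(base)
    return pd.DataFrame(rows)
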