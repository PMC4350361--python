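"""Count normalization, the centered log2FC heatmap matrix, and differential
expression with fold-change / p-value thresholds.

The DE caller is a self-contained negative-binomial exact test: per-sample
counts are equalized to a common library size, a single common dispersion is
estimated across genes by method of moments, and each gene's between-
condition split is tested by conditioning on the total of the equalized
counts (the sum of n iid NB(mu, phi) variables is NB(n*mu, phi/n)).  This
preserves the count nature and threshold semantics of an edgeR-style exact
test without its empirical-Bayes dispersion machinery.  Externally produced
DE tables (gene, log2FC, p) can be substituted downstream wherever a DE
result is consumed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import HIGH_MYC, LOW_MYC, CountMatrix, TSSOccupancy

DE_COLUMNS = ["cpm_high", "cpm_low", "log2fc", "p_value", "fdr", "significant", "direction"]


def cpm(counts: CountMatrix | pd.DataFrame, pseudocount: float = 0.5,
        lib_sizes: Sequence[float] | None = None) -> pd.DataFrame:
    """Counts-per-million with a log2 companion.

    Returns a DataFrame of CPM values (columns sum to 1e6); the matching
    log2(CPM + pseudocount) table is available via :func:`log2cpm`.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = np.asarray(lib_sizes, dtype=float) if lib_sizes is not None else df.sum(axis=0).to_numpy(dtype=float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample(s) with zero total count: {[df.columns[i] for i in zero]}")
    return df * (1e6 / totals)


def log2cpm(counts: CountMatrix | pd.DataFrame, pseudocount: float = 0.5,
            lib_sizes: Sequence[float] | None = None) -> pd.DataFrame:
    return np.log2(cpm(counts, lib_sizes=lib_sizes) + pseudocount)


def filter_low(counts: CountMatrix, min_count: int = 5) -> CountMatrix:
    """Drop genes with fewer than ``min_count`` reads in their lowest sample."""
    keep = counts.counts.min(axis=1) >= min_count
    return CountMatrix(counts.counts.loc[keep], list(counts.samples))


def center_log2fc(log2cpm_table: pd.DataFrame) -> pd.DataFrame:
    """Row-center log2CPM: subtract each gene's mean across samples.

    The resulting per-sample values are the displayed fold changes of the
    expression heatmap; every row sums to zero by construction.
    """
    if log2cpm_table.shape[1] < 1:
        raise ValueError("need at least one sample")
    return log2cpm_table.sub(log2cpm_table.mean(axis=1), axis=0)


def heatmap_matrix(counts: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log2FC matrix ordered by change in expression (most
    upregulated first), the layout of the expression heatmap."""
    centered = center_log2fc(log2cpm(counts, pseudocount))
    high = [s.name for s in counts.samples if s.condition == HIGH_MYC]
    low = [s.name for s in counts.samples if s.condition == LOW_MYC]
    order = (centered[high].mean(axis=1) - centered[low].mean(axis=1)).sort_values(ascending=False)
    return centered.loc[order.index]


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _equalize(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Scale each sample's counts to the geometric-mean library size."""
    ref = np.exp(np.mean(np.log(lib_sizes)))
    return np.rint(counts * (ref / lib_sizes)).astype(np.int64)


def estimate_common_dispersion(counts: np.ndarray, groups: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion on equalized counts.

    Uses E[s^2] = mu + phi * mu^2 within each condition; the pooled estimate
    is a ratio of sums over genes and conditions, clipped at zero.
    """
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        sub = counts[:, groups == g].astype(float)
        n = sub.shape[1]
        if n < 2:
            continue
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        num += float(np.sum(s2 - m))
        den += float(np.sum(m ** 2))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def _nb_exact_pvalue(sa: int, sb: int, na: int, nb: int, phi: float) -> float:
    """Exact two-sided p for an A/B split of equalized NB counts.

    Conditions on s = sa + sb; sums all splits whose joint probability does
    not exceed the observed one.  phi is the per-observation dispersion.
    """
    s = sa + sb
    if s == 0:
        return 1.0
    a = np.arange(s + 1)
    mu = s / (na + nb)
    if phi < 1e-10:
        # Poisson limit: conditional distribution is binomial
        probs = stats.binom.pmf(a, s, na / (na + nb))
    else:
        size_a, size_b = na / phi, nb / phi
        mean_a, mean_b = na * mu, nb * mu
        pa = stats.nbinom.pmf(a, size_a, size_a / (size_a + mean_a))
        pb = stats.nbinom.pmf(s - a, size_b, size_b / (size_b + mean_b))
        probs = pa * pb
        tot = probs.sum()
        if tot <= 0:
            return 1.0
        probs = probs / tot
    p_obs = probs[sa]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def call_de(counts: CountMatrix, fc_threshold: float = 2.0, p_threshold: float = 1e-3,
            pseudocount: float = 0.5, lib_sizes: Sequence[float] | None = None,
            dispersion: float | None = None) -> pd.DataFrame:
    """Differential expression, high vs low MYC.

    Returns a DataFrame indexed by gene with cpm_high, cpm_low, log2fc (on
    condition-mean CPM with a pseudocount), raw p_value, BH fdr (reported,
    not thresholded), significant (|fold| > fc_threshold and
    p < p_threshold, both on the raw scale) and direction (up/down/none).
    """
    conditions = {s.condition for s in counts.samples}
    if conditions != {HIGH_MYC, LOW_MYC}:
        raise ValueError(f"need both MYC conditions, got {sorted(conditions)}")
    libs = {s.library for s in counts.samples}
    if len(libs) > 1:
        raise ValueError(f"mixed library preps in DE input: {sorted(libs)}")
    lines = {s.cell_line for s in counts.samples}
    if len(lines) > 1:
        raise ValueError(f"mixed cell lines in DE input: {sorted(lines)}")
    is_high = np.array([s.condition == HIGH_MYC for s in counts.samples])
    if is_high.sum() < 2 or (~is_high).sum() < 2:
        raise ValueError("need >=2 replicates per condition")

    raw = counts.counts.to_numpy()
    col_sums = raw.sum(axis=0).astype(float)
    if lib_sizes is not None:
        totals = np.asarray(lib_sizes, dtype=float)
        if (totals <= 0).any():
            raise ValueError("library sizes must be positive")
        # lib_sizes act as relative size factors: only their ratios matter,
        # anchored to the data's geometric-mean depth so that a global
        # rescaling of the vector leaves every result unchanged
        totals = totals / np.exp(np.mean(np.log(totals))) * np.exp(np.mean(np.log(col_sums)))
    else:
        if (col_sums <= 0).any():
            raise ValueError("library sizes must be positive")
        totals = col_sums
    eq = _equalize(raw, totals)

    if dispersion is None:
        dispersion = estimate_common_dispersion(eq, is_high.astype(int))

    na, nb = int(is_high.sum()), int((~is_high).sum())
    sa = eq[:, is_high].sum(axis=1)
    sb = eq[:, ~is_high].sum(axis=1)
    pvals = np.array([_nb_exact_pvalue(int(a), int(b), na, nb, dispersion)
                      for a, b in zip(sa, sb)])

    cpm_tab = cpm(counts.counts, lib_sizes=totals)
    cpm_high = cpm_tab.loc[:, is_high].mean(axis=1)
    cpm_low = cpm_tab.loc[:, ~is_high].mean(axis=1)
    log2fc = np.log2((cpm_high + pseudocount) / (cpm_low + pseudocount))

    fold = np.exp2(np.abs(log2fc))
    significant = (fold > fc_threshold) & (pvals < p_threshold)
    direction = np.where(~significant, "none", np.where(log2fc > 0, "up", "down"))

    return pd.DataFrame(
        dict(cpm_high=cpm_high, cpm_low=cpm_low, log2fc=log2fc, p_value=pvals,
             fdr=bh_fdr(pvals), significant=significant, direction=direction),
        index=counts.counts.index.copy(),
    )


def expressed_genes(counts: CountMatrix, condition: str | None = None,
                    min_count: int = 5) -> set[str]:
    """Genes detected in a condition: every replicate has >= min_count reads.

    With ``condition=None`` the rule is applied across all samples.
    """
    sub = counts if condition is None else counts.select(condition=condition)
    if not sub.samples:
        return set()
    keep = sub.counts.min(axis=1) >= min_count
    return set(sub.counts.index[keep])


def select_validation_candidates(de: pd.DataFrame, counts: CountMatrix,
                                 occupancy: Sequence[TSSOccupancy],
                                 fc_threshold: float = 8.0,
                                 min_reads: int = 5,
                                 window: int = 500) -> list[str]:
    """Machine-checkable validation-candidate filter.

    Keeps genes that are (1) significantly upregulated more than
    ``fc_threshold``-fold, (2) detected with more than ``min_reads`` reads in
    every sample (strict >), and (3) MYC-bound within ``window`` bp of the
    TSS.  The supplied occupancy must have been computed at that window.
    """
    occ_by_gene = {}
    for o in occupancy:
        if o.window != window:
            raise ValueError(f"occupancy computed at window {o.window}, expected {window}")
        occ_by_gene[o.gene_id] = o
    min_per_gene = counts.counts.min(axis=1)
    out = []
    for gene in de.index:
        row = de.loc[gene]
        if not (bool(row["significant"]) and row["direction"] == "up"
                and np.exp2(row["log2fc"]) > fc_threshold):
            continue
        if gene not in min_per_gene.index or min_per_gene[gene] <= min_reads:
            continue
        occ = occ_by_gene.get(gene)
        if occ is None or not occ.bound:
            continue
        out.append(gene)
    return out
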