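"""Allelic and non-allelic methylation-expression correlation.

Allelic mode pairs, within each sample and haplotype, the allelic
methylation fraction with the allelic expression fraction of a gene
whose TSS lies within 50 kb of the CpG -- each sample can contribute up
to two data points, one per haplotype.  Non-allelic mode correlates the
per-sample total methylation fraction with library-size scaled,
quantile-normalised, asinh-transformed gene counts.  Both use Pearson
correlation with the two-sided t-test, requiring at least three
complete sample pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .phased_data import cpg_id

TSS_WINDOW = 50_000
MIN_SAMPLES = 3


def allelic_methylation(meth: int, unmeth: int) -> float | None:
    """Methylated fraction of phased reads on one allele.

    None (pair skipped) at zero depth.
    """
    total = meth + unmeth
    if total == 0:
        return None
    return meth / total


def allelic_expression(reads_a: int, reads_b: int) -> float | None:
    """Allele-A fraction of haplotype-resolved RNA reads; B is 1 - A."""
    total = reads_a + reads_b
    if total == 0:
        return None
    return reads_a / total


def quantile_normalise(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise a samples x genes matrix.

    Each sample's values are replaced by the across-sample mean of the
    order statistics at the same rank; ties take the mean of the
    reference values they span.  A single sample is returned unchanged.
    """
    if matrix.shape[0] <= 1:
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    sorted_vals = np.sort(values, axis=1)
    reference = sorted_vals.mean(axis=0)
    ranks = matrix.rank(axis=1, method="average").to_numpy() - 1.0
    lo = np.floor(ranks).astype(int)
    hi = np.ceil(ranks).astype(int)
    out = (reference[lo] + reference[hi]) / 2.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def non_allelic_expression(expression: pd.DataFrame) -> pd.DataFrame:
    """asinh(quantile-normalised(gene reads / sample library reads)).

    ``expression`` is the tidy table with gene_id, sample, total_reads,
    library_reads; returns a samples x genes matrix.
    """
    df = expression.copy()
    df["value"] = df["total_reads"] / df["library_reads"]
    mat = df.pivot_table(index="sample", columns="gene_id", values="value")
    return np.arcsinh(quantile_normalise(mat))


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Pearson R and two-sided p (t, n-2 df); None if either side is
    constant or fewer than three pairs remain."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < MIN_SAMPLES or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _pair_cpgs_genes(cpgs: pd.DataFrame, genes: pd.DataFrame,
                     window: int) -> pd.DataFrame:
    """CpG-gene pairs with |TSS - CpG| <= window on the same chromosome."""
    out = []
    for chrom, sub in cpgs.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        for row in sub.itertuples():
            near = g[(g["tss"] - row.pos).abs() <= window]
            for grow in near.itertuples():
                out.append((cpg_id(str(chrom), row.pos), row.pos,
                            grow.gene_id, grow.tss))
    return pd.DataFrame(out, columns=["cpg_id", "pos", "gene_id", "tss"])


def allelic_correlations(phased: pd.DataFrame, expression: pd.DataFrame,
                         window: int = TSS_WINDOW) -> pd.DataFrame:
    """Per CpG-gene Pearson correlation of allelic methylation vs
    allelic expression fractions.

    Haplotype labels A/B are assumed phase-consistent between the two
    tables (both resolved onto the sample's phased haplotypes); each
    sample contributes one point per haplotype.  Records with zero
    allelic depth on either side are skipped.
    """
    meth = phased.copy()
    meth["cpg_id"] = cpg_id(meth["chrom"], meth["pos"])
    cpgs = meth[["chrom", "pos"]].drop_duplicates()
    gene_sites = expression[["gene_id", "chrom", "tss"]].drop_duplicates()
    pairs = _pair_cpgs_genes(cpgs, gene_sites, window)
    expr = expression.set_index(["gene_id", "sample"])
    rows = []
    for pair in pairs.itertuples():
        m = meth[meth["cpg_id"] == pair.cpg_id]
        xs, ys = [], []
        for rec in m.itertuples():
            try:
                e = expr.loc[(pair.gene_id, rec.sample)]
            except KeyError:
                continue
            ea = allelic_expression(int(e["readsA"]), int(e["readsB"]))
            if ea is None:
                continue
            for meth_c, unmeth_c, efrac in (
                    (rec.methA, rec.unmethA, ea),
                    (rec.methB, rec.unmethB, 1.0 - ea)):
                mfrac = allelic_methylation(int(meth_c), int(unmeth_c))
                if mfrac is None:
                    continue
                xs.append(mfrac)
                ys.append(efrac)
        result = pearson(np.array(xs), np.array(ys)) if xs else None
        if result is None:
            continue
        r, p = result
        rows.append((pair.cpg_id, pair.gene_id, "allelic", len(xs), r, p))
    return pd.DataFrame(rows, columns=["cpg_id", "gene_id", "mode",
                                       "n", "r", "p"])


def non_allelic_correlations(totals: pd.DataFrame, expression: pd.DataFrame,
                             window: int = TSS_WINDOW,
                             min_depth: int = 5) -> pd.DataFrame:
    """Per CpG-gene Pearson correlation of total methylation fraction vs
    normalised total expression across samples."""
    df = totals.copy()
    df["cpg_id"] = cpg_id(df["chrom"], df["pos"])
    depth = df["meth"] + df["unmeth"]
    df["frac"] = np.where(depth >= min_depth,
                          df["meth"] / depth.where(depth > 0), np.nan)
    meth_mat = df.pivot_table(index="sample", columns="cpg_id",
                              values="frac", dropna=False)
    expr_mat = non_allelic_expression(expression)
    common = meth_mat.index.intersection(expr_mat.index)
    meth_mat, expr_mat = meth_mat.loc[common], expr_mat.loc[common]
    cpgs = df[["chrom", "pos"]].drop_duplicates()
    gene_sites = expression[["gene_id", "chrom", "tss"]].drop_duplicates()
    pairs = _pair_cpgs_genes(cpgs, gene_sites, window)
    rows = []
    for pair in pairs.itertuples():
        if pair.cpg_id not in meth_mat.columns \
                or pair.gene_id not in expr_mat.columns:
            continue
        x = meth_mat[pair.cpg_id].to_numpy()
        y = expr_mat[pair.gene_id].to_numpy()
        result = pearson(x, y)
        if result is None:
            continue
        r, p = result
        n = int((~(np.isnan(x) | np.isnan(y))).sum())
        rows.append((pair.cpg_id, pair.gene_id, "non-allelic", n, r, p))
    return pd.DataFrame(rows, columns=["cpg_id", "gene_id", "mode",
                                       "n", "r", "p"])


def compare_correlation_sets(allelic: pd.DataFrame,
                             nonallelic: pd.DataFrame,
                             alpha: float = 0.05) -> dict:
    """Summary comparison of the two correlation modes.

    Returns median |R| per mode, the two-sample KS statistic (and p) on
    |R|, and the sign-concordance Pearson R between modes over CpG-gene
    tests significant (p < alpha) in both.
    """
    if len(allelic) == 0 or len(nonallelic) == 0:
        raise ValueError("both correlation sets must be non-empty")
    abs_a = allelic["r"].abs().to_numpy()
    abs_n = nonallelic["r"].abs().to_numpy()
    ks = stats.ks_2samp(abs_a, abs_n)
    merged = allelic.merge(nonallelic, on=["cpg_id", "gene_id"],
                           suffixes=("_allelic", "_nonallelic"))
    both_sig = merged[(merged["p_allelic"] < alpha)
                      & (merged["p_nonallelic"] < alpha)]
    concordance = pearson(both_sig["r_allelic"].to_numpy(),
                          both_sig["r_nonallelic"].to_numpy())
    return {
        "median_abs_r_allelic": float(np.median(abs_a)),
        "median_abs_r_nonallelic": float(np.median(abs_n)),
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "n_both_significant": int(len(both_sig)),
        "sign_concordance_r": None if concordance is None else concordance[0],
    }
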