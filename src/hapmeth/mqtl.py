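"""Non-allelic cis methylation-QTL mapping.

The response is the per-sample total methylation fraction at a CpG
(both alleles combined); the predictor is the additive genotype dose
(0/1/2) of each SNP within the cis window.  The association is an
ordinary least-squares fit per pair with the t-test on the slope,
the model behind default matrix-eQTL-style QTL scans.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .classify import bh_fdr
from .phased_data import HaplotypeMatrix, cpg_id

CIS_WINDOW = 250_000
MIN_MAF = 0.05


def maf_filter(haplotypes: HaplotypeMatrix,
               min_maf: float = MIN_MAF) -> np.ndarray:
    """Indices of SNPs with minor allele frequency >= ``min_maf``.

    Monomorphic SNPs (MAF 0) are always dropped.
    """
    maf = haplotypes.maf()
    return np.flatnonzero((maf >= min_maf) & (maf > 0.0))


def cis_pairs(cpgs: pd.DataFrame, haplotypes: HaplotypeMatrix,
              window: int = CIS_WINDOW,
              snp_subset: np.ndarray | None = None) -> pd.DataFrame:
    """All CpG-SNP pairs with |SNP pos - CpG pos| <= window, same chrom."""
    snp_idx = (np.arange(haplotypes.n_snps) if snp_subset is None
               else np.asarray(snp_subset))
    out = []
    for chrom, sub in cpgs.groupby("chrom", sort=False):
        on_chrom = snp_idx[haplotypes.chroms[snp_idx] == chrom]
        pos = haplotypes.positions[on_chrom]
        order = np.argsort(pos)
        on_chrom, pos = on_chrom[order], pos[order]
        for p in sub["pos"].to_numpy():
            lo = np.searchsorted(pos, p - window, side="left")
            hi = np.searchsorted(pos, p + window, side="right")
            for j in range(lo, hi):
                k = int(on_chrom[j])
                out.append((cpg_id(str(chrom), p), chrom, int(p),
                            haplotypes.snp_ids[k], k,
                            int(abs(int(pos[j]) - p))))
    return pd.DataFrame(out, columns=["cpg_id", "chrom", "pos", "snp_id",
                                      "snp_index", "distance"])


def mqtl_fit(dose: np.ndarray, meth: np.ndarray
             ) -> tuple[float, float, float] | None:
    """OLS fit meth = a + b * dose; returns (slope, se, p).

    Requires >= 3 complete samples and a non-constant dose; a constant
    response gives slope 0, p 1 by convention.  p is two-sided from the
    t-distribution with n - 2 degrees of freedom.
    """
    dose = np.asarray(dose, dtype=float)
    meth = np.asarray(meth, dtype=float)
    ok = ~(np.isnan(dose) | np.isnan(meth))
    dose, meth = dose[ok], meth[ok]
    n = len(dose)
    if n < 3 or np.ptp(dose) == 0.0:
        return None
    if np.ptp(meth) == 0.0:
        return 0.0, 0.0, 1.0
    xc = dose - dose.mean()
    yc = meth - meth.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    sigma2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(sigma2 / sxx))
    if se == 0.0:
        return slope, 0.0, 0.0 if slope != 0 else 1.0
    t = slope / se
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return slope, se, min(p, 1.0)


def methylation_fractions(totals: pd.DataFrame,
                          min_depth: int = 5) -> pd.DataFrame:
    """Pivot total counts to a CpG x sample fraction matrix.

    Sites with fewer than ``min_depth`` total reads in a sample are
    missing for that sample (mirrors the 5x site coverage rule).
    """
    df = totals.copy()
    df["cpg_id"] = cpg_id(df["chrom"], df["pos"])
    depth = df["meth"] + df["unmeth"]
    df["frac"] = np.where(depth >= min_depth, df["meth"] / depth.where(depth > 0),
                          np.nan)
    return df.pivot_table(index="cpg_id", columns="sample", values="frac",
                          dropna=False)


def run_mqtl(totals: pd.DataFrame, haplotypes: HaplotypeMatrix,
             window: int = CIS_WINDOW, min_maf: float = MIN_MAF,
             min_depth: int = 5) -> pd.DataFrame:
    """Scan all cis CpG-SNP pairs; BH q across every test performed.

    Returns one row per tested pair: cpg_id, snp_id, distance, slope,
    se, p, q.
    """
    keep = maf_filter(haplotypes, min_maf)
    sites = totals[["chrom", "pos"]].drop_duplicates()
    pairs = cis_pairs(sites, haplotypes, window, keep)
    if len(pairs) == 0:
        return pd.DataFrame(columns=["cpg_id", "snp_id", "distance",
                                     "slope", "se", "p", "q"])
    frac = methylation_fractions(totals, min_depth)
    frac = frac.reindex(columns=haplotypes.samples)
    dose = haplotypes.dose()  # (n_samples, n_snps)
    rows = []
    for cid, grp in pairs.groupby("cpg_id", sort=False):
        if cid not in frac.index:
            continue
        y = frac.loc[cid].to_numpy()
        for row in grp.itertuples():
            fit = mqtl_fit(dose[:, row.snp_index], y)
            if fit is None:
                continue
            slope, se, p = fit
            rows.append((cid, row.snp_id, row.distance, slope, se, p))
    res = pd.DataFrame(rows, columns=["cpg_id", "snp_id", "distance",
                                      "slope", "se", "p"])
    res["q"] = bh_fdr(res["p"].to_numpy()) if len(res) else []
    return res
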