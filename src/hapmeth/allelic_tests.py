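"""Allelic test statistics: pooled ASM, the genotype-independent test
(GIT) with its selection-bias correction, and the allelic-histone (ASH)
binomial test.

The ASM test pools methylated/unmethylated reads across samples by the
reference/alternative allele of the phasing SNP and applies a two-sided
Fisher's exact test, so it only sees allelic differences that track the
genotype.  The GIT instead sorts each sample's two alleles into a
high- and a low-methylation allele before pooling, which also captures
imbalance whose direction is unlinked to any SNP (imprinting, random
monoallelic methylation) -- but the sorting step selects each sample's
maximum and would make a naive Fisher test on the pooled table reject
almost always.  The correction conditions each sample's high-allele
methylated count on its own selection event (high fraction strictly
greater than low, margins fixed) and convolves the per-sample
conditional null distributions; the one-sided p-value is the tail
probability of the pooled high-row methylated count under that
convolution.  For a single contributing sample this reduces to the
conditional tail P(X >= x_obs and table in E) / P(E) on the 2x2 table
(exposed as :func:`git_table_test`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats

from .classify import bh_fdr
from .phased_data import HaplotypeMatrix, cpg_id, depth_mask


# ---------------------------------------------------------------------------
# exact tests on small tables
# ---------------------------------------------------------------------------

def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities at most that of the observed
    table (with the conventional 1e-7 relative slack on the comparison),
    enumerated over the whole support with margins fixed.  Degenerate
    margins give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    x = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = _hypergeom_pmf(x, n, c1, r1)
    p_obs = pmf[np.searchsorted(x, a)]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def ash_binomial_test(reads_a: int, reads_b: int) -> float | None:
    """Two-sided exact binomial test of allelic ChIP balance (p0 = 0.5).

    Returns None when there are no reads (no test possible).
    """
    n = reads_a + reads_b
    if n == 0:
        return None
    return float(stats.binomtest(reads_a, n, 0.5).pvalue)


def allelic_histone_ratio(reads_this: int, reads_other: int) -> float | None:
    """Allelic ratio 0.5 - fraction of ChIP reads on this allele.

    Positive values mean the allele is depleted for the mark; None for a
    zero total (record skipped).
    """
    total = reads_this + reads_other
    if total == 0:
        return None
    return 0.5 - reads_this / total


# ---------------------------------------------------------------------------
# hypergeometric machinery for the GIT
# ---------------------------------------------------------------------------

def _hypergeom_pmf(x: np.ndarray, n_total: int, n_meth: int,
                   n_high: int) -> np.ndarray:
    """pmf of drawing x methylated reads into the high row.

    Computed in log space via gammaln; exact to ~1e-14 relative.
    """
    ln = (special.gammaln(n_high + 1) - special.gammaln(x + 1)
          - special.gammaln(n_high - x + 1)
          + special.gammaln(n_total - n_high + 1)
          - special.gammaln(n_meth - x + 1)
          - special.gammaln(n_total - n_high - (n_meth - x) + 1)
          - special.gammaln(n_total + 1) + special.gammaln(n_meth + 1)
          + special.gammaln(n_total - n_meth + 1))
    return np.exp(ln)


def _support(n_meth: int, n_high: int, n_low: int) -> np.ndarray:
    lo = max(0, n_meth - n_low)
    hi = min(n_meth, n_high)
    return np.arange(lo, hi + 1)


def git_table_test(m_high: int, u_high: int, m_low: int, u_low: int) -> float:
    """Selection-corrected one-sided p on a single sorted 2x2 table.

    With margins fixed, X ~ hypergeometric is the methylated count on
    the high row and E the tables where the high-row methylated fraction
    strictly exceeds the low-row fraction; the corrected p-value is
    P(X >= x_obs and X in E) / P(E), 1 when P(E) = 0 or the margins are
    degenerate.
    """
    n_high, n_low = m_high + u_high, m_low + u_low
    n_meth = m_high + m_low
    n_total = n_high + n_low
    if n_high == 0 or n_low == 0 or n_meth == 0 or n_meth == n_total:
        return 1.0
    x = _support(n_meth, n_high, n_low)
    pmf = _hypergeom_pmf(x, n_total, n_meth, n_high)
    in_e = x * n_low > (n_meth - x) * n_high
    p_e = pmf[in_e].sum()
    if p_e <= 0.0:
        return 1.0
    num = pmf[in_e & (x >= m_high)].sum()
    return float(min(1.0, num / p_e))


def git_sample_null(m_high: int, u_high: int, m_low: int, u_low: int,
                    ) -> tuple[int, np.ndarray] | None:
    """One sample's conditional null for its high-allele methylated count.

    Margins are fixed at the observed per-allele depths and total
    methylated reads.  The distribution is conditioned on the selection
    event actually observed: the strict-inequality set E when the sample
    had a strict high/low winner, the tie set when the two allele
    fractions were equal (the assignment was then a fair coin and
    carries no bias).  Returns (support offset, normalised pmf), or
    None when the sample is uninformative (zero margin or empty event).
    """
    n_high, n_low = m_high + u_high, m_low + u_low
    n_meth = m_high + m_low
    n_total = n_high + n_low
    if n_high == 0 or n_low == 0:
        return None
    x = _support(n_meth, n_high, n_low)
    pmf = _hypergeom_pmf(x, n_total, n_meth, n_high)
    lhs, rhs = x * n_low, (n_meth - x) * n_high
    tie_observed = m_high * n_low == (n_meth - m_high) * n_high
    mask = (lhs == rhs) if tie_observed else (lhs > rhs)
    weight = pmf * mask
    total = weight.sum()
    if total <= 0.0:
        return None
    return int(x[0]), weight / total


def git_test(records: pd.DataFrame) -> tuple[float, float]:
    """Cohort-level GIT on the per-sample high/low sorted counts.

    ``records`` must carry columns m_high, u_high, m_low, u_low (one row
    per sample, already sorted high/low).  Returns ``(corrected_p,
    naive_p)`` where ``naive_p`` is the uncorrected one-sided Fisher
    tail on the pooled table, reported for diagnostics.
    """
    m_h = records["m_high"].to_numpy()
    u_h = records["u_high"].to_numpy()
    m_l = records["m_low"].to_numpy()
    u_l = records["u_low"].to_numpy()
    x_obs = int(m_h.sum())

    # uncorrected one-sided tail on the pooled table
    n_high = int((m_h + u_h).sum())
    n_meth = int(m_h.sum() + m_l.sum())
    n_total = int(n_high + (m_l + u_l).sum())
    if n_high == 0 or n_total == n_high or n_meth in (0, n_total):
        naive = 1.0
    else:
        naive = float(stats.hypergeom.sf(x_obs - 1, n_total, n_meth, n_high))

    dist = np.array([1.0])
    base = 0
    for mh, uh, ml, ul in zip(m_h, u_h, m_l, u_l):
        cond = git_sample_null(int(mh), int(uh), int(ml), int(ul))
        if cond is None:
            x_obs -= int(mh)  # uninformative sample drops out of the statistic
            continue
        lo, weight = cond
        dist = np.convolve(dist, weight)
        base += lo
    idx = x_obs - base
    if idx <= 0:
        return 1.0, naive
    corrected = float(min(1.0, dist[idx:].sum()))
    return corrected, naive


# ---------------------------------------------------------------------------
# pooling and per-sample sorting
# ---------------------------------------------------------------------------

def assign_high_low(records: pd.DataFrame,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Categorise each sample's alleles into high/low methylation.

    The high allele is the one with the greater methylated fraction;
    exact ties are broken by a seeded fair coin and flagged.  Returns
    the input plus columns high_allele ('A'/'B'), tie, and the sorted
    counts m_high/u_high/m_low/u_low.
    """
    out = records.copy()
    depth_a = out["methA"] + out["unmethA"]
    depth_b = out["methB"] + out["unmethB"]
    # compare methA/depthA > methB/depthB via cross-multiplication
    lhs = out["methA"] * depth_b
    rhs = out["methB"] * depth_a
    tie = (lhs == rhs).to_numpy()
    a_high = (lhs > rhs).to_numpy()
    coin = rng.random(len(out)) < 0.5
    a_high = np.where(tie, coin, a_high)
    out["high_allele"] = np.where(a_high, "A", "B")
    out["tie"] = tie
    out["m_high"] = np.where(a_high, out["methA"], out["methB"])
    out["u_high"] = np.where(a_high, out["unmethA"], out["unmethB"])
    out["m_low"] = np.where(a_high, out["methB"], out["methA"])
    out["u_low"] = np.where(a_high, out["unmethB"], out["unmethA"])
    return out


def asm_pool(records: pd.DataFrame,
             haplotypes: HaplotypeMatrix) -> tuple[int, int, int, int] | None:
    """Pool reads across samples by the phasing SNP's ref/alt allele.

    ``records`` holds one CpG-SNP pair (all rows share snp_id).  Samples
    whose genotype at the SNP is missing or not phased-heterozygous are
    excluded.  Returns (meth_ref, unmeth_ref, meth_alt, unmeth_alt) or
    None when no sample contributes.
    """
    if len(records) == 0:
        return None
    j = haplotypes.snp_index(records["snp_id"].iloc[0])
    mr = ur = ma = ua = 0
    contributed = False
    for row in records.itertuples():
        try:
            s = haplotypes.sample_index(row.sample)
        except KeyError:
            continue
        hap_a, hap_b = haplotypes.haps[s, j]
        if hap_a < 0 or hap_b < 0 or hap_a == hap_b:
            continue
        contributed = True
        if hap_a == 0:  # haplotype A carries the reference allele
            mr += row.methA; ur += row.unmethA
            ma += row.methB; ua += row.unmethB
        else:
            mr += row.methB; ur += row.unmethB
            ma += row.methA; ua += row.unmethA
    if not contributed:
        return None
    return int(mr), int(ur), int(ma), int(ua)


def git_pool(sorted_records: pd.DataFrame) -> tuple[int, int, int, int]:
    """Sample-merged counts over high and low methylation alleles."""
    return (int(sorted_records["m_high"].sum()),
            int(sorted_records["u_high"].sum()),
            int(sorted_records["m_low"].sum()),
            int(sorted_records["u_low"].sum()))


# ---------------------------------------------------------------------------
# cohort scans
# ---------------------------------------------------------------------------

def _add_ids(phased: pd.DataFrame) -> pd.DataFrame:
    df = phased.copy()
    df["cpg_id"] = cpg_id(df["chrom"], df["pos"])
    return df


def asm_scan(phased: pd.DataFrame, haplotypes: HaplotypeMatrix,
             min_per_allele: int = 5) -> pd.DataFrame:
    """Pooled ASM test for every CpG-SNP pair in a phased-counts table.

    Records failing the per-allele depth filter contribute nothing.
    Returns one row per pair with the pooled table, two-sided Fisher p,
    and BH q across all emitted tests.
    """
    df = _add_ids(phased)
    df = df.loc[depth_mask(df, min_per_allele)]
    rows = []
    for (cid, snp), grp in df.groupby(["cpg_id", "snp_id"], sort=False):
        pooled = asm_pool(grp, haplotypes)
        if pooled is None:
            continue
        mr, ur, ma, ua = pooled
        p = fisher_two_sided(mr, ur, ma, ua)
        rows.append((cid, snp, len(grp), mr, ur, ma, ua, p))
    res = pd.DataFrame(rows, columns=[
        "cpg_id", "snp_id", "n_samples",
        "meth_ref", "unmeth_ref", "meth_alt", "unmeth_alt", "p"])
    res["q"] = bh_fdr(res["p"].to_numpy()) if len(res) else []
    return res


def git_scan(phased: pd.DataFrame, min_per_allele: int = 5,
             seed: int = 0) -> pd.DataFrame:
    """Selection-corrected GIT for every CpG-SNP pair.

    ``seed`` controls the tie-breaking coin only.  Returns one row per
    pair with the pooled sorted table, corrected one-sided p, the
    uncorrected (naive) one-sided p for reference, and BH q on the
    corrected p-values.
    """
    rng = np.random.default_rng(seed)
    df = _add_ids(phased)
    df = df.loc[depth_mask(df, min_per_allele)]
    if len(df) == 0:
        return pd.DataFrame(columns=[
            "cpg_id", "snp_id", "n_samples", "m_high", "u_high",
            "m_low", "u_low", "p", "naive_p", "q"])
    sorted_df = assign_high_low(df, rng)
    rows = []
    for (cid, snp), grp in sorted_df.groupby(["cpg_id", "snp_id"], sort=False):
        p, naive = git_test(grp)
        mh, uh, ml, ul = git_pool(grp)
        rows.append((cid, snp, len(grp), mh, uh, ml, ul, p, naive))
    res = pd.DataFrame(rows, columns=[
        "cpg_id", "snp_id", "n_samples", "m_high", "u_high", "m_low",
        "u_low", "p", "naive_p"])
    res["q"] = bh_fdr(res["p"].to_numpy())
    return res


def ash_scan(histone: pd.DataFrame) -> pd.DataFrame:
    """Binomial allelic-balance test per SNP x mark (reads pooled over
    samples); BH q within each mark."""
    pooled = histone.groupby(["mark", "snp_id"], sort=False).agg(
        mark_type=("mark_type", "first"),
        readsA=("readsA", "sum"),
        readsB=("readsB", "sum"),
    ).reset_index()
    pooled = pooled[(pooled["readsA"] + pooled["readsB"]) > 0].copy()
    pooled["p"] = [
        ash_binomial_test(int(a), int(b))
        for a, b in zip(pooled["readsA"], pooled["readsB"])
    ]
    pooled["q"] = np.nan
    for mark, grp in pooled.groupby("mark"):
        pooled.loc[grp.index, "q"] = bh_fdr(grp["p"].to_numpy())
    return pooled


def map_histone_to_cpg(histone: pd.DataFrame, cpg_pos: int,
                       phasing_snp: str, snp_positions: pd.DataFrame,
                       mode: str = "GIT", window: int = 500,
                       ) -> tuple[int, int] | None:
    """Aggregate allelic ChIP counts onto a CpG.

    GIT mode sums phase-resolved counts over every SNP within ``window``
    bp of the CpG; ASM mode uses only the CpG's own phasing SNP.
    ``snp_positions`` maps snp_id -> pos.  Returns (readsA, readsB) or
    None when nothing maps.
    """
    if mode not in ("GIT", "ASM"):
        raise ValueError(f"unknown mode: {mode!r}")
    if mode == "ASM":
        sub = histone[histone["snp_id"] == phasing_snp]
    else:
        near = snp_positions.loc[
            (snp_positions["pos"] - cpg_pos).abs() <= window, "snp_id"]
        sub = histone[histone["snp_id"].isin(set(near))]
    if len(sub) == 0:
        return None
    return int(sub["readsA"].sum()), int(sub["readsB"].sum())
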