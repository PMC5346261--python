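"""Region-level procedures: epigenetic CpG clusters, high-confidence
non-genetic windows, and positional allelic methylation around
chromatin-state centers."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .expression_link import pearson

logger = logging.getLogger(__name__)


def top_epigenetic_clusters(class_df: pd.DataFrame, k: int = 500,
                            span: int = 2000, min_size: int = 3,
                            ) -> pd.DataFrame:
    """Cluster the top-k epigenetically controlled CpGs.

    ``class_df`` needs cpg_id, chrom, pos, asm_q, mqtl_q, git_q.  Among
    CpGs with asm_q >= 0.1 and mqtl_q >= 0.1 (missing counts as
    non-significant), the k smallest GIT q (ties broken by position)
    are clustered by single-linkage chaining with a ``span`` gap
    threshold; clusters of >= ``min_size`` members are reported.
    """
    df = class_df.copy()
    asm_q = df["asm_q"].fillna(1.0)
    mqtl_q = df["mqtl_q"].fillna(1.0)
    qual = df[(asm_q >= 0.1) & (mqtl_q >= 0.1) & df["git_q"].notna()]
    if len(qual) < k:
        logger.warning("only %d qualifying CpGs (requested top %d)",
                       len(qual), k)
    top = qual.sort_values(["git_q", "pos"]).head(k)
    top = top.sort_values(["chrom", "pos"])
    clusters = []
    for chrom, sub in top.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        ids = sub["cpg_id"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > span) + 1
        for chunk in np.split(np.arange(len(pos)), breaks):
            if len(chunk) >= min_size:
                clusters.append({
                    "chrom": chrom,
                    "start": int(pos[chunk[0]]),
                    "end": int(pos[chunk[-1]]) + 1,
                    "n_cpgs": len(chunk),
                    "members": list(ids[chunk]),
                })
    return pd.DataFrame(clusters,
                        columns=["chrom", "start", "end", "n_cpgs", "members"])


def high_confidence_windows(class_df: pd.DataFrame, min_cpgs: int = 15,
                            git_q_max: float = 1e-5,
                            median_lnq_max: float = -10.0) -> pd.DataFrame:
    """Maximal runs of consecutive tested CpGs with non-genetic,
    strongly imbalanced methylation.

    Consecutiveness is counted over CpGs tested in all three analyses.
    Every member must have asm_q >= 0.1, mqtl_q >= 0.1 and
    git_q < ``git_q_max``; runs of >= ``min_cpgs`` whose median
    ln(git_q) < ``median_lnq_max`` become windows.
    """
    tested = class_df.dropna(subset=["asm_q", "mqtl_q", "git_q"]) \
        .sort_values(["chrom", "pos"])
    out = []
    for chrom, sub in tested.groupby("chrom", sort=False):
        good = ((sub["asm_q"] >= 0.1) & (sub["mqtl_q"] >= 0.1)
                & (sub["git_q"] < git_q_max)).to_numpy()
        pos = sub["pos"].to_numpy()
        ids = sub["cpg_id"].to_numpy()
        q = sub["git_q"].to_numpy()
        i = 0
        while i < len(good):
            if not good[i]:
                i += 1
                continue
            j = i
            while j < len(good) and good[j]:
                j += 1
            if j - i >= min_cpgs:
                med = float(np.median(np.log(q[i:j])))
                if med < median_lnq_max:
                    out.append({
                        "chrom": chrom, "start": int(pos[i]),
                        "end": int(pos[j - 1]) + 1, "n_cpgs": j - i,
                        "median_ln_git_q": med, "members": list(ids[i:j]),
                    })
            i = j
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_cpgs",
                                      "median_ln_git_q", "members"])


def select_expressed_transcript(transcripts: pd.DataFrame) -> str:
    """Pick the representative isoform of a gene.

    ``transcripts`` needs transcript_id, exonic_reads, gene_reads.
    Argmax by exonic reads; ties broken by gene reads, then by
    lexicographically smallest id (deterministic).
    """
    if len(transcripts) == 0:
        raise ValueError("no transcripts given")
    ordered = transcripts.sort_values(
        ["exonic_reads", "gene_reads", "transcript_id"],
        ascending=[False, False, True], kind="mergesort")
    return str(ordered["transcript_id"].iloc[0])


def select_enhancer_regions(regions: pd.DataFrame, signal: pd.DataFrame,
                            r_min: float = 0.4, p_max: float = 0.05,
                            max_size: int = 10_000) -> pd.DataFrame:
    """Chromatin-state regions whose histone signal tracks expression.

    ``regions`` is BED-like (chrom, start, end, state, region_id);
    ``signal`` is tidy per region and sample with columns region_id,
    sample, peak, expr.  Regions longer than ``max_size`` are excluded
    outright; the rest are kept when Pearson |R| > ``r_min`` and
    p < ``p_max`` between per-sample peak height and expression
    (regions with < 3 samples are skipped).
    """
    size_ok = regions[(regions["end"] - regions["start"]) <= max_size]
    rows = []
    grouped = signal.groupby("region_id")
    for reg in size_ok.itertuples():
        try:
            sub = grouped.get_group(reg.region_id)
        except KeyError:
            continue
        result = pearson(sub["peak"].to_numpy(), sub["expr"].to_numpy())
        if result is None:
            continue
        r, p = result
        if abs(r) > r_min and p < p_max:
            rows.append({**reg._asdict(), "r": r, "p": p})
    out = pd.DataFrame(rows)
    return out.drop(columns=["Index"], errors="ignore")


def positional_bins(regions: pd.DataFrame, cpg_alleles: pd.DataFrame,
                    bin_size: int = 100) -> pd.DataFrame:
    """Per-distance-bin log2 ratio of methylation on high- vs
    low-expression alleles.

    ``regions`` needs region_id and center; ``cpg_alleles`` one row per
    CpG x sample with region_id, pos, meth_high, meth_low (methylation
    fractions phased onto the high/low gene-expression allele).  CpGs
    are grouped by absolute distance from the region center in
    ``bin_size`` increments, pooling across regions; a bin whose
    low-allele mean is zero is flagged undefined (NaN ratio).
    """
    merged = cpg_alleles.merge(regions[["region_id", "center"]],
                               on="region_id")
    merged["bin"] = ((merged["pos"] - merged["center"]).abs()
                     // bin_size).astype(int)
    rows = []
    for b, grp in merged.groupby("bin"):
        high = float(grp["meth_high"].mean())
        low = float(grp["meth_low"].mean())
        if low == 0.0:
            rows.append((b, len(grp), high, low, np.nan, True))
        else:
            rows.append((b, len(grp), high, low,
                         float(np.log2(high / low)) if high > 0 else -np.inf,
                         False))
    return pd.DataFrame(rows, columns=["bin", "n_cpgs", "mean_meth_high",
                                       "mean_meth_low", "log2_ratio",
                                       "undefined"])
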