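"""LD from phased haplotypes, greedy LD pruning, and Fisher enrichment
of disease-associated SNPs among allelically methylated SNPs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Set

import numpy as np
import pandas as pd

from .allelic_tests import fisher_two_sided
from .phased_data import HaplotypeMatrix

R2_PRUNE = 0.1
R2_LINK = 0.8
LD_WINDOW = 250_000
GWAS_P = 1e-5


def ld_r2(hap1: np.ndarray, hap2: np.ndarray) -> float | None:
    """Squared haplotype correlation r2 between two SNPs.

    ``hap1``/``hap2`` are 0/1 vectors over the 2n phased haplotypes
    (missing entries < 0 are dropped pairwise).  None when either SNP
    is monomorphic on the retained haplotypes.
    """
    h1 = np.asarray(hap1).ravel()
    h2 = np.asarray(hap2).ravel()
    ok = (h1 >= 0) & (h2 >= 0)
    h1, h2 = h1[ok].astype(float), h2[ok].astype(float)
    if len(h1) == 0:
        return None
    p1, p2 = h1.mean(), h2.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return None
    p12 = (h1 * h2).mean()
    d = p12 - p1 * p2
    return float(d * d / (p1 * (1 - p1) * p2 * (1 - p2)))


def _hap_vectors(haplotypes: HaplotypeMatrix) -> np.ndarray:
    """(2n, n_snps) matrix of phased haplotypes."""
    return haplotypes.haps.transpose(0, 2, 1).reshape(
        haplotypes.n_samples * 2, haplotypes.n_snps)


def ld_prune(snps: pd.DataFrame, haplotypes: HaplotypeMatrix,
             r2_max: float = R2_PRUNE,
             window: int = LD_WINDOW) -> pd.DataFrame:
    """Greedy clumping to an independent SNP subset.

    ``snps`` needs snp_id and p (association p-value).  SNPs are
    accepted in increasing p order; a candidate is rejected when its r2
    to any already accepted SNP within ``window`` bp is >= ``r2_max``.
    """
    hv = _hap_vectors(haplotypes)
    pos = {s: haplotypes.positions[haplotypes.snp_index(s)]
           for s in snps["snp_id"]}
    chrom = {s: haplotypes.chroms[haplotypes.snp_index(s)]
             for s in snps["snp_id"]}
    accepted: list[str] = []
    for row in snps.sort_values(["p", "snp_id"]).itertuples():
        sid = row.snp_id
        keep = True
        for other in accepted:
            if chrom[other] != chrom[sid] \
                    or abs(int(pos[other]) - int(pos[sid])) > window:
                continue
            r2 = ld_r2(hv[:, haplotypes.snp_index(sid)],
                       hv[:, haplotypes.snp_index(other)])
            if r2 is not None and r2 >= r2_max:
                keep = False
                break
        if keep:
            accepted.append(sid)
    return snps[snps["snp_id"].isin(accepted)].copy()


def asm_snp_set(asm_results: pd.DataFrame, haplotypes: HaplotypeMatrix,
                q_max: float = 0.1, r2_link: float = R2_LINK,
                window: int = LD_WINDOW) -> Set[str]:
    """SNPs with significant ASM, expanded by high-LD proxies.

    ``asm_results`` needs snp_id and q (per-SNP minimum q).  Any SNP in
    the haplotype panel with r2 > ``r2_link`` to a significant SNP
    within ``window`` bp joins the set.
    """
    per_snp = asm_results.groupby("snp_id")["q"].min()
    core = set(per_snp[per_snp < q_max].index)
    hv = _hap_vectors(haplotypes)
    expanded = set(core)
    for sid in core:
        j = haplotypes.snp_index(sid)
        near = np.flatnonzero(
            (haplotypes.chroms == haplotypes.chroms[j])
            & (np.abs(haplotypes.positions - haplotypes.positions[j])
               <= window))
        for k in near:
            other = haplotypes.snp_ids[k]
            if other in expanded:
                continue
            r2 = ld_r2(hv[:, j], hv[:, k])
            if r2 is not None and r2 > r2_link:
                expanded.add(other)
    return expanded


@dataclass
class EnrichmentResult:
    """2x2 enrichment of disease SNPs among allelically methylated loci."""

    disease_in: int
    disease_out: int
    background_in: int
    background_out: int
    odds_ratio: float
    fold: float
    p: float

    @property
    def table(self) -> list[list[int]]:
        return [[self.disease_in, self.disease_out],
                [self.background_in, self.background_out]]


def enrichment_test(disease: Iterable[str], background: Iterable[str],
                    asm_set: Set[str]) -> EnrichmentResult | None:
    """Fisher enrichment of disease-associated SNPs in the ASM set.

    ``disease`` are the pruned disease-associated SNPs, ``background``
    all pruned tested SNPs (a superset); the second table row counts
    background-only SNPs.  Fold is the rate ratio of the two rows; None
    when a margin is empty.
    """
    disease = set(disease)
    bg_only = set(background) - disease
    a = len(disease & asm_set)
    b = len(disease) - a
    c = len(bg_only & asm_set)
    d = len(bg_only) - c
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return None
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    fold = np.inf if c == 0 else (a / (a + b)) / (c / (c + d))
    p = fisher_two_sided(a, b, c, d)
    return EnrichmentResult(a, b, c, d, float(odds), float(fold), p)
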