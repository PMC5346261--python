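"""Core data model for haplotype-resolved bisulfite data.

Conventions used throughout the package:

* Coordinates are 0-based half-open internally.  VCF input (1-based) is
  converted on read; BED output stays 0-based half-open.
* A CpG site is identified by ``"<chrom>:<pos>"`` where ``pos`` is the
  0-based position of the C of the dinucleotide.
* Phased per-CpG read counts are tabular (one row per CpG x sample x
  phasing SNP) with haplotype labels A/B referring to the sample's first
  and second phased haplotype.  Orientation relative to the phasing
  SNP's reference/alternative allele is recovered from the
  :class:`HaplotypeMatrix` when a test needs it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: column order of the phased-counts table
PHASED_COLUMNS = [
    "chrom", "pos", "strand", "context", "sample", "snp_id",
    "methA", "unmethA", "methB", "unmethB",
]

#: column order of the per-sample total (non-allelic) counts table
TOTAL_COLUMNS = ["chrom", "pos", "sample", "meth", "unmeth"]

CPG = "CpG"
CPH = "CpH"

# Base pairs whose bisulfite signal collides with the SNP alleles on one
# strand: a C/T SNP is unreadable on the forward strand (unmethylated C
# reads as T), a G/A SNP on the reverse strand.
_REVERSE_ONLY = frozenset({frozenset({"C", "T"})})
_FORWARD_ONLY = frozenset({frozenset({"G", "A"})})
_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CpGSite:
    """A cytosine in CpG or CpH context.

    ``pos`` is the 0-based coordinate of the C.
    """

    chrom: str
    pos: int
    context: str = CPG
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position: {self.pos}")
        if self.context not in (CPG, CPH):
            raise ValueError(f"unknown context: {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand: {self.strand!r}")

    @property
    def cpg_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


def cpg_id(chrom: Iterable[str] | str, pos) -> pd.Series | str:
    """Build ``chrom:pos`` identifiers (vectorised for pandas inputs)."""
    if isinstance(chrom, str):
        return f"{chrom}:{int(pos)}"
    return pd.Series(chrom).astype(str) + ":" + pd.Series(pos).astype(int).astype(str)


class HaplotypeMatrix:
    """Phased 0/1 alleles for ``n_samples x n_snps`` SNPs.

    ``haps`` has shape ``(n_samples, n_snps, 2)`` holding the two phased
    haplotypes per sample; entry -1 marks a missing/unphased genotype.
    Haplotype 0 is haplotype "A" of the phased-counts table.
    """

    def __init__(
        self,
        samples: Sequence[str],
        snp_ids: Sequence[str],
        chroms: Sequence[str],
        positions: Sequence[int],
        haps: np.ndarray,
        ref: Sequence[str] | None = None,
        alt: Sequence[str] | None = None,
    ) -> None:
        self.samples = list(samples)
        self.snp_ids = list(snp_ids)
        self.chroms = np.asarray(chroms, dtype=object)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.haps = np.asarray(haps, dtype=np.int8)
        n_samples, n_snps = len(self.samples), len(self.snp_ids)
        if self.haps.shape != (n_samples, n_snps, 2):
            raise ValueError(
                f"haps shape {self.haps.shape} != {(n_samples, n_snps, 2)}"
            )
        self.ref = list(ref) if ref is not None else ["A"] * n_snps
        self.alt = list(alt) if alt is not None else ["G"] * n_snps
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._snp_index = {s: i for i, s in enumerate(self.snp_ids)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def sample_index(self, sample: str) -> int:
        return self._sample_index[sample]

    def snp_index(self, snp_id: str) -> int:
        return self._snp_index[snp_id]

    def dose(self) -> np.ndarray:
        """Additive genotype dose (0/1/2); missing entries are NaN."""
        h = self.haps.astype(float)
        h[h < 0] = np.nan
        return h.sum(axis=2)

    def is_het(self) -> np.ndarray:
        """Boolean (n_samples, n_snps): phased heterozygous entries."""
        valid = (self.haps >= 0).all(axis=2)
        return valid & (self.haps[:, :, 0] != self.haps[:, :, 1])

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP over non-missing haplotypes."""
        h = self.haps
        alt = np.where(h >= 0, h, 0).sum(axis=(0, 2)).astype(float)
        n = (h >= 0).sum(axis=(0, 2)).astype(float)
        with np.errstate(invalid="ignore"):
            f = alt / n
        return np.minimum(f, 1.0 - f)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write a haplotype TSV (``pos`` is 0-based; GT as ``0|1``)."""
        gt = np.where(
            (self.haps >= 0).all(axis=2),
            np.char.add(
                np.char.add(self.haps[:, :, 0].astype(str), "|"),
                self.haps[:, :, 1].astype(str),
            ),
            ".|.",
        )
        df = pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chroms, "pos": self.positions,
             "ref": self.ref, "alt": self.alt}
        )
        for i, s in enumerate(self.samples):
            df[s] = gt[i]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HaplotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        meta = ["snp_id", "chrom", "pos", "ref", "alt"]
        samples = [c for c in df.columns if c not in meta]
        haps = np.full((len(samples), len(df), 2), -1, dtype=np.int8)
        for i, s in enumerate(samples):
            gt = df[s].astype(str).str.split("|", expand=True)
            ok = gt[0].isin(["0", "1"]) & gt[1].isin(["0", "1"])
            haps[i, ok.to_numpy(), 0] = gt.loc[ok, 0].astype(np.int8)
            haps[i, ok.to_numpy(), 1] = gt.loc[ok, 1].astype(np.int8)
        return cls(samples, df["snp_id"].astype(str), df["chrom"], df["pos"],
                   haps, df["ref"], df["alt"])

    @classmethod
    def from_vcf(cls, path) -> "HaplotypeMatrix":
        """Read phased genotypes from a VCF via cyvcf2.

        Only biallelic records with phased GT fields are used (unphased
        or missing genotypes become missing entries); 1-based POS is
        converted to the internal 0-based convention.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        snp_ids, chroms, positions, refs, alts, rows = [], [], [], [], [], []
        for variant in vcf:
            if len(variant.ALT) != 1:
                logger.warning("skipping multi-allelic record %s at %s:%d",
                               variant.ID, variant.CHROM, variant.POS)
                continue
            row = np.full((len(samples), 2), -1, dtype=np.int8)
            for i, (a, b, phased) in enumerate(variant.genotypes):
                if phased and a in (0, 1) and b in (0, 1):
                    row[i] = (a, b)
            snp_ids.append(variant.ID
                           or f"{variant.CHROM}:{variant.POS - 1}")
            chroms.append(variant.CHROM)
            positions.append(variant.POS - 1)
            refs.append(variant.REF)
            alts.append(variant.ALT[0])
            rows.append(row)
        haps = (np.stack(rows, axis=1) if rows
                else np.empty((len(samples), 0, 2), dtype=np.int8))
        return cls(samples, snp_ids, chroms, positions, haps, refs, alts)


# ---------------------------------------------------------------------------
# filtering rules
# ---------------------------------------------------------------------------

def select_usable_strand(
    ref: str,
    alt: str,
    forward: tuple[int, int],
    reverse: tuple[int, int],
) -> tuple[int, int] | None:
    """Restrict per-allele counts to the bisulfite-informative strand.

    For a C/T SNP only reverse-strand reads are usable, for a G/A SNP only
    forward-strand reads; any other base pair does not conflict with
    bisulfite conversion and both strands are summed.  ``forward`` and
    ``reverse`` are (methylated, unmethylated) count pairs.  Returns the
    retained pair, or None (with a warning) for an unknown base pair.
    """
    if ref not in _VALID_BASES or alt not in _VALID_BASES:
        logger.warning("unknown SNP base pair %s/%s; record rejected", ref, alt)
        return None
    pair = frozenset({ref, alt})
    if pair in _REVERSE_ONLY:
        return tuple(reverse)
    if pair in _FORWARD_ONLY:
        return tuple(forward)
    return (forward[0] + reverse[0], forward[1] + reverse[1])


def depth_filter(records: pd.DataFrame, min_per_allele: int = 5) -> pd.DataFrame:
    """Keep phased records with >= ``min_per_allele`` reads on each allele."""
    return records.loc[depth_mask(records, min_per_allele)].copy()


def depth_mask(records: pd.DataFrame, min_per_allele: int = 5) -> pd.Series:
    depth_a = records["methA"] + records["unmethA"]
    depth_b = records["methB"] + records["unmethB"]
    return (depth_a >= min_per_allele) & (depth_b >= min_per_allele)


def link_cpg_to_snp(
    cpgs: pd.DataFrame,
    haplotypes: HaplotypeMatrix,
    window: int = 500,
) -> pd.DataFrame:
    """Link each CpG to every usable phasing SNP within ``window`` bp.

    ``cpgs`` needs columns chrom, pos.  A SNP is usable if it is phased
    heterozygous in at least one sample.  Returns one row per CpG-SNP
    pair with columns cpg_id, chrom, pos, snp_id, snp_pos, distance;
    CpGs with no SNP in range appear once with snp_id NA (unphaseable).
    """
    usable = haplotypes.is_het().any(axis=0)
    out = []
    for chrom, sub in cpgs.groupby("chrom", sort=False):
        on_chrom = np.flatnonzero((haplotypes.chroms == chrom) & usable)
        snp_pos = haplotypes.positions[on_chrom]
        order = np.argsort(snp_pos)
        on_chrom, snp_pos = on_chrom[order], snp_pos[order]
        for pos in sub["pos"].to_numpy():
            lo = np.searchsorted(snp_pos, pos - window, side="left")
            hi = np.searchsorted(snp_pos, pos + window, side="right")
            if lo == hi:
                out.append((cpg_id(str(chrom), pos), chrom, pos, None, -1, -1))
                continue
            for j in range(lo, hi):
                k = on_chrom[j]
                out.append((
                    cpg_id(str(chrom), pos), chrom, pos,
                    haplotypes.snp_ids[k], int(snp_pos[j]),
                    int(abs(int(snp_pos[j]) - pos)),
                ))
    return pd.DataFrame(
        out, columns=["cpg_id", "chrom", "pos", "snp_id", "snp_pos", "distance"]
    )


def cph_site_filter(
    site_table: pd.DataFrame,
    snp_positions: pd.DataFrame,
    min_covered: int = 50,
    min_nonzero: int = 25,
) -> pd.DataFrame:
    """Retain CpH sites suitable for allelic testing.

    ``site_table`` is long-format per-site/per-sample counts (chrom, pos,
    strand, sample, meth, unmeth).  A site is kept when it is covered in
    at least ``min_covered`` individuals, at least ``min_nonzero`` of them
    show methylation > 0, and no SNP overlaps the dinucleotide (positions
    pos and pos+1 on +, pos and pos-1 on -).  Returns the retained unique
    sites (chrom, pos, strand).
    """
    covered = site_table[(site_table["meth"] + site_table["unmeth"]) > 0]
    stats = covered.groupby(["chrom", "pos", "strand"]).agg(
        n_covered=("sample", "nunique"),
        n_nonzero=("meth", lambda m: int((m > 0).sum())),
    ).reset_index()
    keep = stats[(stats["n_covered"] >= min_covered)
                 & (stats["n_nonzero"] >= min_nonzero)].copy()
    snp_keys = set(zip(snp_positions["chrom"].astype(str),
                       snp_positions["pos"].astype(int)))
    second = np.where(keep["strand"] == "+", keep["pos"] + 1, keep["pos"] - 1)
    hit = [
        (str(c), int(p)) in snp_keys or (str(c), int(q)) in snp_keys
        for c, p, q in zip(keep["chrom"], keep["pos"], second)
    ]
    return keep.loc[~np.asarray(hit), ["chrom", "pos", "strand"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_phased_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str,
                                            "snp_id": str})
    missing = set(PHASED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phased counts table missing columns: {sorted(missing)}")
    return df


def write_phased_counts(df: pd.DataFrame, path) -> None:
    df.loc[:, PHASED_COLUMNS].to_csv(path, sep="\t", index=False)


def read_total_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})


def write_total_counts(df: pd.DataFrame, path) -> None:
    df.loc[:, TOTAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed_regions(path) -> pd.DataFrame:
    """Read BED3+label chromatin-state regions (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "state"],
                     dtype={"chrom": str})
    df["center"] = (df["start"] + df["end"]) // 2
    return df
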