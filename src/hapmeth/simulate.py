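"""Synthetic phased bisulfite cohorts with known regulatory architecture.

The generator emulates the data structures a phased bisulfite pipeline
produces downstream of alignment: per-sample, per-CpG read counts
resolved to the two haplotypes through a nearby heterozygous phasing
SNP, per-sample total counts, allelically resolved gene expression, and
allelic ChIP read counts at heterozygous SNPs.

Four per-CpG scenarios span the regulatory architectures the tests are
built to separate:

``null``
    both alleles methylate at the baseline rate mu.
``genetic_cis``
    the haplotype carrying the alternative allele of the CpG's own
    phasing SNP methylates at mu + delta/2, the other at mu - delta/2.
``genetic_distal``
    as genetic_cis, but the causal SNP is a different (cis but >500 bp
    away) SNP than the one used for phasing.
``imprinted_like``
    per sample one haplotype is picked uniformly at random - independent
    of genotype - to carry mu + delta/2; the signature of imprinting or
    random monoallelic methylation that a genotype-independent test
    detects and an allele-pooled genetic test cancels out.

Counts are beta-binomial: the per-haplotype methylation rate is drawn
from a Beta with mean equal to the scenario rate and dispersion ``rho``
(rho = 0 degenerates to a plain binomial, recovering the exact-test
null). Per-allele depths are Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .phased_data import HaplotypeMatrix, PHASED_COLUMNS, TOTAL_COLUMNS, cpg_id

SCENARIOS = ("null", "genetic_cis", "genetic_distal", "imprinted_like")

DEFAULT_SCENARIOS: Mapping[str, int] = {
    "null": 500,
    "genetic_cis": 200,
    "genetic_distal": 100,
    "imprinted_like": 100,
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults describe a mid-sized targeted-bisulfite cohort: 100 samples,
    mean 30x per allele, baseline methylation 0.5 with a 0.4 allelic
    effect where one is planted.  Dispersion defaults to 0 so the
    generator's read-sampling null coincides with the binomial null the
    exact tests assume; set ``rho`` > 0 to emulate the between-sample
    overdispersion of real cohorts (under which pooled exact tests are
    anti-conservative).
    """

    n_samples: int = 100
    scenarios: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIOS))
    delta: float = 0.4            # allelic methylation difference
    mu: float = 0.5               # baseline methylation probability
    rho: float = 0.0              # beta-binomial overdispersion, in [0, 1)
    depth: float = 30.0           # mean reads per allele per CpG
    maf: float = 0.3              # minor allele frequency of every SNP
    ld_block: int = 1             # SNPs per LD block
    ld_copy_prob: float = 0.95    # within-block haplotype copy probability
    chrom: str = "chr1"
    start: int = 2000
    spacing: int = 10_000         # distance between consecutive CpGs
    snp_offset: int = 100         # phasing SNP sits this far from its CpG
    distal_offset: int = 5        # causal SNP of distal CpGs, in SNP units
    # expression coupling
    n_genes: int = 100
    expr_slope: float = 4.0       # logit-scale allelic coupling
    expr_intercept: float = 0.0
    expr_total_slope: float = 4.0  # log-scale coupling of total expression
    expr_allelic_depth: float = 50.0
    expr_base_reads: float = 500.0
    expr_dispersion: float = 10.0  # NB shape; larger = closer to Poisson
    library_reads: float = 1e6
    tss_offset: int = 1000
    # histone coupling
    histone_slope: float = 4.0
    histone_depth: float = 30.0
    seed: int = 0
    # explicit layout overrides (fixtures: planted blocks, custom geometry)
    positions: tuple[int, ...] | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            counts: dict[str, int] = {}
            for lab in self.labels:
                counts[lab] = counts.get(lab, 0) + 1
            self.scenarios = counts
        if self.positions is not None \
                and len(self.positions) != self.n_cpgs:
            raise ValueError("positions must match the number of CpGs")
        bad = set(self.scenarios) - set(SCENARIOS)
        if bad:
            raise ValueError(f"unknown scenarios: {sorted(bad)}")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must be a probability")
        lo, hi = self.mu - self.delta / 2, self.mu + self.delta / 2
        if lo < 0.0 or hi > 1.0:
            raise ValueError("mu +/- delta/2 must stay within [0, 1]")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")

    @property
    def n_cpgs(self) -> int:
        return int(sum(self.scenarios.values()))

    def rngs(self, n: int = 5) -> list[np.random.Generator]:
        """Independent RNG streams derived from the master seed."""
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(self.seed).spawn(n)]


def _cpg_positions(config: SimulationConfig) -> np.ndarray:
    if config.positions is not None:
        return np.asarray(config.positions, dtype=np.int64)
    return config.start + config.spacing * np.arange(config.n_cpgs)


def assign_scenarios(config: SimulationConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Ground truth: scenario label, causal SNP, and effect per CpG.

    Scenario counts match the configuration exactly.  Labels are placed
    at shuffled positions so architectures interleave along the
    chromosome, unless ``config.labels`` pins an explicit layout (e.g.,
    a planted contiguous imprinted block).
    """
    if config.labels is not None:
        labels = np.asarray(config.labels, dtype=object)
    else:
        labels = np.concatenate([
            np.repeat(name, count)
            for name, count in config.scenarios.items()
        ])
        rng.shuffle(labels)
    pos = _cpg_positions(config)
    n = config.n_cpgs
    causal = np.arange(n)
    distal = labels == "genetic_distal"
    causal[distal] = (causal[distal] - config.distal_offset) % n
    truth = pd.DataFrame({
        "cpg_id": cpg_id([config.chrom] * n, pos),
        "chrom": config.chrom,
        "pos": pos,
        "scenario": labels,
        "phasing_snp": [f"snp{i}" for i in range(n)],
        "causal_snp": [
            f"snp{c}" if lab in ("genetic_cis", "genetic_distal") else ""
            for c, lab in zip(causal, labels)
        ],
        "delta": np.where(labels == "null", 0.0, config.delta),
    })
    return truth


def simulate_haplotypes(config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> HaplotypeMatrix:
    """Phased haplotypes with block-wise LD.

    Within a block of ``ld_block`` SNPs each haplotype copies its allele
    from the previous SNP with probability ``ld_copy_prob`` and redraws
    from the allele frequency otherwise; blocks are independent.
    """
    if rng is None:
        rng = config.rngs()[0]
    n, m = config.n_samples, config.n_cpgs
    haps = np.empty((n, m, 2), dtype=np.int8)
    freq = config.maf
    for j in range(m):
        if j % config.ld_block == 0:
            haps[:, j, :] = rng.random((n, 2)) < freq
        else:
            redraw = rng.random((n, 2)) >= config.ld_copy_prob
            haps[:, j, :] = np.where(
                redraw, rng.random((n, 2)) < freq, haps[:, j - 1, :])
    pos = _cpg_positions(config) + config.snp_offset
    return HaplotypeMatrix(
        samples=[f"S{i:03d}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(m)],
        chroms=[config.chrom] * m,
        positions=pos,
        haps=haps,
        ref=["A"] * m,
        alt=["G"] * m,
    )


@dataclass
class MethylationTables:
    """Simulated methylation: tidy tables plus dense per-haplotype arrays.

    ``meth``/``depth`` have shape (n_cpgs, n_samples, 2); ``rates`` holds
    the generating per-haplotype methylation probabilities, used by the
    expression and histone simulators as the biological signal.
    """

    phased: pd.DataFrame
    totals: pd.DataFrame
    meth: np.ndarray
    depth: np.ndarray
    rates: np.ndarray


def _beta_binomial(rng: np.random.Generator, depth: np.ndarray,
                   mean: np.ndarray, rho: float) -> np.ndarray:
    if rho == 0.0:
        return rng.binomial(depth, mean)
    conc = (1.0 - rho) / rho
    a = np.clip(mean * conc, 1e-12, None)
    b = np.clip((1.0 - mean) * conc, 1e-12, None)
    p = rng.beta(a, b)
    return rng.binomial(depth, p)


def simulate_methylation(config: SimulationConfig,
                         haplotypes: HaplotypeMatrix,
                         truth: pd.DataFrame,
                         rng: np.random.Generator | None = None,
                         ) -> MethylationTables:
    """Draw per-haplotype read counts for every CpG and sample.

    Phased records are emitted only for samples heterozygous at the
    CpG's phasing SNP (others cannot be resolved to haplotypes); total
    counts are emitted for every sample.  Samples failing the 5-read
    depth filter are retained so downstream filters are exercised.
    """
    if rng is None:
        rng = config.rngs()[1]
    n_cpgs, n_samples = config.n_cpgs, config.n_samples
    half = config.delta / 2.0
    rates = np.full((n_cpgs, n_samples, 2), config.mu)
    scen = truth["scenario"].to_numpy()
    causal_ids = truth["causal_snp"].to_numpy()
    for i in range(n_cpgs):
        if scen[i] in ("genetic_cis", "genetic_distal"):
            j = haplotypes.snp_index(causal_ids[i])
            carries_alt = haplotypes.haps[:, j, :] == 1
            rates[i] = np.where(carries_alt, config.mu + half, config.mu - half)
        elif scen[i] == "imprinted_like":
            pick = rng.integers(0, 2, size=n_samples)
            rates[i, np.arange(n_samples), pick] = config.mu + half
            rates[i, np.arange(n_samples), 1 - pick] = config.mu - half
    depth = rng.poisson(config.depth, size=rates.shape)
    meth = _beta_binomial(rng, depth, rates, config.rho)

    het = haplotypes.is_het()  # (n_samples, n_snps); snp j phases cpg j
    ci, si = np.nonzero(het.T)
    samples = np.asarray(haplotypes.samples, dtype=object)
    pos = truth["pos"].to_numpy()
    phased = pd.DataFrame({
        "chrom": config.chrom,
        "pos": pos[ci],
        "strand": "+",
        "context": "CpG",
        "sample": samples[si],
        "snp_id": truth["phasing_snp"].to_numpy()[ci],
        "methA": meth[ci, si, 0],
        "unmethA": depth[ci, si, 0] - meth[ci, si, 0],
        "methB": meth[ci, si, 1],
        "unmethB": depth[ci, si, 1] - meth[ci, si, 1],
    })[PHASED_COLUMNS]

    ct, st = np.meshgrid(np.arange(n_cpgs), np.arange(n_samples),
                         indexing="ij")
    ct, st = ct.ravel(), st.ravel()
    totals = pd.DataFrame({
        "chrom": config.chrom,
        "pos": pos[ct],
        "sample": samples[st],
        "meth": meth[ct, st].sum(axis=1),
        "unmeth": (depth[ct, st] - meth[ct, st]).sum(axis=1),
    })[TOTAL_COLUMNS]
    return MethylationTables(phased, totals, meth, depth, rates)


def couple_genes(config: SimulationConfig, truth: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Pick the CpGs that drive a gene each (one gene per coupled CpG)."""
    n_genes = min(config.n_genes, len(truth))
    idx = rng.choice(len(truth), size=n_genes, replace=False)
    idx.sort()
    genes = truth.iloc[idx][["cpg_id", "chrom", "pos"]].copy()
    genes["gene_id"] = [f"gene{k}" for k in range(n_genes)]
    genes["tss"] = genes["pos"] + config.tss_offset
    genes["coupling_sign"] = -1  # higher methylation -> lower expression
    genes["cpg_index"] = idx
    return genes.reset_index(drop=True)


def simulate_expression(config: SimulationConfig,
                        haplotypes: HaplotypeMatrix,
                        meth: MethylationTables,
                        genes: pd.DataFrame,
                        rng: np.random.Generator | None = None,
                        ) -> pd.DataFrame:
    """Allelic and total gene expression coupled to methylation.

    The haplotype-A read fraction follows a logit link with negative
    slope on the methylation difference (hypermethylated allele is
    expressed less); total gene reads are negative-binomial with a
    sample library-size factor and a log-linear dependence on the mean
    methylation of the driving CpG, so the non-allelic channel carries
    the same coupling sign as the allelic one.
    """
    if rng is None:
        rng = config.rngs()[2]
    n_samples = config.n_samples
    lib = np.exp(rng.normal(0.0, 0.2, size=n_samples))
    rows = []
    for g in genes.itertuples():
        i = g.cpg_index
        p_a, p_b = meth.rates[i, :, 0], meth.rates[i, :, 1]
        logit = config.expr_intercept - config.expr_slope * (p_a - p_b)
        frac_a = 1.0 / (1.0 + np.exp(-logit))
        allelic_depth = rng.poisson(config.expr_allelic_depth, n_samples)
        reads_a = rng.binomial(allelic_depth, frac_a)
        mean_total = (config.expr_base_reads * lib
                      * np.exp(-config.expr_total_slope
                               * ((p_a + p_b) / 2.0 - config.mu)))
        shape = config.expr_dispersion
        total = rng.poisson(rng.gamma(shape, mean_total / shape))
        rows.append(pd.DataFrame({
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "tss": g.tss,
            "sample": haplotypes.samples,
            "total_reads": total,
            "library_reads": np.round(config.library_reads * lib).astype(int),
            "readsA": reads_a,
            "readsB": allelic_depth - reads_a,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_histone(config: SimulationConfig,
                     haplotypes: HaplotypeMatrix,
                     meth: MethylationTables,
                     truth: pd.DataFrame,
                     marks: Mapping[str, str] | None = None,
                     rng: np.random.Generator | None = None,
                     ) -> pd.DataFrame:
    """Allelic ChIP read counts at phasing SNPs, coupled to methylation.

    Activating marks are depleted on the hypermethylated haplotype
    (negative coupling), repressive marks enriched (positive coupling).
    Records are emitted for samples heterozygous at the SNP.
    """
    if marks is None:
        marks = {"H3K27ac": "activating", "H3K27me3": "repressive"}
    bad = set(marks.values()) - {"activating", "repressive"}
    if bad:
        raise ValueError(f"unknown mark types: {sorted(bad)}")
    if rng is None:
        rng = config.rngs()[3]
    het = haplotypes.is_het()
    ci, si = np.nonzero(het.T)
    diff = meth.rates[ci, si, 0] - meth.rates[ci, si, 1]
    samples = np.asarray(haplotypes.samples, dtype=object)
    pos = haplotypes.positions
    rows = []
    for mark, kind in marks.items():
        sign = -1.0 if kind == "activating" else 1.0
        frac_a = 1.0 / (1.0 + np.exp(-sign * config.histone_slope * diff))
        depth = rng.poisson(config.histone_depth, size=len(ci))
        reads_a = rng.binomial(depth, frac_a)
        rows.append(pd.DataFrame({
            "mark": mark,
            "mark_type": kind,
            "snp_id": np.asarray(haplotypes.snp_ids, dtype=object)[ci],
            "chrom": config.chrom,
            "pos": pos[ci],
            "sample": samples[si],
            "readsA": reads_a,
            "readsB": depth - reads_a,
        }))
    return pd.concat(rows, ignore_index=True)


@dataclass
class Cohort:
    """Everything one simulated study produces."""

    config: SimulationConfig
    haplotypes: HaplotypeMatrix
    truth: pd.DataFrame
    methylation: MethylationTables
    genes: pd.DataFrame
    expression: pd.DataFrame
    histone: pd.DataFrame


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Run the full generator with one RNG stream per table."""
    r_hap, r_meth, r_expr, r_hist, r_truth = config.rngs(5)
    truth = assign_scenarios(config, r_truth)
    haplotypes = simulate_haplotypes(config, r_hap)
    methylation = simulate_methylation(config, haplotypes, truth, r_meth)
    genes = couple_genes(config, truth, r_expr)
    expression = simulate_expression(config, haplotypes, methylation, genes,
                                     r_expr)
    histone = simulate_histone(config, haplotypes, methylation, truth,
                               rng=r_hist)
    return Cohort(config, haplotypes, truth, methylation, genes, expression,
                  histone)
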