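"""Synthetic plasma-sequencing data generator.

Emulates the data a shallow-depth NIPT run produces: a phased reference
haplotype panel with genuine linkage disequilibrium, a diploid mother plus
one paternally inherited fetal haplotype mixed at a known fetal fraction
``F``, Poisson-depth read pileups with sequencing error, per-sample
confounder metrics, and chromosome-Y read fractions.

The panel generator is a mosaic-copying process (each new haplotype copies
a random earlier one, switching template between adjacent sites and
occasionally miscopying) rather than a full coalescent simulation: it
creates the LD structure genotype imputation exploits while staying easy
to reason about.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Site",
    "HaplotypePanel",
    "TrioTruth",
    "PlasmaPileup",
    "Confounders",
    "MafSample",
    "PlasmaSample",
    "simulate_panel",
    "sample_trio",
    "simulate_plasma_pileup",
    "simulate_confounders",
    "simulate_chry_fraction",
    "simulate_maf_sample",
    "simulate_cohort",
    "suppress_fetal_signal",
]

_NUCLEOTIDES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class Site:
    """One biallelic SNP site."""

    chrom: str
    pos: int  # 1-based, bp
    ref_allele: str
    alt_allele: str
    maf: float  # min(f, 1 - f) for panel alt-allele frequency f


@dataclass
class SiteTable:
    """Column-oriented site list shared by panels, pileups and tracks."""

    chrom: np.ndarray  # str per site
    pos: np.ndarray  # 1-based int per site
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    maf: np.ndarray

    def __len__(self) -> int:
        return len(self.pos)

    def __iter__(self):
        for i in range(len(self)):
            yield Site(
                str(self.chrom[i]),
                int(self.pos[i]),
                str(self.ref_allele[i]),
                str(self.alt_allele[i]),
                float(self.maf[i]),
            )

    def validate(self) -> None:
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")


@dataclass
class HaplotypePanel:
    """Phased reference haplotypes over ordered biallelic sites.

    ``haplotypes`` is an H x L binary matrix; allele 0 = ref, 1 = alt.
    """

    sites: SiteTable
    haplotypes: np.ndarray
    population_label: str = "synthetic"

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def recompute_maf(self) -> None:
        f = self.haplotypes.mean(axis=0)
        self.sites.maf = np.minimum(f, 1.0 - f)


@dataclass
class TrioTruth:
    """Ground-truth mother/father/fetus haplotypes for one pregnancy."""

    sites: SiteTable
    maternal_hap_a: np.ndarray
    maternal_hap_b: np.ndarray
    paternal_hap: np.ndarray
    fetal_transmitted_hap: np.ndarray
    true_ff: float

    @property
    def maternal_genotype(self) -> np.ndarray:
        return self.maternal_hap_a + self.maternal_hap_b

    @property
    def fetal_genotype(self) -> np.ndarray:
        return self.fetal_transmitted_hap + self.paternal_hap


@dataclass
class PlasmaPileup:
    """Per-site ref/alt allele read counts for one plasma sample."""

    sites: SiteTable
    ref_count: np.ndarray
    alt_count: np.ndarray
    seq_error_rate: float = 0.0

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class Confounders:
    """Per-sample sequencing-characteristic covariates for the regression."""

    total_coverage: float
    mq_gt0_coverage: float
    pcr_dup_rate: float

    def __post_init__(self):
        if self.mq_gt0_coverage > self.total_coverage + 1e-12:
            raise ValueError("mq_gt0_coverage must not exceed total_coverage")
        if not 0.0 <= self.pcr_dup_rate <= 1.0:
            raise ValueError("pcr_dup_rate must be in [0, 1]")


@dataclass
class MafSample:
    """Per-site minor-allele read fractions from a deeply sequenced sample."""

    maf_values: np.ndarray  # reals in [0, 0.5]
    depths: np.ndarray

    def __post_init__(self):
        self.maf_values = np.asarray(self.maf_values, dtype=float)
        self.depths = np.asarray(self.depths, dtype=int)
        if np.any((self.maf_values < 0) | (self.maf_values > 0.5)):
            raise ValueError("minor-allele fractions must lie in [0, 0.5]")


@dataclass
class PlasmaSample:
    """One simulated cohort member with everything downstream stages need."""

    sample_id: str
    pileup: PlasmaPileup
    confounders: Confounders
    true_ff: float
    trio: TrioTruth | None = None
    pct_chry: float | None = None


def _mosaic_copy(rng: np.random.Generator, pool: np.ndarray,
                 switch_rate: float, mutation_rate: float) -> np.ndarray:
    """Copy a new haplotype as a mosaic of the rows of ``pool``."""
    n, length = pool.shape
    # template index per site: Markov chain, switch w.p. switch_rate
    tmpl = np.empty(length, dtype=np.int64)
    tmpl[0] = rng.integers(n)
    switches = rng.random(length - 1) < switch_rate
    draws = rng.integers(n, size=length - 1)
    for j in range(1, length):
        tmpl[j] = draws[j - 1] if switches[j - 1] else tmpl[j - 1]
    hap = pool[tmpl, np.arange(length)].copy()
    if mutation_rate > 0:
        flips = rng.random(length) < mutation_rate
        hap[flips] = 1 - hap[flips]
    return hap


def simulate_panel(n_haplotypes: int, sites_per_chrom: int, n_chroms: int,
                   switch_rate: float, mutation_rate: float, seed: int,
                   chrom_length_bp: int = 50_000_000,
                   population_label: str = "synthetic") -> HaplotypePanel:
    """Simulate a phased reference panel with LD via mosaic copying.

    The first two haplotypes are independent Bernoulli(0.5) draws per site;
    every later haplotype copies a random earlier one, switching template
    with probability ``switch_rate`` between adjacent sites and flipping the
    copied allele with probability ``mutation_rate``. Sites are spaced
    evenly over ``chrom_length_bp`` on each chromosome and per-site MAF is
    recomputed from the final matrix.
    """
    if n_haplotypes < 4:
        raise ValueError("n_haplotypes must be >= 4")
    if sites_per_chrom < 2 or n_chroms < 1:
        raise ValueError("sites_per_chrom must be >= 2 and n_chroms >= 1")
    for name, rate in [("switch_rate", switch_rate), ("mutation_rate", mutation_rate)]:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    length = sites_per_chrom * n_chroms
    haps = np.zeros((n_haplotypes, length), dtype=np.int8)
    haps[0] = rng.integers(0, 2, size=length)
    haps[1] = rng.integers(0, 2, size=length)
    for i in range(2, n_haplotypes):
        haps[i] = _mosaic_copy(rng, haps[:i], switch_rate, mutation_rate)

    spacing = chrom_length_bp // sites_per_chrom
    pos_one = spacing // 2 + spacing * np.arange(sites_per_chrom) + 1
    chrom = np.repeat([f"chr{i + 1}" for i in range(n_chroms)], sites_per_chrom)
    pos = np.tile(pos_one, n_chroms)
    ref_idx = rng.integers(0, 4, size=length)
    alt_idx = (ref_idx + rng.integers(1, 4, size=length)) % 4
    sites = SiteTable(
        chrom=chrom.astype(object),
        pos=pos.astype(np.int64),
        ref_allele=_NUCLEOTIDES[ref_idx].astype(object),
        alt_allele=_NUCLEOTIDES[alt_idx].astype(object),
        maf=np.zeros(length),
    )
    panel = HaplotypePanel(sites=sites, haplotypes=haps,
                           population_label=population_label)
    panel.recompute_maf()
    return panel


def sample_trio(panel: HaplotypePanel, true_ff: float, recomb_rate: float,
                seed: int, copy_switch_rate: float = 0.005,
                copy_mutation_rate: float = 1e-3) -> TrioTruth:
    """Draw a mother/father pair related to the panel and one fetus.

    Parental haplotypes are fresh mosaic copies of the panel (related to,
    but not verbatim rows of, the reference). The transmitted fetal
    haplotype is a recombinant of the two maternal haplotypes with per-site
    switch probability ``recomb_rate``.
    """
    if not 0.0 <= true_ff <= 1.0:
        raise ValueError("true_ff must lie in [0, 1]")
    if panel.n_sites == 0:
        raise ValueError("panel is empty")
    rng = np.random.default_rng(seed)
    pool = panel.haplotypes
    hap_a = _mosaic_copy(rng, pool, copy_switch_rate, copy_mutation_rate)
    hap_b = _mosaic_copy(rng, pool, copy_switch_rate, copy_mutation_rate)
    hap_p = _mosaic_copy(rng, pool, copy_switch_rate, copy_mutation_rate)
    # meiosis: recombinant of the two maternal haplotypes
    length = panel.n_sites
    which = np.empty(length, dtype=np.int8)
    which[0] = rng.integers(2)
    cross = rng.random(length - 1) < recomb_rate
    which[1:] = (which[0] + np.cumsum(cross)) % 2
    transmitted = np.where(which == 0, hap_a, hap_b).astype(np.int8)
    return TrioTruth(
        sites=panel.sites,
        maternal_hap_a=hap_a,
        maternal_hap_b=hap_b,
        paternal_hap=hap_p,
        fetal_transmitted_hap=transmitted,
        true_ff=float(true_ff),
    )


def suppress_fetal_signal(trio: TrioTruth, site_mask: np.ndarray) -> TrioTruth:
    """Return a trio whose fetal genotype equals the maternal one at masked sites.

    Used to construct cohorts in which imputation discordance carries fetal
    signal only at chosen sites (e.g. only above a MAF cutoff): at masked
    sites the fetus inherits exactly the maternal allele pair.
    """
    site_mask = np.asarray(site_mask, dtype=bool)
    transmitted = trio.fetal_transmitted_hap.copy()
    paternal = trio.paternal_hap.copy()
    transmitted[site_mask] = trio.maternal_hap_a[site_mask]
    paternal[site_mask] = trio.maternal_hap_b[site_mask]
    return replace(trio, fetal_transmitted_hap=transmitted, paternal_hap=paternal)


def simulate_plasma_pileup(trio: TrioTruth, mean_depth: float,
                           seq_error_rate: float, seed: int) -> PlasmaPileup:
    """Sequence the maternal/fetal cfDNA mixture at shallow depth.

    Per site, depth ~ Poisson(mean_depth); each read is fetal with
    probability ``trio.true_ff`` else maternal; the read's allele is a
    uniform draw from the chosen individual's two alleles, then flipped
    with probability ``seq_error_rate``.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0.0 <= seq_error_rate < 0.5:
        raise ValueError("seq_error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    length = len(trio.sites)
    depth = rng.poisson(mean_depth, size=length)
    n_fetal = rng.binomial(depth, trio.true_ff)
    n_maternal = depth - n_fetal
    eps = seq_error_rate
    # alt probability of one read from each source, with error folded in
    p_mat = trio.maternal_genotype / 2.0
    p_fet = trio.fetal_genotype / 2.0
    p_mat = p_mat * (1 - eps) + (1 - p_mat) * eps
    p_fet = p_fet * (1 - eps) + (1 - p_fet) * eps
    alt = rng.binomial(n_maternal, p_mat) + rng.binomial(n_fetal, p_fet)
    return PlasmaPileup(
        sites=trio.sites,
        ref_count=(depth - alt).astype(np.int64),
        alt_count=alt.astype(np.int64),
        seq_error_rate=eps,
    )


def simulate_confounders(pileup: PlasmaPileup, dup_rate_mean: float,
                         seed: int, jitter: float = 0.01) -> Confounders:
    """Synthesize the three regression confounders from a pileup."""
    if not 0.0 <= dup_rate_mean < 1.0:
        raise ValueError("dup_rate_mean must lie in [0, 1)")
    if len(pileup.sites) == 0:
        raise ValueError("pileup is empty")
    rng = np.random.default_rng(seed)
    total = float(pileup.depth.mean())
    mq = total * rng.uniform(0.9, 1.0)
    dup = dup_rate_mean + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
    dup = float(np.clip(dup, 0.0, 1.0))
    return Confounders(total_coverage=total, mq_gt0_coverage=mq, pcr_dup_rate=dup)


def simulate_chry_fraction(true_ff: float, male_pct_chry: float,
                           female_pct_chry: float, n_reads: int,
                           seed: int) -> float:
    """Simulate the fraction of reads mapping to chrY.

    The expected fraction mixes the adult-male and euploid-female-pregnancy
    baselines linearly in the fetal fraction:
    %chrY = male%chrY * F + female%chrY * (1 - F).
    """
    if not 0.0 <= female_pct_chry < male_pct_chry <= 1.0:
        raise ValueError("require 0 <= female_pct_chry < male_pct_chry <= 1")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0.0 <= true_ff <= 1.0:
        raise ValueError("true_ff must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = male_pct_chry * true_ff + female_pct_chry * (1.0 - true_ff)
    return float(rng.binomial(n_reads, p)) / n_reads


def simulate_maf_sample(true_ff: float, n_sites: int, seed: int,
                        peak_sd: float = 0.005, background_weight: float = 0.3,
                        background_sd: float = 0.002, mean_depth: int = 130,
                        maf_upper: float = 0.25) -> MafSample:
    """Synthesize per-site minor-allele fractions from a deep plasma sample.

    A fraction ``1 - background_weight`` of sites are maternal-homozygous /
    fetal-heterozygous, whose minor-allele fraction peaks at F/2 (modelled
    as a Gaussian bump, the high-depth limit); the rest are error-driven
    sites with tiny minor-allele fractions. Values are truncated to
    (0, maf_upper].
    """
    if not 0.0 <= true_ff <= 1.0:
        raise ValueError("true_ff must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    is_bg = rng.random(n_sites) < background_weight
    vals = np.where(
        is_bg,
        np.abs(rng.normal(0.0, background_sd, size=n_sites)),
        rng.normal(true_ff / 2.0, peak_sd, size=n_sites),
    )
    vals = vals[(vals > 0) & (vals <= maf_upper)]
    depths = rng.poisson(mean_depth, size=len(vals))
    return MafSample(maf_values=np.clip(vals, 0.0, 0.5), depths=depths)


def simulate_cohort(panel: HaplotypePanel, true_ffs, mean_depth: float,
                    seq_error_rate: float, dup_rate_mean: float, seed: int,
                    recomb_rate: float = 0.005,
                    male_pct_chry: float = 0.0035,
                    female_pct_chry: float = 0.0002,
                    chry_n_reads: int = 7_000_000) -> list[PlasmaSample]:
    """Simulate a plasma cohort: one trio, pileup, confounder set and chrY
    read fraction per requested fetal fraction."""
    rng = np.random.default_rng(seed)
    samples = []
    for i, ff in enumerate(np.asarray(true_ffs, dtype=float)):
        sub = int(rng.integers(2**31 - 1))
        trio = sample_trio(panel, ff, recomb_rate, seed=sub)
        pileup = simulate_plasma_pileup(trio, mean_depth, seq_error_rate,
                                        seed=sub + 1)
        conf = simulate_confounders(pileup, dup_rate_mean, seed=sub + 2)
        pct = simulate_chry_fraction(ff, male_pct_chry, female_pct_chry,
                                     chry_n_reads, seed=sub + 3)
        samples.append(PlasmaSample(
            sample_id=f"S{i:04d}", pileup=pileup, confounders=conf,
            true_ff=float(ff), trio=trio, pct_chry=pct,
        ))
    return samples
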