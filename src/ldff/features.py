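"""Genome binning and the regional LD-ratio feature vector.

The regional LD-ratio of a genomic bin is the proportion of eligible SNP
sites whose imputed genotype disagrees with the directly observed genotype.
Eligible sites are those with panel minor allele frequency above a cutoff
(common variants impute reliably) and a non-missing observed genotype.
Ratios over all bins, plus three sequencing confounders (total coverage,
MQ>0 coverage, PCR duplication rate), form the design matrix of the
fetal-fraction regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .impute import MISSING, GenotypeTrack
from .simdata import Confounders

__all__ = [
    "GenomeBins",
    "FeatureVector",
    "DEFAULT_EXCLUDED_CHROMS",
    "make_bins",
    "regional_ld_ratios",
    "compute_feature_vector",
    "assemble_design_matrix",
    "CONFOUNDER_COLUMNS",
]

# chromosomes carrying fetal-aneuploidy or fetal-sex signal are excluded
# from the model so it cannot overfit to them
DEFAULT_EXCLUDED_CHROMS = frozenset(
    {"13", "18", "21", "X", "Y", "chr13", "chr18", "chr21", "chrX", "chrY"}
)

CONFOUNDER_COLUMNS = ("total_coverage", "mq_gt0_coverage", "pcr_dup_rate")


@dataclass
class GenomeBins:
    """Ordered, non-overlapping 0-based half-open genomic intervals."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    bin_size_bp: int = 5_000_000
    excluded_chroms: frozenset = DEFAULT_EXCLUDED_CHROMS

    def __len__(self) -> int:
        return len(self.start)

    @property
    def bin_ids(self) -> list[str]:
        return [f"bin_{i + 1:04d}" for i in range(len(self))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "start": self.start, "end": self.end,
            "bin_id": self.bin_ids,
        })


@dataclass
class FeatureVector:
    """Per-sample regression inputs: per-bin LD-ratios plus confounders."""

    sample_id: str
    ld_ratios: np.ndarray  # per-bin ratio in [0,1], NaN where undefined
    confounders: Confounders
    maf_cutoff: float


def _mask_overlap(chrom: str, start: int, end: int, mask) -> int:
    total = 0
    for mc, ms, me in mask:
        if mc == chrom:
            total += max(0, min(end, me) - max(start, ms))
    return total


def make_bins(chrom_lengths: dict[str, int], bin_size_bp: int = 5_000_000,
              excluded_chroms=DEFAULT_EXCLUDED_CHROMS,
              mask=None, max_mask_overlap: float = 0.5) -> GenomeBins:
    """Tile each non-excluded chromosome into fixed-size bins.

    ``mask`` is an optional list of (chrom, start, end) intervals modelling
    assembly gaps (N-regions); a bin overlapping the mask over more than
    ``max_mask_overlap`` of its width is dropped.
    """
    if bin_size_bp <= 0:
        raise ValueError("bin_size_bp must be positive")
    excluded = frozenset(excluded_chroms)
    chroms, starts, ends = [], [], []
    for chrom in chrom_lengths:
        if chrom in excluded or chrom.removeprefix("chr") in excluded:
            continue
        length = int(chrom_lengths[chrom])
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        for s in range(0, length, bin_size_bp):
            e = min(s + bin_size_bp, length)
            if mask is not None:
                if _mask_overlap(chrom, s, e, mask) > max_mask_overlap * (e - s):
                    continue
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
    return GenomeBins(
        chrom=np.array(chroms, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        bin_size_bp=bin_size_bp,
        excluded_chroms=excluded,
    )


def regional_ld_ratios(track: GenotypeTrack, bins: GenomeBins,
                       maf_cutoff: float) -> np.ndarray:
    """Per-bin discordance proportion between imputed and observed genotypes.

    A site is eligible if its panel MAF exceeds ``maf_cutoff`` and its
    observed genotype is non-missing. Bins with no eligible site yield NaN.
    """
    if not 0.0 <= maf_cutoff < 0.5:
        raise ValueError("maf_cutoff must lie in [0, 0.5)")
    sites = track.sites
    eligible = (sites.maf > maf_cutoff) & (track.observed_gt != MISSING)
    discord = eligible & (track.imputed_gt != track.observed_gt)
    ratios = np.full(len(bins), np.nan)
    # sites are 1-based; bins 0-based half-open, so site in bin iff
    # start < pos <= end
    for b in range(len(bins)):
        in_bin = ((sites.chrom == bins.chrom[b])
                  & (sites.pos > bins.start[b])
                  & (sites.pos <= bins.end[b]))
        n_elig = np.count_nonzero(in_bin & eligible)
        if n_elig:
            ratios[b] = np.count_nonzero(in_bin & discord) / n_elig
    return ratios


def compute_feature_vector(sample_id: str, track: GenotypeTrack,
                           bins: GenomeBins, maf_cutoff: float,
                           confounders: Confounders) -> FeatureVector:
    """Bundle a sample's regional LD-ratios and confounders."""
    return FeatureVector(
        sample_id=sample_id,
        ld_ratios=regional_ld_ratios(track, bins, maf_cutoff),
        confounders=confounders,
        maf_cutoff=maf_cutoff,
    )


def assemble_design_matrix(features: list[FeatureVector],
                           bin_fill: np.ndarray | None = None,
                           bin_ids: list[str] | None = None):
    """Stack feature vectors into an n x (B + 3) design matrix.

    Columns are the B bin ratios followed by the three confounders, in a
    stable recorded order. Missing ratios are replaced by ``bin_fill``
    (typically per-bin training means); a missing ratio with no finite fill
    raises an error naming the bin.

    Returns (matrix, column_names).
    """
    if not features:
        raise ValueError("no feature vectors supplied")
    n_bins = len(features[0].ld_ratios)
    cutoff = features[0].maf_cutoff
    for f in features:
        if len(f.ld_ratios) != n_bins:
            raise ValueError(
                f"inconsistent bin counts: {f.sample_id} has "
                f"{len(f.ld_ratios)}, expected {n_bins}")
        if f.maf_cutoff != cutoff:
            raise ValueError("feature vectors mix MAF cutoffs")
    if bin_ids is None:
        bin_ids = [f"bin_{i + 1:04d}" for i in range(n_bins)]
    columns = list(bin_ids) + list(CONFOUNDER_COLUMNS)
    x = np.empty((len(features), n_bins + 3))
    for i, f in enumerate(features):
        row = f.ld_ratios.astype(float).copy()
        nan = np.isnan(row)
        if nan.any():
            if bin_fill is None:
                b = int(np.flatnonzero(nan)[0])
                raise ValueError(
                    f"sample {f.sample_id}: missing ratio in {bin_ids[b]} "
                    "and no fill values supplied")
            fill = np.asarray(bin_fill, dtype=float)
            if np.isnan(fill[nan]).any():
                b = int(np.flatnonzero(nan & np.isnan(fill))[0])
                raise ValueError(
                    f"sample {f.sample_id}: missing ratio in {bin_ids[b]} "
                    "with no finite fill value")
            row[nan] = fill[nan]
        c = f.confounders
        x[i] = np.concatenate(
            [row, [c.total_coverage, c.mq_gt0_coverage, c.pcr_dup_rate]])
    return x, columns
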