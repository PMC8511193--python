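"""Readers and writers for the formats the pipeline touches.

Haplotype panels and genotypes travel as VCF 4.2 (phased GT, one sample
column per diploid haplotype pair, alt-allele frequency in INFO/AF); bins
as BED (0-based half-open); pileups, features, genotype tracks, truth and
predictions as tab-separated tables with a header row and ``.`` for
missing; trained models as schema-versioned JSON. Internally coordinates
are 0-based half-open for intervals and 1-based for sites, converted only
at these boundaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .features import CONFOUNDER_COLUMNS, FeatureVector, GenomeBins
from .impute import MISSING, GenotypeTrack
from .regress import LDFFModel
from .simdata import Confounders, HaplotypePanel, PlasmaPileup, SiteTable

logger = logging.getLogger("ldff")

__all__ = [
    "read_panel_vcf", "write_panel_vcf", "VcfReadReport",
    "read_pileup_tsv", "write_pileup_tsv",
    "read_features_tsv", "write_features_tsv",
    "read_model_json", "write_model_json",
    "read_bed", "write_bed",
    "read_track_tsv", "write_track_tsv",
    "load_config", "CONFIG_DEFAULTS",
]

_MISSING_TOKEN = "."


# ---------------------------------------------------------------- panel VCF

@dataclass
class VcfReadReport:
    """Counts of records skipped while reading a panel VCF."""

    n_unphased: int = 0
    n_multiallelic: int = 0
    n_loaded: int = 0


def write_panel_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write phased panel haplotypes, pairing consecutive haplotypes into
    diploid sample columns. Requires an even haplotype count."""
    h = panel.n_haplotypes
    if h % 2:
        raise ValueError("panel must have an even number of haplotypes "
                         "to pair into diploid VCF samples")
    n_samples = h // 2
    sites = panel.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=ldff(panel={panel.population_label})\n")
        for c in dict.fromkeys(sites.chrom):
            last = int(sites.pos[sites.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={last + 1}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                 'Description="Alt allele frequency in the panel">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = "\t".join(f"HAPPAIR{i + 1:04d}" for i in range(n_samples))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + names + "\n")
        alt_freq = panel.haplotypes.mean(axis=0)
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{panel.haplotypes[2 * s, j]}|{panel.haplotypes[2 * s + 1, j]}"
                for s in range(n_samples))
            fh.write(f"{sites.chrom[j]}\t{sites.pos[j]}\t.\t"
                     f"{sites.ref_allele[j]}\t{sites.alt_allele[j]}\t.\t.\t"
                     f"AF={alt_freq[j]:.6g}\tGT\t{gts}\n")


def read_panel_vcf(path: str, population_label: str = "vcf"):
    """Read a phased panel VCF.

    Unphased or multiallelic records are rejected and counted in the
    returned report. Returns (HaplotypePanel, VcfReadReport).
    """
    report = VcfReadReport()
    chroms, positions, refs, alts = [], [], [], []
    columns = []
    vcf = VCF(path)
    for var in vcf:
        if len(var.ALT) != 1:
            report.n_multiallelic += 1
            continue
        gts = var.genotypes  # [a, b, phased] per sample
        if not all(g[2] for g in gts):
            report.n_unphased += 1
            continue
        columns.append([a for g in gts for a in g[:2]])
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        report.n_loaded += 1
    vcf.close()
    if not columns:
        raise ValueError(f"no usable phased biallelic records in {path}")
    haps = np.array(columns, dtype=np.int8).T
    sites = SiteTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        maf=np.zeros(len(positions)),
    )
    panel = HaplotypePanel(sites=sites, haplotypes=haps,
                           population_label=population_label)
    panel.recompute_maf()
    if report.n_unphased or report.n_multiallelic:
        logger.warning("rejected %d unphased and %d multiallelic records in %s",
                       report.n_unphased, report.n_multiallelic, path)
    return panel, report


# ------------------------------------------------------------------- pileup

_PILEUP_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


def write_pileup_tsv(pileup: PlasmaPileup, path: str) -> None:
    pd.DataFrame({
        "chrom": pileup.sites.chrom,
        "pos": pileup.sites.pos,
        "ref": pileup.sites.ref_allele,
        "alt": pileup.sites.alt_allele,
        "ref_count": pileup.ref_count,
        "alt_count": pileup.alt_count,
    }).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str, maf: np.ndarray | None = None) -> PlasmaPileup:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _PILEUP_COLUMNS:
        raise ValueError(f"pileup header mismatch in {path}: {list(df.columns)}")
    if df[["ref_count", "alt_count"]].isna().any().any():
        raise ValueError(f"NaN read counts in {path}")
    sites = SiteTable(
        chrom=df["chrom"].astype(str).to_numpy(dtype=object),
        pos=df["pos"].to_numpy(np.int64),
        ref_allele=df["ref"].astype(str).to_numpy(dtype=object),
        alt_allele=df["alt"].astype(str).to_numpy(dtype=object),
        maf=np.zeros(len(df)) if maf is None else np.asarray(maf, dtype=float),
    )
    return PlasmaPileup(sites=sites,
                        ref_count=df["ref_count"].to_numpy(np.int64),
                        alt_count=df["alt_count"].to_numpy(np.int64))


# ----------------------------------------------------------- genotype track

_TRACK_COLUMNS = ["chrom", "pos", "maf", "observed_gt", "imputed_gt",
                  "p0", "p1", "p2"]


def write_track_tsv(track: GenotypeTrack, path: str) -> None:
    obs = pd.array(track.observed_gt, dtype="Int64")
    obs = obs.to_numpy(dtype=object)
    obs[track.observed_gt == MISSING] = None
    pd.DataFrame({
        "chrom": track.sites.chrom,
        "pos": track.sites.pos,
        "maf": track.sites.maf,
        "observed_gt": obs,
        "imputed_gt": track.imputed_gt,
        "p0": track.imputed_posterior[:, 0],
        "p1": track.imputed_posterior[:, 1],
        "p2": track.imputed_posterior[:, 2],
    }).to_csv(path, sep="\t", index=False, na_rep=_MISSING_TOKEN)


def read_track_tsv(path: str) -> GenotypeTrack:
    df = pd.read_csv(path, sep="\t", na_values=[_MISSING_TOKEN])
    if list(df.columns) != _TRACK_COLUMNS:
        raise ValueError(f"track header mismatch in {path}: {list(df.columns)}")
    obs = df["observed_gt"].to_numpy(dtype=float)
    observed = np.where(np.isnan(obs), MISSING, obs).astype(np.int8)
    post = df[["p0", "p1", "p2"]].to_numpy(dtype=float)
    post /= post.sum(axis=1, keepdims=True)
    sites = SiteTable(
        chrom=df["chrom"].astype(str).to_numpy(dtype=object),
        pos=df["pos"].to_numpy(np.int64),
        ref_allele=np.full(len(df), "N", dtype=object),
        alt_allele=np.full(len(df), "N", dtype=object),
        maf=df["maf"].to_numpy(dtype=float),
    )
    return GenotypeTrack(
        sites=sites,
        observed_gt=observed,
        imputed_posterior=post,
        imputed_gt=df["imputed_gt"].to_numpy(np.int8),
    )


# ----------------------------------------------------------------- features

def write_features_tsv(features: list[FeatureVector], path: str,
                       bin_ids: list[str] | None = None) -> None:
    n_bins = len(features[0].ld_ratios)
    if bin_ids is None:
        bin_ids = [f"bin_{i + 1:04d}" for i in range(n_bins)]
    rows = []
    for f in features:
        row = {"sample_id": f.sample_id}
        row.update({b: v for b, v in zip(bin_ids, f.ld_ratios)})
        c = f.confounders
        row.update({"total_coverage": c.total_coverage,
                    "mq_gt0_coverage": c.mq_gt0_coverage,
                    "pcr_dup_rate": c.pcr_dup_rate})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=_MISSING_TOKEN)


def read_features_tsv(path: str, maf_cutoff: float) -> list[FeatureVector]:
    df = pd.read_csv(path, sep="\t", na_values=[_MISSING_TOKEN])
    expected_tail = list(CONFOUNDER_COLUMNS)
    if df.columns[0] != "sample_id" or list(df.columns[-3:]) != expected_tail:
        raise ValueError(f"features header mismatch in {path}")
    bin_cols = list(df.columns[1:-3])
    feats = []
    for _, row in df.iterrows():
        feats.append(FeatureVector(
            sample_id=str(row["sample_id"]),
            ld_ratios=row[bin_cols].to_numpy(dtype=float),
            confounders=Confounders(
                total_coverage=float(row["total_coverage"]),
                mq_gt0_coverage=float(row["mq_gt0_coverage"]),
                pcr_dup_rate=float(row["pcr_dup_rate"]),
            ),
            maf_cutoff=maf_cutoff,
        ))
    return feats


# -------------------------------------------------------------------- model

def write_model_json(model: LDFFModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model_json(path: str) -> LDFFModel:
    with open(path) as fh:
        return LDFFModel.from_dict(json.load(fh))


# ---------------------------------------------------------------------- BED

def write_bed(bins: GenomeBins, path: str) -> None:
    bins.to_frame().to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str, bin_size_bp: int = 5_000_000) -> GenomeBins:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "bin_id"])
    return GenomeBins(
        chrom=df["chrom"].astype(str).to_numpy(dtype=object),
        start=df["start"].to_numpy(np.int64),
        end=df["end"].to_numpy(np.int64),
        bin_size_bp=bin_size_bp,
    )


# ------------------------------------------------------------------- config

CONFIG_DEFAULTS: dict = {
    "seed": 0,
    "log_level": "INFO",
    "simdata": {
        "n_haplotypes": 40,
        "sites_per_chrom": 1000,
        "n_chroms": 2,
        "chrom_length_bp": 50_000_000,
        "switch_rate": 0.02,
        "mutation_rate": 0.01,
        "recomb_rate": 0.005,
        "mean_depth": 1.0,
        "seq_error_rate": 1e-3,
        "dup_rate_mean": 0.05,
        "ff_low": 0.01,
        "ff_high": 0.30,
        "n_samples": 40,
        "male_pct_chry": 0.0035,
        "female_pct_chry": 0.0002,
        "chry_n_reads": 7_000_000,
    },
    "impute": {
        "window_bp": 5_000_000,
        "buffer_bp": 250_000,
        "switch_prob": 1e-3,
        "miscopy_prob": 1e-3,
        "seq_error_rate": 1e-3,
    },
    "features": {
        "bin_size_bp": 5_000_000,
        "maf_cutoff": 0.2,
        "excluded_chroms": ["13", "18", "21", "X", "Y"],
    },
    "regress": {
        "maf_grid": [0.15, 0.2, 0.25, 0.3],
    },
    "baselines": {
        "male_pct_chry": 0.0035,
        "female_pct_chry": 0.0002,
        "n_components": 3,
        "maf_upper": 0.25,
        "min_depth": 30,
        "noise_floor": 0.005,
    },
}


def _merge_checked(defaults: dict, user: dict, prefix: str = "") -> dict:
    merged = dict(defaults)
    for key, value in user.items():
        if key not in defaults:
            raise ValueError(f"unknown config key: {prefix}{key}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config section {prefix}{key} must be a mapping")
            merged[key] = _merge_checked(defaults[key], value, f"{prefix}{key}.")
        else:
            merged[key] = value
    return merged


def load_config(path: str | None) -> dict:
    """Load a YAML run configuration, rejecting unknown keys and filling
    documented defaults."""
    if path is None:
        return _merge_checked(CONFIG_DEFAULTS, {})
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config root must be a mapping")
    return _merge_checked(CONFIG_DEFAULTS, user)
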