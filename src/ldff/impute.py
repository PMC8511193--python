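"""Windowed diploid genotype imputation from shallow read counts.

A Li–Stephens haplotype-copying HMM: the sample's two chromosomes are
modelled as mosaic copies of reference-panel haplotypes, so the hidden
state at each site is an ordered pair of panel haplotypes (H^2 states).
Each copied haplotype independently stays on its template with probability
1 - rho or jumps to a uniformly random haplotype with probability rho
between adjacent sites. Emissions are read-count likelihoods: each copied
haplotype contributes alt-allele probability q = h(1-mu) + (1-h)mu, a read
draws its allele from the two copies with equal probability, and sequencing
error eps flips it. Posterior genotype probabilities follow by summing
state posteriors against the Bernoulli(q1) x Bernoulli(q2) allele model.

Imputation is run per genomic window (default 5 Mb) with flanking buffer
sites (default 250 kb) included in the HMM but excluded from the report, so
window edges do not distort posteriors.

The diploid assumption is deliberate and central: maternal plasma contains
a third, fetal haplotype, so a diploid imputer "rectifies" part of the
fetal signal, and the rate at which imputed and observed genotypes disagree
grows with the fetal fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simdata import HaplotypePanel, PlasmaPileup, SiteTable

__all__ = [
    "ImputationParams",
    "GenotypeTrack",
    "MISSING",
    "impute_window",
    "impute_genome",
    "call_observed_genotypes",
]

MISSING = -1  # observed-genotype code for zero-depth sites


@dataclass(frozen=True)
class ImputationParams:
    """Tuning parameters of the copying model and windowing scheme.

    switch_prob is the per-adjacent-site template-switch probability rho,
    miscopy_prob the allele miscopy probability mu, seq_error_rate the
    per-read base error eps.
    """

    window_bp: int = 5_000_000
    buffer_bp: int = 250_000
    switch_prob: float = 1e-3
    miscopy_prob: float = 1e-3
    seq_error_rate: float = 1e-3

    def __post_init__(self):
        if self.window_bp <= 2 * self.buffer_bp:
            raise ValueError("window_bp must exceed twice buffer_bp")
        for name in ("switch_prob", "miscopy_prob", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5)")


@dataclass
class GenotypeTrack:
    """Observed and imputed genotype dosages with imputation posteriors."""

    sites: SiteTable
    observed_gt: np.ndarray  # int8 in {0,1,2, MISSING}
    imputed_posterior: np.ndarray  # L x 3, rows sum to 1
    imputed_gt: np.ndarray  # int8 in {0,1,2}

    def __post_init__(self):
        sums = self.imputed_posterior.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("posterior triples must each sum to 1")


def call_observed_genotypes(pileup: PlasmaPileup) -> np.ndarray:
    """Hard genotype calls from raw allele counts.

    Zero depth -> MISSING; only ref reads -> 0; only alt reads -> 2; both
    alleles seen -> 1. At ~0.1x most sites carry a single read, where this
    rule and a likelihood-based caller coincide.
    """
    r = np.asarray(pileup.ref_count)
    a = np.asarray(pileup.alt_count)
    if np.any(r < 0) or np.any(a < 0):
        raise ValueError("negative read counts")
    gt = np.full(len(r), MISSING, dtype=np.int8)
    gt[(r > 0) & (a == 0)] = 0
    gt[(r > 0) & (a > 0)] = 1
    gt[(r == 0) & (a > 0)] = 2
    return gt


def _ls_transition(msg: np.ndarray, rho: float) -> np.ndarray:
    """Apply the factorized Li–Stephens transition to an H x H message.

    Per copied haplotype the one-step kernel is (1-rho) I + (rho/H) J; the
    diploid kernel is its tensor square, applied along each axis in turn.
    The kernel is symmetric and doubly stochastic, so the same operator
    serves forward and backward passes.
    """
    h = msg.shape[0]
    msg = (1.0 - rho) * msg + (rho / h) * msg.sum(axis=0, keepdims=True)
    msg = (1.0 - rho) * msg + (rho / h) * msg.sum(axis=1, keepdims=True)
    return msg


def impute_window(panel: HaplotypePanel, pileup: PlasmaPileup,
                  site_range: tuple[int, int],
                  params: ImputationParams) -> np.ndarray:
    """Forward–backward genotype posteriors over one window of sites.

    Returns an (stop - start) x 3 array of P(G = 0/1/2 | reads) for the
    half-open site-index interval ``site_range``. Zero-depth sites emit
    likelihood 1, so their posterior is driven purely by LD.
    """
    start, stop = site_range
    if panel.n_sites == 0:
        raise ValueError("panel is empty")
    if panel.n_sites != len(pileup.sites):
        raise ValueError("panel and pileup must share the site list")
    if not 0 <= start < stop <= panel.n_sites:
        raise ValueError("site_range out of bounds")

    haps = panel.haplotypes[:, start:stop].astype(float)
    ref = np.asarray(pileup.ref_count[start:stop], dtype=float)
    alt = np.asarray(pileup.alt_count[start:stop], dtype=float)
    h, length = haps.shape
    rho, mu, eps = params.switch_prob, params.miscopy_prob, params.seq_error_rate

    q = haps * (1.0 - mu) + (1.0 - haps) * mu  # H x L alt prob per copy
    # per-site emission matrices over ordered haplotype pairs
    theta = 0.5 * (q[:, None, :] + q[None, :, :])  # H x H x L
    theta = theta * (1.0 - eps) + (1.0 - theta) * eps
    emit = theta ** alt * (1.0 - theta) ** ref  # depth-0 sites -> all ones

    # forward pass with per-site scaling
    fwd = np.empty((length, h, h))
    msg = np.full((h, h), 1.0 / (h * h)) * emit[:, :, 0]
    msg /= msg.sum()
    fwd[0] = msg
    for t in range(1, length):
        msg = _ls_transition(msg, rho) * emit[:, :, t]
        msg /= msg.sum()
        fwd[t] = msg

    # backward pass
    post = np.empty((length, 3))
    bwd = np.ones((h, h))
    q0 = 1.0 - q
    for t in range(length - 1, -1, -1):
        state_post = fwd[t] * bwd
        state_post /= state_post.sum()
        # genotype posterior from independent Bernoulli(q1), Bernoulli(q2)
        p0 = q0[:, t] @ state_post @ q0[:, t]
        p2 = q[:, t] @ state_post @ q[:, t]
        post[t, 0] = p0
        post[t, 2] = p2
        post[t, 1] = 1.0 - p0 - p2
        if t > 0:
            bwd = _ls_transition(bwd * emit[:, :, t], rho)
            bwd /= bwd.max()
    np.clip(post, 0.0, None, out=post)
    post /= post.sum(axis=1, keepdims=True)
    return post


def _hard_call(post: np.ndarray) -> np.ndarray:
    # argmax breaks ties toward the smaller dosage (first index wins)
    return np.argmax(post, axis=1).astype(np.int8)


def impute_genome(panel: HaplotypePanel, pileup: PlasmaPileup,
                  params: ImputationParams | None = None) -> GenotypeTrack:
    """Impute every site chromosome by chromosome in buffered windows.

    Each chromosome is partitioned into core windows of ``window_bp``;
    buffer sites within ``buffer_bp`` of a core edge join the HMM but only
    core posteriors are reported, so concatenated cores cover each site
    exactly once.
    """
    params = params or ImputationParams()
    sites = panel.sites
    if panel.n_sites != len(pileup.sites):
        raise ValueError("panel and pileup must share the site list")
    order = np.lexsort((sites.pos,))
    # verify sortedness within chromosome blocks
    chroms, starts = np.unique(sites.chrom, return_index=True)
    posterior = np.empty((panel.n_sites, 3))
    seen = np.zeros(panel.n_sites, dtype=bool)
    for c in chroms:
        idx = np.flatnonzero(sites.chrom == c)
        if np.any(np.diff(idx) != 1) or np.any(np.diff(sites.pos[idx]) <= 0):
            raise ValueError("sites must be sorted and contiguous by (chrom, pos)")
        pos = sites.pos[idx]
        lo_bp = 0
        max_bp = int(pos[-1])
        while lo_bp <= max_bp:
            hi_bp = lo_bp + params.window_bp
            core = idx[(pos > lo_bp) & (pos <= hi_bp)]
            if len(core):
                buffered = idx[(pos > lo_bp - params.buffer_bp)
                               & (pos <= hi_bp + params.buffer_bp)]
                b0, b1 = int(buffered[0]), int(buffered[-1]) + 1
                win_post = impute_window(panel, pileup, (b0, b1), params)
                rel = core - b0
                posterior[core] = win_post[rel]
                seen[core] = True
            lo_bp = hi_bp
    assert seen.all()
    return GenotypeTrack(
        sites=sites,
        observed_gt=call_observed_genotypes(pileup),
        imputed_posterior=posterior,
        imputed_gt=_hard_call(posterior),
    )
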