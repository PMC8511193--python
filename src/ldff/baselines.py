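"""Reference fetal-fraction estimators.

Two classical estimators serve as the reference against which the
LD-discordance regression is trained and validated:

* the chromosome-Y method, valid for male fetuses only, which inverts the
  linear mixture %chrY = male%chrY * F + female%chrY * (1 - F);
* the MAF-mixture method, which fits a mixture of normals to per-site
  minor-allele read fractions on (0, 0.25] from deep sequencing and reads
  the fetal fraction off the fetal peak located at F/2 (sites homozygous in
  the mother and heterozygous in the fetus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .simdata import MafSample

__all__ = [
    "ChrYCalibration",
    "MafFFResult",
    "chry_ff",
    "maf_ff",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Raised when too few usable sites are available for estimation."""


@dataclass(frozen=True)
class ChrYCalibration:
    """Mean chrY read fractions of adult males and of pregnancies bearing
    euploid female fetuses (the background mismapping level)."""

    male_pct_chry: float
    female_pct_chry: float

    def __post_init__(self):
        if not 0.0 <= self.female_pct_chry < self.male_pct_chry <= 1.0:
            raise ValueError(
                "require 0 <= female_pct_chry < male_pct_chry <= 1")


def chry_ff(pct_chry: float, calib: ChrYCalibration,
            clamp: bool = True) -> float:
    """Invert the chrY read-fraction mixture to the fetal fraction.

    F = (%chrY - female%chrY) / (male%chrY - female%chrY); with ``clamp``
    the estimate is truncated to [0, 1] (female-fetus minima report as 0).
    """
    denom = calib.male_pct_chry - calib.female_pct_chry
    if denom <= 0:
        raise ZeroDivisionError("degenerate calibration: male == female %chrY")
    f = (pct_chry - calib.female_pct_chry) / denom
    return float(np.clip(f, 0.0, 1.0)) if clamp else float(f)


@dataclass
class MafFFResult:
    """Fitted MAF-mixture estimate with the mixture description."""

    ff: float
    no_fetal_signal: bool
    component_means: np.ndarray
    component_sds: np.ndarray
    component_weights: np.ndarray
    fetal_component: int  # index into the arrays above, -1 if none


def maf_ff(sample: MafSample, n_components: int = 3, maf_upper: float = 0.25,
           min_depth: int = 30, noise_floor: float = 0.005,
           max_iter: int = 500, tol: float = 1e-8) -> MafFFResult:
    """Estimate the fetal fraction from deep-coverage minor-allele fractions.

    Fits an ``n_components`` Gaussian mixture by EM (deterministic
    k-quantile initialization) to MAF values in (0, maf_upper] at sites
    with depth >= ``min_depth``. The fetal component is the
    largest-weight component whose mean exceeds ``noise_floor`` (the
    homozygous-error band); the estimate is twice that component's mean.
    With no component above the floor the estimate is 0 with the
    ``no_fetal_signal`` flag set.
    """
    vals = sample.maf_values[(sample.depths >= min_depth)
                             & (sample.maf_values > 0)
                             & (sample.maf_values <= maf_upper)]
    if len(vals) < 100:
        raise InsufficientDataError(
            f"need >= 100 usable sites, got {len(vals)}")
    x = vals.reshape(-1, 1)
    quantiles = np.quantile(vals, (np.arange(n_components) + 0.5) / n_components)
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="diag",
        means_init=quantiles.reshape(-1, 1),
        weights_init=np.full(n_components, 1.0 / n_components),
        precisions_init=np.full((n_components, 1), 1.0 / max(vals.var(), 1e-8)),
        max_iter=max_iter,
        tol=tol,
        reg_covar=1e-10,
        random_state=0,
    ).fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    above = np.flatnonzero(means > noise_floor)
    if len(above) == 0:
        return MafFFResult(0.0, True, means, sds, weights, -1)
    fetal = int(above[np.argmax(weights[above])])
    return MafFFResult(float(2.0 * means[fetal]), False, means, sds,
                       weights, fetal)
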