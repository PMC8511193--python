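"""Fetal-fraction regression: fitting, influence diagnostics, outlier
filtering, MAF-cutoff selection and prediction.

The model is a multivariate linear regression of a reference fetal fraction
(typically the chrY-based estimate on male-bearing pregnancies) on the
per-bin regional LD-ratios plus three sequencing confounders. Training
removes influential samples in a single pass using seven classical
single-case diagnostics (max |residual|, max |studentized residual|,
max |standardized residual|, leverage > 2(p+1)/n, |DFFITS| > 2*sqrt((p+1)/n),
max Cook's distance, max |COVRATIO - 1|) and refits, then the minor-allele
frequency cutoff used for the LD-ratio features is chosen by grid search on
the training Pearson correlation without outliers.

Throughout, p denotes the number of non-intercept coefficients, so p + 1
counts the intercept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .features import (CONFOUNDER_COLUMNS, FeatureVector, GenomeBins,
                       assemble_design_matrix, regional_ld_ratios)

__all__ = [
    "OLSFit",
    "DiagnosticsTable",
    "LDFFModel",
    "LDFFRegressor",
    "SingularDesignError",
    "fit_ols",
    "compute_diagnostics",
    "detect_outliers",
    "select_maf_cutoff",
    "train_ldff",
    "predict_ff",
    "MAF_GRID",
]

MAF_GRID = (0.15, 0.2, 0.25, 0.3)

MODEL_SCHEMA_VERSION = 1


class SingularDesignError(ValueError):
    """Raised when the regression design is rank deficient."""


@dataclass
class OLSFit:
    """Least-squares fit with the quantities diagnostics need."""

    intercept: float
    coef: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    s2: float  # RSS / (n - p - 1)
    hat: np.ndarray  # leverage h_ii of the intercept-augmented design
    rss: float
    n: int
    p: int  # non-intercept coefficients


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    # rank-revealing QR: pivots past the numerical rank name the culprits
    _, r, piv = linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = piv[np.count_nonzero(diag > tol):]
    return [names[j] for j in sorted(bad)]


def fit_ols(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
            column_names: list[str] | None = None) -> OLSFit:
    """Ordinary (optionally weighted) least squares with an intercept.

    ``weights`` is a per-sample weight hook; the default of all ones gives
    plain OLS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = x.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 samples (n={n}, k={k})")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < k + 1:
        names = ["intercept"] + (
            column_names if column_names is not None
            else [f"x{j}" for j in range(k)])
        bad = _collinear_columns(design, names)
        raise SingularDesignError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(bad))
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    res = sm.WLS(y, design, weights=w).fit()
    # leverage from the (weight-scaled) design via thin QR
    qmat, _ = np.linalg.qr(design * np.sqrt(w)[:, None])
    hat = (qmat**2).sum(axis=1)
    resid = y - res.fittedvalues
    rss = float(res.wresid @ res.wresid) if weights is not None else float(resid @ resid)
    return OLSFit(
        intercept=float(res.params[0]),
        coef=np.asarray(res.params[1:]),
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(resid),
        s2=rss / (n - k - 1),
        hat=np.asarray(hat),
        rss=rss,
        n=n,
        p=k,
    )


@dataclass
class DiagnosticsTable:
    """Per-sample single-case influence measures."""

    table: pd.DataFrame  # residual, standardized, studentized, leverage,
    #                      dffits, cooks_d, covratio

    def __getitem__(self, col):
        return self.table[col].to_numpy()


def compute_diagnostics(fit: OLSFit) -> DiagnosticsTable:
    """Closed-form leave-one-out influence diagnostics.

    Every column equals an explicit refit without the corresponding sample:
    the externally studentized residual uses the deleted variance estimate
    s_(i)^2 = (RSS - e_i^2/(1-h_ii)) / (n - p - 2), DFFITS scales it by
    leverage, Cook's distance measures the shift of fitted values and
    COVRATIO the change of the coefficient covariance determinant.
    """
    n, p = fit.n, fit.p
    if n <= p + 2:
        raise ValueError("need n > p + 2 for deleted-variance diagnostics")
    e = fit.residuals
    h = fit.hat
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("degenerate leverage: some h_ii = 1")
    s2 = fit.s2
    standardized = e / np.sqrt(s2 * (1.0 - h))
    s2_del = (fit.rss - e**2 / (1.0 - h)) / (n - p - 2)
    s2_del = np.maximum(s2_del, np.finfo(float).tiny)
    student = e / np.sqrt(s2_del * (1.0 - h))
    dffits = student * np.sqrt(h / (1.0 - h))
    cooks = e**2 * h / ((p + 1) * s2 * (1.0 - h) ** 2)
    covratio = (s2_del / s2) ** (p + 1) / (1.0 - h)
    return DiagnosticsTable(pd.DataFrame({
        "residual": e,
        "standardized": standardized,
        "studentized": student,
        "leverage": h,
        "dffits": dffits,
        "cooks_d": cooks,
        "covratio": covratio,
    }))


def detect_outliers(diag: DiagnosticsTable, n: int, p: int):
    """Single-pass union of the seven outlier criteria.

    Criteria 1-3, 6 and 7 each flag the single most extreme sample
    (max |residual|, |studentized|, |standardized|, Cook's D,
    |COVRATIO - 1|); criteria 4 and 5 flag every sample beyond the
    classical leverage and DFFITS thresholds.

    Returns (sorted flagged indices, per-criterion index lists).
    """
    t = diag.table
    by_criterion = {
        "max_abs_residual": [int(t["residual"].abs().idxmax())],
        "max_abs_studentized": [int(t["studentized"].abs().idxmax())],
        "max_abs_standardized": [int(t["standardized"].abs().idxmax())],
        "high_leverage": [int(i) for i in
                          np.flatnonzero(t["leverage"] > 2 * (p + 1) / n)],
        "high_dffits": [int(i) for i in
                        np.flatnonzero(t["dffits"].abs() > 2 * np.sqrt((p + 1) / n))],
        "max_cooks_d": [int(t["cooks_d"].idxmax())],
        "max_covratio_dist": [int((t["covratio"] - 1.0).abs().idxmax())],
    }
    union = sorted({i for ids in by_criterion.values() for i in ids})
    return union, by_criterion


class LDFFRegressor(BaseEstimator, RegressorMixin):
    """Linear fetal-fraction model with single-pass influence filtering.

    fit(X, y) performs an initial least-squares fit, flags the union of the
    seven single-case outlier criteria, removes those samples and refits.
    predict(X) returns the raw linear predictor; use ``clamp=True`` for the
    reportable estimate truncated to [0, 1].

    Parameters
    ----------
    remove_outliers : bool, default True
        Apply the single-pass seven-criterion filter before the final fit.
    sample_weight_hook : callable or None
        Optional function mapping (X, y) to per-sample weights; the default
        weighs every sample equally.
    """

    def __init__(self, remove_outliers: bool = True, sample_weight_hook=None):
        self.remove_outliers = remove_outliers
        self.sample_weight_hook = sample_weight_hook

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per element of y")
        weights = (self.sample_weight_hook(X, y)
                   if self.sample_weight_hook is not None else None)
        fit = fit_ols(X, y, weights=weights)
        outliers: list[int] = []
        by_criterion: dict = {}
        if self.remove_outliers:
            diag = compute_diagnostics(fit)
            outliers, by_criterion = detect_outliers(diag, fit.n, fit.p)
            self.initial_diagnostics_ = diag
            keep = np.setdiff1d(np.arange(len(y)), outliers)
            sub_w = None if weights is None else weights[keep]
            fit = fit_ols(X[keep], y[keep], weights=sub_w)
            y_in, fitted_in = y[keep], fit.fitted
        else:
            y_in, fitted_in = y, fit.fitted
        self.intercept_ = fit.intercept
        self.coef_ = fit.coef
        self.outlier_indices_ = np.asarray(outliers, dtype=int)
        self.outliers_by_criterion_ = by_criterion
        self.fit_ = fit
        self.n_features_in_ = X.shape[1]
        r = (float(stats.pearsonr(y_in, fitted_in)[0])
             if np.std(fitted_in) > 0 and np.std(y_in) > 0 else np.nan)
        self.training_r_ = r
        self.training_mae_ = float(np.mean(np.abs(y_in - fitted_in)))
        return self

    def predict(self, X, clamp: bool = False):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        raw = self.intercept_ + X @ self.coef_
        return np.clip(raw, 0.0, 1.0) if clamp else raw


@dataclass
class LDFFModel:
    """Serializable trained model: coefficients plus feature provenance."""

    intercept: float
    coefficients: np.ndarray
    column_names: list[str]
    maf_cutoff: float
    bin_fill_means: np.ndarray
    removed_outliers: list[str]
    training_summary: dict
    schema_version: int = MODEL_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "intercept": self.intercept,
            "coefficients": [float(c) for c in self.coefficients],
            "column_names": list(self.column_names),
            "maf_cutoff": self.maf_cutoff,
            "bin_fill_means": [None if np.isnan(v) else float(v)
                               for v in self.bin_fill_means],
            "removed_outliers": list(self.removed_outliers),
            "training_summary": self.training_summary,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDFFModel":
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        return cls(
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            column_names=list(d["column_names"]),
            maf_cutoff=float(d["maf_cutoff"]),
            bin_fill_means=np.array(
                [np.nan if v is None else v for v in d["bin_fill_means"]],
                dtype=float),
            removed_outliers=list(d["removed_outliers"]),
            training_summary=dict(d["training_summary"]),
        )


def _features_at_cutoff(tracks, confounders, sample_ids, bins, cutoff):
    feats = []
    for sid, track, conf in zip(sample_ids, tracks, confounders):
        feats.append(FeatureVector(
            sample_id=sid,
            ld_ratios=regional_ld_ratios(track, bins, cutoff),
            confounders=conf,
            maf_cutoff=cutoff,
        ))
    return feats


def _bin_fill_means(feats) -> np.ndarray:
    stacked = np.vstack([f.ld_ratios for f in feats])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)


def select_maf_cutoff(tracks, confounders, sample_ids, reference_ff,
                      bins: GenomeBins, grid=MAF_GRID):
    """Grid-search the MAF filtering cutoff for the LD-ratio features.

    For each cutoff the features are recomputed, the model fitted, outliers
    removed and refitted, and the training Pearson correlation and MAE
    (without outliers) recorded. The cutoff with the highest correlation
    wins; ties break to the lower MAE, then the smaller cutoff. A cutoff
    whose design is rank deficient is recorded as failed, never chosen.

    Returns (chosen cutoff, per-cutoff results DataFrame).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("cutoff grid is empty")
    y = np.asarray(reference_ff, dtype=float)
    rows = []
    fits = {}
    for cutoff in grid:
        feats = _features_at_cutoff(tracks, confounders, sample_ids, bins, cutoff)
        fill = _bin_fill_means(feats)
        try:
            x, cols = assemble_design_matrix(feats, bin_fill=fill,
                                             bin_ids=bins.bin_ids)
            est = LDFFRegressor().fit(x, y)
        except (SingularDesignError, ValueError) as exc:
            rows.append({"maf_cutoff": cutoff, "pearson_r": np.nan,
                         "mae": np.nan, "n_outliers": np.nan,
                         "status": f"failed: {exc}"})
            continue
        rows.append({"maf_cutoff": cutoff, "pearson_r": est.training_r_,
                     "mae": est.training_mae_,
                     "n_outliers": len(est.outlier_indices_), "status": "ok"})
        fits[cutoff] = (est, feats, fill, cols)
    table = pd.DataFrame(rows)
    ok = table[table["status"] == "ok"].dropna(subset=["pearson_r"])
    if ok.empty:
        raise SingularDesignError("every MAF cutoff failed to fit")
    ranked = ok.sort_values(["pearson_r", "mae", "maf_cutoff"],
                            ascending=[False, True, True], kind="stable")
    chosen = float(ranked.iloc[0]["maf_cutoff"])
    return chosen, table, fits[chosen]


def train_ldff(tracks, confounders, sample_ids, reference_ff,
               bins: GenomeBins, grid=MAF_GRID) -> LDFFModel:
    """Full training: cutoff grid search, outlier removal, final fit."""
    y = np.asarray(reference_ff, dtype=float)
    cutoff, table, (est, feats, fill, cols) = select_maf_cutoff(
        tracks, confounders, sample_ids, y, bins, grid)
    removed = [sample_ids[i] for i in est.outlier_indices_]
    summary = {
        "n": int(len(y) - len(removed)),
        "p": int(est.n_features_in_),
        "pearson_r": float(est.training_r_),
        "mae": float(est.training_mae_),
        "cutoff_grid": {f"{row['maf_cutoff']}": {
            "pearson_r": None if np.isnan(row["pearson_r"]) else float(row["pearson_r"]),
            "mae": None if np.isnan(row["mae"]) else float(row["mae"]),
            "status": row["status"],
        } for _, row in table.iterrows()},
    }
    return LDFFModel(
        intercept=est.intercept_,
        coefficients=est.coef_,
        column_names=cols,
        maf_cutoff=cutoff,
        bin_fill_means=fill,
        removed_outliers=removed,
        training_summary=summary,
    )


def predict_ff(model: LDFFModel, feature: FeatureVector):
    """Estimate the fetal fraction of one sample from its features.

    Returns (raw, clamped); the clamped value is truncated to [0, 1] (the
    reporting convention that sets female-fetus chrY estimates to zero at
    minimum), the raw value is kept for diagnostics.
    """
    if feature.maf_cutoff != model.maf_cutoff:
        raise ValueError(
            f"feature MAF cutoff {feature.maf_cutoff} does not match the "
            f"model's {model.maf_cutoff}")
    n_bins = len(model.column_names) - len(CONFOUNDER_COLUMNS)
    if len(feature.ld_ratios) != n_bins:
        raise ValueError("feature bin count does not match the model")
    row = feature.ld_ratios.astype(float).copy()
    nan = np.isnan(row)
    row[nan] = model.bin_fill_means[nan]
    if np.isnan(row).any():
        raise ValueError("missing bin ratio with no training fill value")
    c = feature.confounders
    x = np.concatenate(
        [row, [c.total_coverage, c.mq_gt0_coverage, c.pcr_dup_rate]])
    raw = float(model.intercept + x @ model.coefficients)
    return raw, float(np.clip(raw, 0.0, 1.0))
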