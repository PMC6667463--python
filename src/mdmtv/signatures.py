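"""Cross-region analysis of MDM signatures.

A signature matrix has one row per brain region and one column per MDM
dimension (the MTV derivative of one qMRI parameter).  Because the columns
carry heterogeneous units (s^-1 per MTV, p.u. per MTV, ...), every analysis
starts by z-scoring each column across regions; PCA is then an
eigendecomposition of the resulting correlation-scale covariance.  The
same standardization factors let per-cell dispersion (MAD across subjects)
be projected onto the PC basis.

Molecular features of regions (e.g. a lipid class fraction) are predicted
as a weighted linear sum of the R1 and MTsat derivatives, with the weights
fitted under leave-one-out cross-validation so each region's prediction
never sees its own feature value.  Correlations of PC scores against
external covariates (e.g. gene-module eigengenes) use simple regression
with an F-test and FDR correction over an explicitly declared family size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .aging import fdr_adjust
from .errors import DataError

__all__ = [
    "PCAResult",
    "FeaturePrediction",
    "zscore_columns",
    "signature_pca",
    "project_dispersion",
    "predict_feature_loo",
    "correlate_with_covariate",
    "correlate_with_covariates",
]


def zscore_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, sample SD 1 (ddof=1).

    Zero-variance columns are dropped with a warning; if every column is
    constant the matrix is unusable and a :class:`DataError` is raised.
    Idempotent: z-scoring twice equals z-scoring once.
    """
    matrix = matrix.astype(float)
    sds = matrix.std(ddof=1)
    constant = sds[(sds == 0) | sds.isna()].index.tolist()
    if len(constant) == len(matrix.columns):
        raise DataError("all columns are constant; nothing to standardize")
    if constant:
        warnings.warn(f"dropping zero-variance columns: {constant}", stacklevel=2)
        matrix = matrix.drop(columns=constant)
        sds = sds.drop(constant)
    return (matrix - matrix.mean()) / sds


@dataclass
class PCAResult:
    """Eigendecomposition of the z-scored signature matrix.

    ``loadings`` columns are orthonormal PC vectors over the original
    (retained) columns; ``scores`` are region projections; signs follow the
    deterministic convention that each PC's largest-magnitude loading is
    positive.  ``column_means``/``column_sds`` record the standardization
    applied, enabling dispersion projection.
    """

    loadings: pd.DataFrame  # index: variables, columns: PC1..PCk
    scores: pd.DataFrame  # index: regions, columns: PC1..PCk
    explained_variance_ratio: np.ndarray
    column_means: pd.Series
    column_sds: pd.Series
    sign_convention: str = "largest-loading-positive"


def _orient(v: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Flip a loading vector so its largest-magnitude entry is positive.

    Magnitude ties (within ``rtol`` of the max) resolve to the lowest index,
    so the convention is stable under last-ulp eigensolver differences.
    """
    mags = np.abs(v)
    j = int(np.flatnonzero(mags >= mags.max() * (1 - rtol))[0])
    return -v if v[j] < 0 else v


def signature_pca(matrix: pd.DataFrame) -> PCAResult:
    """Correlation-mode PCA: z-score columns, then eigendecompose.

    Variables are the MDM dimensions (columns), observations the regions
    (rows).  Requires at least 2 rows and 2 non-constant columns.
    """
    sds = matrix.astype(float).std(ddof=1)
    keep = sds[(sds > 0)].index
    Z = zscore_columns(matrix)
    if Z.shape[0] < 2 or Z.shape[1] < 2:
        raise DataError(
            f"need >= 2 rows and >= 2 non-constant columns, got {Z.shape}"
        )
    cov = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for k in range(eigvecs.shape[1]):  # deterministic sign
        eigvecs[:, k] = _orient(eigvecs[:, k])
    pcs = [f"PC{i + 1}" for i in range(eigvecs.shape[1])]
    loadings = pd.DataFrame(eigvecs, index=Z.columns, columns=pcs)
    scores = pd.DataFrame(Z.to_numpy() @ eigvecs, index=Z.index, columns=pcs)
    total = eigvals.sum()
    ratio = eigvals / total if total > 0 else eigvals
    means = matrix.astype(float).mean()[keep]
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=ratio,
        column_means=means,
        column_sds=sds[keep],
    )


def project_dispersion(mad_matrix: pd.DataFrame, pca: PCAResult) -> pd.DataFrame:
    """Project per-cell dispersion (MAD across subjects) onto the PC basis.

    Each MAD is divided by the column's standardization SD (same scale
    factor applied to the data; no re-centering — dispersions are spreads,
    not locations) and multiplied through the loading vectors.
    """
    cols = list(pca.loadings.index)
    missing = set(cols) - set(mad_matrix.columns)
    if missing or list(mad_matrix.index) != list(pca.scores.index):
        raise DataError("dispersion matrix is not aligned with the PCA input")
    scaled = mad_matrix[cols].astype(float) / pca.column_sds[cols]
    return pd.DataFrame(
        scaled.to_numpy() @ pca.loadings.to_numpy(),
        index=mad_matrix.index,
        columns=pca.loadings.columns,
    )


@dataclass
class FeaturePrediction:
    """Leave-one-out predictions of a per-region molecular feature."""

    predicted: pd.Series
    observed: pd.Series
    r2_loo: float
    r2_loo_adj: float
    weights: pd.Series  # full-data coefficients (intercept last)


def _ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    design = np.column_stack([X, np.ones(len(X))])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def predict_feature_loo(matrix: pd.DataFrame, feature: pd.Series) -> FeaturePrediction:
    """Predict a molecular feature from the dR1/dMTV and dMTsat/dMTV columns.

    For each region the weighted linear model (OLS with intercept) is fitted
    on all *other* regions and evaluated on the held-out one; the quality
    measure is the R^2 of LOO-predicted vs observed values, adjusted for the
    number of predictors.  Collinear predictors fall back to the
    minimum-norm solution with a warning.
    """
    if len(matrix) < 4:
        raise DataError(f"need >= 4 regions for leave-one-out, got {len(matrix)}")
    feature = feature.reindex(matrix.index)
    if feature.isna().any():
        raise DataError("feature not aligned with matrix rows (NaN after reindex)")
    X = matrix.to_numpy(dtype=float)
    y = feature.to_numpy(dtype=float)
    n = len(y)
    if np.linalg.matrix_rank(np.column_stack([X, np.ones(n)])) < X.shape[1] + 1:
        warnings.warn("collinear predictors: minimum-norm weights", stacklevel=2)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        coef = _ols_fit(X[keep], y[keep])
        preds[i] = X[i] @ coef[:-1] + coef[-1]
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("feature has zero variance")
    r2 = 1.0 - ss_res / ss_tot
    p = X.shape[1]
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    full = _ols_fit(X, y)
    return FeaturePrediction(
        predicted=pd.Series(preds, index=matrix.index, name="predicted"),
        observed=feature,
        r2_loo=r2,
        r2_loo_adj=r2_adj,
        weights=pd.Series(full, index=[*matrix.columns, "intercept"]),
    )


def correlate_with_covariate(
    scores, covariate, n_comparisons: int = 1
) -> tuple[float, float, float]:
    """Simple regression of a covariate on region scores, with FDR context.

    Returns ``(adjusted R^2, p, q)`` where p is the F-test p-value of the
    regression and q the Benjamini-Hochberg value treating this test as one
    member of a declared family of ``n_comparisons`` tests (unseen members
    counted at p = 1, i.e. q = min(1, p * n_comparisons)).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need aligned vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero-variance input")
    n = len(x)
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    p = float(res.pvalue)  # t-test on the slope == F-test for simple regression
    q = float(min(1.0, p * n_comparisons))
    return float(r2_adj), p, q


def correlate_with_covariates(
    scores: pd.Series, covariates: pd.DataFrame, n_comparisons: int | None = None
) -> pd.DataFrame:
    """Regress every covariate column on the scores; BH-correct jointly.

    ``n_comparisons`` may declare a family larger than the supplied columns
    (e.g. the 57-comparison family when covariates are split across calls);
    the unseen members enter the step-up at p = 1.
    """
    scores = scores.reindex(covariates.index)
    if scores.isna().any():
        raise DataError("scores not aligned with covariate rows")
    rows = []
    for name in covariates.columns:
        r2_adj, p, _ = correlate_with_covariate(scores, covariates[name], 1)
        rows.append(dict(covariate=name, r2_adj=r2_adj, p=p))
    out = pd.DataFrame(rows)
    family = len(out) if n_comparisons is None else int(n_comparisons)
    if family < len(out):
        raise DataError("declared family smaller than the number of tests")
    padded = np.concatenate([out["p"].to_numpy(), np.ones(family - len(out))])
    out["q"] = fdr_adjust(padded)[: len(out)]
    return out
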