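"""Immune-cell fraction estimation by linear nu-support-vector regression.

Each bulk profile is regressed on the reference signature over their shared
genes; the mixture is z-scored and the signature standardized globally (one
mean and one standard deviation for the whole matrix), which keeps the
relative scale of the cell-type columns so that coefficients stay
proportional to mixing fractions. A small grid of nu values is tried and the
fit with the lowest reconstruction RMSE wins. Negative coefficients are
clipped to zero and the rest renormalized to proportions, the convention of
signature-based deconvolution of relative immune content.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .containers import CellFractionTable, ExpressionMatrix, SignatureMatrix

DEFAULT_NUS = (0.25, 0.5, 0.75)


def _zscore(x: np.ndarray, axis: int = 0) -> np.ndarray:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    return (x - mu) / np.where(sd > 0, sd, 1.0)


def nusvr_deconvolve(mixture: np.ndarray, signature: SignatureMatrix,
                     nus: tuple[float, ...] = DEFAULT_NUS,
                     ) -> tuple[np.ndarray, float, float]:
    """Estimate cell fractions for one bulk profile.

    ``mixture`` must already be restricted to (and ordered like) the
    signature genes. Returns (fractions, rmse, pearson_r); all-nonpositive
    raw coefficients yield an all-zero row with a warning.
    """
    mixture = np.asarray(mixture, dtype=float)
    S = signature.values.to_numpy(dtype=float)
    if mixture.shape[0] != S.shape[0]:
        raise ValueError("mixture length does not match signature genes")
    if S.shape[0] < 2 * S.shape[1]:
        raise ValueError("need at least 2x more genes than cell types")
    y = _zscore(mixture[:, None], axis=0).ravel()
    sd = S.std()
    X = (S - S.mean()) / (sd if sd > 0 else 1.0)  # global standardization

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for nu in nus:
        model = NuSVR(kernel="linear", nu=nu, C=1.0, tol=1e-4)
        model.fit(X, y)
        coef = model.coef_.ravel()
        recon = X @ coef + model.intercept_
        rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, coef, recon)
    rmse, coef, recon = best
    r = float(np.corrcoef(recon, y)[0, 1]) if np.std(recon) > 0 else 0.0
    w = np.maximum(coef, 0.0)
    total = w.sum()
    if total <= 0:
        warnings.warn("all nu-SVR coefficients nonpositive; returning zeros")
        return np.zeros_like(w), rmse, r
    return w / total, rmse, r


def deconvolve_matrix(matrix: ExpressionMatrix, signature: SignatureMatrix,
                      nus: tuple[float, ...] = DEFAULT_NUS) -> CellFractionTable:
    """Apply nu-SVR deconvolution to every sample of a TPM matrix."""
    shared = signature.gene_ids.intersection(matrix.gene_ids)
    if len(shared) < 0.5 * len(signature.gene_ids):
        missing = signature.gene_ids.difference(matrix.gene_ids)
        raise ValueError(
            f"only {len(shared)}/{len(signature.gene_ids)} signature genes "
            f"present in expression; missing e.g. {list(missing[:10])}")
    sig = SignatureMatrix(signature.values.loc[shared])
    expr = matrix.values.loc[shared].to_numpy(dtype=float)
    fracs, rmses, rs = [], [], []
    for j in range(expr.shape[1]):
        f, rmse, r = nusvr_deconvolve(expr[:, j], sig, nus)
        fracs.append(f)
        rmses.append(rmse)
        rs.append(r)
    fractions = pd.DataFrame(np.vstack(fracs), index=matrix.sample_ids,
                             columns=signature.cell_type_ids)
    return CellFractionTable(
        fractions=fractions,
        rmse=pd.Series(rmses, index=matrix.sample_ids, name="rmse"),
        pearson_r=pd.Series(rs, index=matrix.sample_ids, name="pearson_r"),
    )
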