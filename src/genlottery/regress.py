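"""Cluster-robust linear-regression primitives shared by all estimators.

Small, explicit numpy implementations: OLS via least squares, the
cluster-robust sandwich variance with the finite-sample correction
G/(G-1) * (n-1)/(n-k), Frisch-Waugh-Lovell partialling, and within-group
demeaning. statsmodels reproduces these numbers and serves as the
cross-check in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class EstimationError(RuntimeError):
    pass


class RankDeficiencyError(EstimationError):
    pass


def factorize_clusters(*arrays) -> np.ndarray:
    """Integer codes for the intersection of one or more cluster variables."""
    if len(arrays) == 1:
        codes, _ = pd.factorize(np.asarray(arrays[0]))
        return codes
    frame = pd.DataFrame({i: np.asarray(a) for i, a in enumerate(arrays)})
    return frame.groupby(list(frame.columns), sort=False).ngroup().to_numpy()


def check_rank(X: np.ndarray, names=None) -> None:
    """Raise RankDeficiencyError naming (approximately) collinear columns."""
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank >= k:
        return
    # name the columns a pivoted QR leaves out of the independent set
    from scipy.linalg import qr

    _, _, piv = qr(X, mode="economic", pivoting=True)
    bad = sorted(piv[rank:])
    labels = [names[j] if names is not None else f"col{j}" for j in bad]
    raise RankDeficiencyError(f"design matrix is rank deficient; offending columns: {labels}")


def cluster_ols(y, X, clusters=None, k_absorbed: int = 0):
    """OLS of y on X with a cluster-robust sandwich covariance.

    ``clusters`` are integer codes (None means one observation per cluster,
    i.e. heteroskedasticity-robust). ``k_absorbed`` adds degrees of freedom
    consumed outside X (absorbed fixed effects) to the small-sample
    correction. Returns (beta, cov, n, n_clusters).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, k = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    u = y - X @ beta
    if clusters is None:
        clusters = np.arange(n)
    codes = np.asarray(clusters)
    if codes.dtype.kind not in "iu":
        codes = factorize_clusters(codes)
    g = int(codes.max()) + 1 if len(codes) else 0
    xu = X * u[:, None]
    sums = np.zeros((g, k))
    np.add.at(sums, codes, xu)
    meat = sums.T @ sums
    bread = np.linalg.pinv(X.T @ X)
    k_eff = k + k_absorbed
    denom = max(n - k_eff, 1)
    corr = (g / max(g - 1, 1)) * ((n - 1) / denom)
    cov = corr * bread @ meat @ bread
    # exact fits can leave tiny negative diagonal round-off
    d = np.einsum("ii->i", cov)
    d[d < 0] = 0.0
    return beta, cov, n, g


def partial_out(mat, covariates=None):
    """Residualize each column of ``mat`` on [1, covariates] (FWL step)."""
    mat = np.asarray(mat, dtype=float)
    one_d = mat.ndim == 1
    M = mat[:, None] if one_d else mat
    n = M.shape[0]
    C = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)
        cov = cov[:, None] if cov.ndim == 1 else cov
        C = np.hstack([C, cov])
    coef, _, _, _ = np.linalg.lstsq(C, M, rcond=None)
    res = M - C @ coef
    return res[:, 0] if one_d else res


def demean_within(mat, groups):
    """Subtract group means from each column of ``mat``."""
    mat = np.asarray(mat, dtype=float)
    one_d = mat.ndim == 1
    M = mat[:, None] if one_d else mat
    codes = np.asarray(groups)
    if codes.dtype.kind not in "iu":
        codes = factorize_clusters(codes)
    g = int(codes.max()) + 1
    sums = np.zeros((g, M.shape[1]))
    np.add.at(sums, codes, M)
    counts = np.bincount(codes, minlength=g).astype(float)
    means = sums / counts[:, None]
    out = M - means[codes]
    return out[:, 0] if one_d else out
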