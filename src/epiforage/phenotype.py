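"""Canonical correlation phenotyping of parameters against behaviour.

Canonical correlation (variates) analysis finds paired linear combinations
of two multivariate sets — here, subject-level parameter estimates and
behavioural measures — that are maximally correlated. Columns are first
normalised to mean zero and unit sum of squares; correlations are the
singular values of the whitened cross-covariance, and the dimensionality is
assessed with Bartlett's chi-squared statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CVAResult:
    """Canonical correlations, vectors, variates and significance tests.

    ``chi2[d]`` tests the null that canonical correlations ``d+1`` onward
    are zero (Bartlett), with ``log_p`` the log p-values in nats.
    """

    correlations: np.ndarray  # (k,) nonincreasing in [0, 1]
    x_vectors: np.ndarray  # (p, k)
    y_vectors: np.ndarray  # (q, k)
    x_variates: np.ndarray  # (n, k)
    y_variates: np.ndarray  # (n, k)
    chi2: np.ndarray  # (k,)
    df: np.ndarray  # (k,) degrees of freedom per test
    log_p: np.ndarray  # (k,) in nats
    x_names: tuple[str, ...] = ()
    y_names: tuple[str, ...] = ()

    def n_significant(self, alpha: float = 0.05) -> int:
        """Number of leading dimensions significant at ``alpha``."""
        n = 0
        for lp in self.log_p:
            if lp < np.log(alpha):
                n += 1
            else:
                break
        return n


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    X = np.asarray(X, dtype=float)
    return X, tuple(f"col{i}" for i in range(X.shape[1]))


def standardize(X) -> np.ndarray:
    """Normalise each column to mean zero and sum of squares one.

    Accepts an array or DataFrame; rejects constant columns by name.
    """
    M, names = _as_matrix(X)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    M = M - M.mean(axis=0)
    ss = np.sqrt((M**2).sum(axis=0))
    bad = np.where(ss == 0)[0]
    if len(bad):
        raise ValueError(f"constant column(s): {[names[i] for i in bad]}")
    return M / ss


def cva(X, Y, ridge: float = 0.0) -> CVAResult:
    """Canonical correlation analysis of two matrices over the same subjects.

    Both sets are standardised internally. Correlations come from the SVD of
    ``Sxx^{-1/2} Sxy Syy^{-1/2}``; rank-deficient within-set covariances are
    ridge-regularised (1e-8) with a warning. Sign indeterminacy is fixed by
    making the largest-magnitude loading of each x-vector positive.
    """
    import warnings

    Xm, x_names = _as_matrix(X)
    Ym, y_names = _as_matrix(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = Xm.shape
    q = Ym.shape[1]
    if n <= p + q:
        warnings.warn(
            f"n={n} subjects is small for p+q={p + q} variables", stacklevel=2
        )
    Xs = standardize(Xm)
    Ys = standardize(Ym)
    Sxx = Xs.T @ Xs
    Syy = Ys.T @ Ys
    Sxy = Xs.T @ Ys

    def inv_sqrt(S, label):
        nonlocal ridge
        w, V = np.linalg.eigh(S)
        if w.min() < 1e-10 and ridge == 0.0:
            warnings.warn(
                f"rank-deficient within-set covariance ({label}); adding ridge 1e-8",
                stacklevel=3,
            )
            ridge = 1e-8
        w = w + ridge
        return V @ np.diag(1.0 / np.sqrt(w)) @ V.T

    Kx = inv_sqrt(Sxx, "X")
    Ky = inv_sqrt(Syy, "Y")
    U, s, Vt = np.linalg.svd(Kx @ Sxy @ Ky)
    k = min(p, q)
    r = np.clip(s[:k], 0.0, 1.0)
    a = Kx @ U[:, :k]
    b = Ky @ Vt.T[:, :k]
    # fix sign indeterminacy: largest-magnitude x-loading positive
    for i in range(k):
        lead = np.argmax(np.abs(a[:, i]))
        if a[lead, i] < 0:
            a[:, i] *= -1
            b[:, i] *= -1
    # Bartlett's sequential chi-squared tests
    scale = n - 1 - (p + q + 1) / 2.0
    chi2 = np.zeros(k)
    df = np.zeros(k)
    log_p = np.zeros(k)
    with np.errstate(divide="ignore"):
        log1mr2 = np.log1p(-(r**2))
    for d in range(k):
        chi2[d] = -scale * log1mr2[d:].sum()
        df[d] = (p - d) * (q - d)
        log_p[d] = stats.chi2.logsf(chi2[d], df[d])
    return CVAResult(
        correlations=r,
        x_vectors=a,
        y_vectors=b,
        x_variates=Xs @ a,
        y_variates=Ys @ b,
        chi2=chi2,
        df=df,
        log_p=log_p,
        x_names=x_names,
        y_names=y_names,
    )
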