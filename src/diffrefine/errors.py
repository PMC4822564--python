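"""Parameter covariance and propagation to model-state and unit-cell e.s.d.s.

After convergence the parameter covariance is estimated by inverting the
normal matrix, cov = s^2 (J^T W J)^{-1} with the variance factor
s^2 = L_min / (m - p).  The factor is applied even under statistical
weighting, so miscalibrated centroid variances inflate the error estimates
consistently.  Cell e.s.d.s follow by first-order propagation through the
map from free metrical parameters to real-space cell parameters; symmetry
constraints are never enforced explicitly — a tetragonal cell yields exactly
zero angle e.s.d.s and identical a and b e.s.d.s purely because the
constrained directions have zero gradient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse

from .parameterisation import CellParameterisation

__all__ = ["parameter_covariance", "propagate_cell_esds", "correlation_matrix"]


def parameter_covariance(
    J: np.ndarray, W: np.ndarray, residuals: np.ndarray, n_params: int | None = None
) -> np.ndarray:
    """Covariance of the refined parameters from the normal matrix.

    ``W`` may be the weight vector (diagonal) or a full matrix.  Requires
    more residual terms than parameters.
    """
    sparse_J = scipy.sparse.issparse(J)
    if not sparse_J:
        J = np.asarray(J, dtype=float)
    m, p = J.shape
    if n_params is None:
        n_params = p
    if m <= n_params:
        raise ValueError("need more residuals than parameters for a variance estimate")
    W = np.asarray(W, dtype=float)
    if sparse_J:
        if W.ndim != 1:
            raise ValueError("sparse Jacobian requires a diagonal weight vector")
        N = np.asarray((J.T @ scipy.sparse.diags(W) @ J).todense())
        L = float(np.sum(W * residuals**2))
    elif W.ndim == 1:
        JTW = J.T * W
        L = float(np.sum(W * residuals**2))
        N = JTW @ J
    else:
        JTW = J.T @ W
        L = float(residuals @ W @ residuals)
        N = JTW @ J
    try:
        N_inv = np.linalg.inv(N)
    except np.linalg.LinAlgError as exc:
        # report the most null directions to help diagnose degeneracy
        vals, vecs = np.linalg.eigh(N)
        worst = vecs[:, np.argsort(vals)[:3]].T
        raise ValueError(
            f"singular normal matrix; near-null parameter combinations: {np.round(worst, 3)}"
        ) from exc
    s_sq = L / (m - n_params)
    return s_sq * N_inv


def propagate_cell_esds(
    cov_cell_block: np.ndarray, cell_parameterisation: CellParameterisation
) -> tuple[float, float, float, float, float, float]:
    """E.s.d.s of (a, b, c, alpha, beta, gamma) from the free-metrical covariance.

    var(cell_j) = g^T cov g with g the gradient of cell parameter j with
    respect to the free metrical parameters, evaluated by central differences
    of the cell-composition map.  Cell quantities fixed by symmetry have zero
    gradient and therefore exactly zero e.s.d.
    """
    cp = cell_parameterisation
    cov = np.atleast_2d(np.asarray(cov_cell_block, dtype=float))
    n = cp.num_total
    if cov.shape != (n, n):
        raise ValueError(f"covariance block is {cov.shape}, expected {(n, n)}")
    values = cp.get_params(only_free=False)
    grads = np.zeros((6, n))
    for i in range(n):
        step = max(abs(values[i]), 1e-4) * 1e-8
        lo, hi = values.copy(), values.copy()
        lo[i] -= step
        hi[i] += step
        c_lo = np.array(cp.cell_from_params(lo))
        c_hi = np.array(cp.cell_from_params(hi))
        grads[:, i] = (c_hi - c_lo) / (2.0 * step)
    variances = np.einsum("ji,ik,jk->j", grads, cov, grads)
    return tuple(np.sqrt(np.maximum(variances, 0.0)))


def correlation_matrix(J: np.ndarray, W: np.ndarray, labels: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation between weighted Jacobian columns.

    The columns of sqrt(W) J describe the sensitivity of the weighted
    residuals to each parameter; their pairwise correlations show which
    parameters have nearly indistinguishable effects (the corrgram display).
    Zero-variance columns get correlation 0 with a warning.
    """
    if J.shape[1] < 2:
        raise ValueError("need at least 2 free parameters for a correlation matrix")
    W = np.asarray(W, dtype=float)
    m = J.shape[0]
    if W.ndim == 1:
        # sufficient statistics of the sqrt(W)-scaled columns; works for
        # sparse J without ever densifying it
        sw = np.sqrt(W)
        if scipy.sparse.issparse(J):
            S = np.asarray((J.T @ scipy.sparse.diags(W) @ J).todense())
            colsum = np.asarray(J.T @ sw).ravel()
        else:
            J = np.asarray(J, dtype=float)
            Jw = J * sw[:, None]
            S = Jw.T @ Jw
            colsum = Jw.sum(axis=0)
        cov = S - np.outer(colsum, colsum) / m
    else:
        Jw = np.linalg.cholesky(W) @ np.asarray(J, dtype=float)
        centred = Jw - Jw.mean(axis=0)
        cov = centred.T @ centred
    var = np.diag(cov).copy()
    zero = var <= 0
    if np.any(zero):
        import warnings

        warnings.warn(f"{int(zero.sum())} zero-variance Jacobian column(s); correlation set to 0")
    safe = np.sqrt(np.where(zero, 1.0, var))
    C = cov / np.outer(safe, safe)
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    if labels is None:
        labels = [f"p{i}" for i in range(J.shape[1])]
    return pd.DataFrame(C, index=labels, columns=labels)
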