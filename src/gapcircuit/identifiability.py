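"""Practical identifiability: asymptotic confidence intervals and
collinearity-index subset scanning.

Both analyses work on the sensitivity (residual Jacobian) matrix J of
size N x m — the partial derivatives of the N transformed residuals
with respect to the m free parameters, evaluated at the fitted point.
The (1-alpha) joint confidence region is the ellipsoid

    (theta - theta_hat)^T J^T J (theta - theta_hat)
        <= m/(N-m) * S(theta_hat) * F_{alpha; m, N-m}

whose axis projection gives the per-parameter intervals reported here;
a parameter whose sign matters is called identifiable when its interval
is bounded away from zero.  The collinearity index of a parameter
subset is gamma_k = 1/sqrt(lambda_min) of the corresponding submatrix
of the column-normalised J^T J; subsets with gamma above a threshold
(default 4) are jointly poorly identifiable.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "residual_jacobian", "confidence_intervals", "confidence_ellipsoid",
    "collinearity_index", "scan_collinear_subsets",
]

#: gamma reported for an exactly singular subset.
GAMMA_CAP = 1.0e8


def residual_jacobian(residual_fn, theta: np.ndarray,
                      rel_step: float = 1.0e-4,
                      abs_step: float = 1.0e-8) -> np.ndarray:
    """Central-difference Jacobian of the residual vector w.r.t. theta.

    ``residual_fn(theta)`` must return the (variance-stabilised)
    residual vector.  The step per coordinate is
    ``rel_step * |theta_i| + abs_step``.
    """
    theta = np.asarray(theta, dtype=float)
    r0 = np.asarray(residual_fn(theta), dtype=float)
    if not np.isfinite(r0).all():
        raise ValueError("non-finite residuals at the expansion point")
    jac = np.empty((r0.size, theta.size))
    for i in range(theta.size):
        h = rel_step * abs(theta[i]) + abs_step
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        rp = np.asarray(residual_fn(tp), dtype=float)
        rm = np.asarray(residual_fn(tm), dtype=float)
        if not (np.isfinite(rp).all() and np.isfinite(rm).all()):
            raise ValueError(
                f"non-finite residuals when perturbing parameter {i}")
        jac[:, i] = (rp - rm) / (2.0 * h)
    return jac


def confidence_intervals(jacobian: np.ndarray, theta: np.ndarray,
                         s_hat: float, alpha: float = 0.05,
                         names: list[str] | None = None) -> pd.DataFrame:
    """Axis projections of the joint confidence ellipsoid per parameter.

    Half-width_i = sqrt( m/(N-m) * S(theta_hat) * F_{alpha,m,N-m}
                         * [(J^T J)^-1]_ii ).
    Parameters involved in a (numerically) singular J^T J get infinite
    intervals and are flagged non-identifiable.
    """
    jac = np.asarray(jacobian, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n, m = jac.shape
    if n <= m:
        raise ValueError(f"need N > m, got N={n}, m={m}")
    f_quant = stats.f.ppf(1.0 - alpha, m, n - m)
    scale = m / (n - m) * s_hat * f_quant

    # column-normalise before inversion: parameter scales span many
    # orders of magnitude and would otherwise swamp the rank decision.
    # [(J^T J)^-1]_ii = [(Jhat^T Jhat)^-1]_ii / norm_i^2 exactly.
    norms = np.linalg.norm(jac, axis=0)
    zero_col = norms == 0.0
    safe = np.where(zero_col, 1.0, norms)
    jtj_hat = (jac / safe).T @ (jac / safe)
    eigval, eigvec = np.linalg.eigh(jtj_hat)
    tol = m * np.finfo(float).eps * max(eigval.max(), 1.0)
    singular = eigval <= tol
    null_mask = zero_col.copy()
    if singular.any():
        null_mask |= (np.abs(eigvec[:, singular]) > 1.0e-8).any(axis=1)
    inv_eig = np.where(singular, 0.0, 1.0 / np.where(singular, 1.0,
                                                     eigval))
    diag_inv = np.einsum("ik,k,ik->i", eigvec, inv_eig, eigvec)
    half = np.sqrt(scale * diag_inv) / safe
    half[null_mask] = np.inf

    lo = theta - half
    hi = theta + half
    if names is None:
        names = [f"p{i}" for i in range(m)]
    return pd.DataFrame({
        "parameter": names,
        "estimate": theta,
        "a": lo,
        "b": hi,
        "identifiable": (lo > 0) | (hi < 0),
        "alpha": alpha,
    })


def confidence_ellipsoid(jacobian: np.ndarray, s_hat: float,
                         alpha: float = 0.05):
    """(J^T J, radius^2) of the joint ellipsoid: d^T JtJ d <= radius^2."""
    jac = np.asarray(jacobian, dtype=float)
    n, m = jac.shape
    if n <= m:
        raise ValueError("need N > m")
    radius2 = m / (n - m) * s_hat * stats.f.ppf(1.0 - alpha, m, n - m)
    return jac.T @ jac, radius2


def _normalized(jacobian: np.ndarray) -> np.ndarray:
    jac = np.asarray(jacobian, dtype=float)
    norms = np.linalg.norm(jac, axis=0)
    if (norms == 0).any():
        bad = list(np.flatnonzero(norms == 0))
        raise ValueError(f"zero-norm sensitivity columns {bad}; "
                         "collinearity undefined")
    return jac / norms


def collinearity_index(jacobian: np.ndarray,
                       subset: list[int] | tuple[int, ...]) -> float:
    """gamma = 1/sqrt(min eigenvalue) of the normalised subset J^T J.

    1 for orthogonal columns; grows without bound as the subset
    approaches linear dependence (capped at 1e8).
    """
    subset = tuple(subset)
    if len(subset) < 2:
        raise ValueError("subset must have >= 2 parameters")
    sub = _normalized(jacobian)[:, subset]
    lam = np.linalg.eigvalsh(sub.T @ sub)[0]
    if lam <= 1.0 / GAMMA_CAP ** 2:
        return GAMMA_CAP
    return float(1.0 / np.sqrt(lam))


def scan_collinear_subsets(jacobian: np.ndarray,
                           names: list[str] | None = None,
                           k_max: int = 3,
                           threshold: float = 4.0) -> pd.DataFrame:
    """All parameter subsets of size 2..k_max with gamma > threshold.

    Exhaustive enumeration; sorted by gamma descending.
    """
    jac = _normalized(jacobian)
    m = jac.shape[1]
    if names is None:
        names = [f"p{i}" for i in range(m)]
    gram = jac.T @ jac
    rows = []
    for k in range(2, k_max + 1):
        for subset in combinations(range(m), k):
            sub = gram[np.ix_(subset, subset)]
            lam = np.linalg.eigvalsh(sub)[0]
            gamma = GAMMA_CAP if lam <= 1.0 / GAMMA_CAP ** 2 \
                else float(1.0 / np.sqrt(lam))
            if gamma > threshold:
                rows.append({
                    "subset": tuple(names[i] for i in subset),
                    "size": k,
                    "gamma": gamma,
                })
    report = pd.DataFrame(rows, columns=["subset", "size", "gamma"])
    return report.sort_values("gamma", ascending=False,
                              ignore_index=True)
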