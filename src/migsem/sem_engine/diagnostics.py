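"""Fit diagnostics: variance-explained ratios, collinearity, convergence."""

from __future__ import annotations

import numpy as np

__all__ = ["r_squared", "vif", "gelman_rubin"]


def r_squared(
    var_fixed: float, var_random_sum: float, var_resid: float
) -> tuple[float, float]:
    """Marginal and conditional R-squared for a Gaussian mixed model.

    ``R2m = var_fixed / total`` and ``R2c = (var_fixed + var_random) /
    total`` with ``total = var_fixed + var_random + var_resid``
    (Nakagawa-Schielzeth variance partitioning).
    """
    for name, v in (
        ("var_fixed", var_fixed),
        ("var_random_sum", var_random_sum),
        ("var_resid", var_resid),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    total = var_fixed + var_random_sum + var_resid
    if total == 0:
        raise ValueError("all variance components are zero")
    return var_fixed / total, (var_fixed + var_random_sum) / total


def vif(X: np.ndarray, names: list[str] | None = None) -> dict[str, float]:
    """Variance inflation factors, ``1 / (1 - R2_j)`` per predictor.

    Each column is regressed (with intercept) on the remaining columns.
    Perfect collinearity is reported as ``inf``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    out: dict[str, float] = {}
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError(f"zero-variance predictor: {names[j]}")
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[names[j]] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def gelman_rubin(chains: np.ndarray) -> float | np.ndarray:
    """Split-R-hat potential scale reduction factor.

    *chains* has shape ``(n_chains, n_draws)`` or ``(n_chains, n_draws,
    n_params)``; at least two chains of equal length are required. Each
    chain is split in half before computing the classical between/within
    variance ratio. Chains that are all identical constants give 1.0 by
    the limit convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        return float(gelman_rubin(chains[:, :, None])[0])
    if chains.ndim != 3:
        raise ValueError("chains must be 2- or 3-dimensional")
    m, n, k = chains.shape
    if m < 2:
        raise ValueError("at least 2 chains are required")
    if n < 4:
        raise ValueError("chains too short to split")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m2, n2 = split.shape[0], split.shape[1]

    means = split.mean(axis=1)  # (m2, k)
    W = split.var(axis=1, ddof=1).mean(axis=0)  # (k,)
    B_over_n = means.var(axis=0, ddof=1)  # (k,)
    rhat = np.ones(k)
    nz = W > 0
    var_plus = (n2 - 1) / n2 * W[nz] + B_over_n[nz]
    rhat[nz] = np.sqrt(var_plus / W[nz])
    # constant-within but different-between chains: truly divergent
    rhat[(~nz) & (B_over_n > 0)] = np.inf
    return rhat
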