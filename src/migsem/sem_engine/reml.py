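"""REML likelihood backend for the phylogenetic mixed model.

The model is ``y = X b + u_phylo + u_species + u_paper + u_year + e``
with ``u_phylo ~ N(0, s2_phylo * C_corr)`` across species (``C_corr`` the
phylogenetic correlation matrix) and the other intercepts i.i.d. Writing
``u_phylo = L v`` with ``C_corr = L L'`` reduces everything to a single
tall i.i.d. random-effect design ``U`` with a diagonal covariance, so the
marginal covariance is ``V = s2_e (I + U G U')`` and all REML quantities
follow from q x q linear algebra via the Woodbury identity (``q`` = total
number of random levels), independent of the number of observations once
the cross-products are formed.

Variance ratios are profiled on the log scale; the residual variance has
a closed-form profile. Intervals for the fixed effects are Wald intervals
from the GLS covariance at the REML variance estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

__all__ = ["RandomDesign", "build_random_design", "RemlResult", "reml_fit"]

logger = logging.getLogger(__name__)

_LOG_RATIO_BOUNDS = (np.log(1e-8), np.log(1e6))


@dataclass
class RandomDesign:
    """Stacked random-effect columns with named blocks."""

    U: np.ndarray  # (n, q)
    block_names: list[str]
    block_slices: list[slice]

    @property
    def q(self) -> int:
        return self.U.shape[1]

    def column_ratios(self, gamma: np.ndarray) -> np.ndarray:
        g = np.empty(self.q)
        for val, sl in zip(gamma, self.block_slices):
            g[sl] = val
        return g


def _indicator(idx: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(idx), n_levels))
    Z[np.arange(len(idx)), idx] = 1.0
    return Z


def build_random_design(
    species_idx: np.ndarray,
    n_species: int,
    paper_idx: np.ndarray,
    n_papers: int,
    year_idx: np.ndarray,
    n_years: int,
    phylo_corr: np.ndarray | None,
) -> RandomDesign:
    """Assemble ``U = [Z_sp L | Z_sp | Z_paper | Z_year]``.

    With ``phylo_corr=None`` the phylogenetic block is omitted.
    """
    Z_sp = _indicator(species_idx, n_species)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if phylo_corr is not None:
        if phylo_corr.shape != (n_species, n_species):
            raise ValueError("phylogenetic correlation matrix does not match species set")
        L = linalg.cholesky(phylo_corr + 1e-10 * np.eye(n_species), lower=True)
        blocks.append(Z_sp @ L)
        names.append("phylo")
    blocks.append(Z_sp)
    names.append("species")
    blocks.append(_indicator(paper_idx, n_papers))
    names.append("paper")
    blocks.append(_indicator(year_idx, n_years))
    names.append("year")

    slices: list[slice] = []
    start = 0
    for b in blocks:
        slices.append(slice(start, start + b.shape[1]))
        start += b.shape[1]
    return RandomDesign(U=np.hstack(blocks), block_names=names, block_slices=slices)


@dataclass
class RemlResult:
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    sigma2: dict[str, float]  # per-block variances plus "resid"
    converged: bool
    n_obs: int
    n_fixed: int
    reml_criterion: float


class _RemlWorkspace:
    """Cross-products shared across objective evaluations."""

    def __init__(self, y: np.ndarray, X: np.ndarray, design: RandomDesign):
        self.n, self.p = X.shape
        self.design = design
        U = design.U
        self.UtU = U.T @ U
        self.UtX = U.T @ X
        self.Uty = U.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def profile(self, log_gamma: np.ndarray):
        """Return (criterion, beta, XtViX, sigma2_e) at variance ratios."""
        gamma = np.exp(log_gamma)
        g = self.design.column_ratios(gamma)
        s = np.sqrt(g)
        M = self.UtU * np.outer(s, s)
        M[np.diag_indices_from(M)] += 1.0
        try:
            cf = linalg.cho_factor(M, lower=True)
        except linalg.LinAlgError:
            return np.inf, None, None, None
        logdet_V0 = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))

        sUtX = s[:, None] * self.UtX
        sUty = s * self.Uty
        MinvX = linalg.cho_solve(cf, sUtX)
        Minvy = linalg.cho_solve(cf, sUty)
        XtV0X = self.XtX - sUtX.T @ MinvX
        XtV0y = self.Xty - sUtX.T @ Minvy
        ytV0y = self.yty - float(sUty @ Minvy)
        try:
            cfx = linalg.cho_factor(XtV0X, lower=True)
        except linalg.LinAlgError:
            return np.inf, None, None, None
        beta = linalg.cho_solve(cfx, XtV0y)
        logdet_XtV0X = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
        quad = max(ytV0y - float(XtV0y @ beta), 1e-300)
        df = self.n - self.p
        crit = logdet_V0 + logdet_XtV0X + df * np.log(quad)
        sigma2_e = quad / df
        return crit, beta, XtV0X, sigma2_e


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    design: RandomDesign,
    starts: tuple[float, ...] = (0.1, 1.0),
) -> RemlResult:
    """Profile-REML fit; multi-start over initial variance ratios."""
    ws = _RemlWorkspace(np.asarray(y, float), np.asarray(X, float), design)
    k = len(design.block_names)

    def objective(theta: np.ndarray) -> float:
        crit, *_ = ws.profile(theta)
        return crit if np.isfinite(crit) else 1e12

    best = None
    success = False
    for s0 in starts:
        x0 = np.full(k, np.log(s0))
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[_LOG_RATIO_BOUNDS] * k,
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
        success = success or bool(res.success)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML optimization failed")

    crit, beta, XtV0X, sigma2_e = ws.profile(best.x)
    if beta is None:
        raise RuntimeError("REML profile evaluation failed at the optimum")
    cov_beta = linalg.inv(XtV0X) * sigma2_e
    se = np.sqrt(np.diag(cov_beta))
    gamma = np.exp(best.x)
    sigma2 = {name: float(g * sigma2_e) for name, g in zip(design.block_names, gamma)}
    sigma2["resid"] = float(sigma2_e)
    if not success:
        logger.warning("REML optimizer did not report success (criterion %.4g)", crit)
    return RemlResult(
        beta=beta,
        se=se,
        cov_beta=cov_beta,
        sigma2=sigma2,
        converged=success,
        n_obs=ws.n,
        n_fixed=ws.p,
        reml_criterion=float(crit),
    )
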