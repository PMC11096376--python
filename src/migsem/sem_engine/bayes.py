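"""Bayesian MCMC backend: blocked Gibbs sampler for the mixed model.

Priors are weakly informative on the standardized scale: Normal(0, 2.5)
on each fixed effect and half-Student-t(3, 0, 2.5) on every standard
deviation (random-effect and residual), the latter implemented through
the inverse-gamma scale-mixture representation so every full conditional
is conjugate. Fixed and random coefficients are drawn jointly from their
Gaussian full conditional (Henderson's mixed-model equations), which
mixes far better than single-site updates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .diagnostics import gelman_rubin
from .reml import RandomDesign

__all__ = ["GibbsResult", "gibbs_fit"]


@dataclass
class GibbsResult:
    beta_draws: np.ndarray  # (chains, kept_draws, p)
    sigma2_draws: dict[str, np.ndarray]  # name -> (chains, kept_draws)
    rhat: np.ndarray  # per fixed effect
    converged: bool
    n_obs: int
    n_fixed: int

    @property
    def beta_pooled(self) -> np.ndarray:
        return self.beta_draws.reshape(-1, self.beta_draws.shape[-1])


def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def gibbs_fit(
    y: np.ndarray,
    X: np.ndarray,
    design: RandomDesign,
    chains: int = 4,
    iterations: int = 10_000,
    burn_in: int = 1_000,
    seed: int | None = None,
    prior_beta_sd: float = 2.5,
    prior_sd_scale: float = 2.5,
    prior_sd_df: float = 3.0,
    rhat_threshold: float = 1.1,
) -> GibbsResult:
    """Run the Gibbs sampler and collect post-burn-in fixed-effect draws."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if chains < 2:
        raise ValueError("at least 2 chains are required for convergence checks")
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")

    U = design.U
    q = U.shape[1]
    T = np.hstack([X, U])
    TtT = T.T @ T
    Tty = T.T @ y
    yty = float(y @ y)
    nu = prior_sd_df
    A2 = prior_sd_scale**2
    beta_prec = 1.0 / prior_beta_sd**2
    kept = iterations - burn_in
    names = list(design.block_names)

    ss = np.random.SeedSequence(seed)
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(chains)]

    beta_draws = np.empty((chains, kept, p))
    sigma2_draws = {name: np.empty((chains, kept)) for name in names + ["resid"]}

    for c, rng in enumerate(chain_rngs):
        sigma2_e = 1.0
        sigma2_b = {name: 1.0 for name in names}
        aux_e = 1.0
        aux_b = {name: 1.0 for name in names}
        for it in range(iterations):
            # joint draw of (beta, v) from the Gaussian full conditional
            prec_diag = np.empty(p + q)
            prec_diag[:p] = beta_prec
            for name, sl in zip(names, design.block_slices):
                prec_diag[p + sl.start : p + sl.stop] = 1.0 / sigma2_b[name]
            Q = TtT / sigma2_e
            Q[np.diag_indices_from(Q)] += prec_diag
            cf = linalg.cho_factor(Q, lower=True)
            mean = linalg.cho_solve(cf, Tty / sigma2_e)
            z = rng.standard_normal(p + q)
            theta = mean + linalg.solve_triangular(cf[0].T, z, lower=False)

            rss = yty - 2.0 * float(theta @ Tty) + float(theta @ (TtT @ theta))
            rss = max(rss, 1e-12)
            sigma2_e = _inv_gamma(rng, (nu + n) / 2.0, nu / aux_e + rss / 2.0)
            aux_e = _inv_gamma(rng, (nu + 1) / 2.0, nu / sigma2_e + 1.0 / A2)

            for name, sl in zip(names, design.block_slices):
                v = theta[p + sl.start : p + sl.stop]
                qk = sl.stop - sl.start
                ssq = float(v @ v)
                sigma2_b[name] = _inv_gamma(
                    rng, (nu + qk) / 2.0, nu / aux_b[name] + ssq / 2.0
                )
                aux_b[name] = _inv_gamma(
                    rng, (nu + 1) / 2.0, nu / sigma2_b[name] + 1.0 / A2
                )

            if it >= burn_in:
                j = it - burn_in
                beta_draws[c, j] = theta[:p]
                sigma2_draws["resid"][c, j] = sigma2_e
                for name in names:
                    sigma2_draws[name][c, j] = sigma2_b[name]

    rhat = np.asarray(gelman_rubin(beta_draws))
    converged = bool(np.all(rhat < rhat_threshold))
    return GibbsResult(
        beta_draws=beta_draws,
        sigma2_draws=sigma2_draws,
        rhat=rhat,
        converged=converged,
        n_obs=n,
        n_fixed=p,
    )
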