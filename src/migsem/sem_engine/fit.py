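"""One structural equation: fitting front-end and result container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import stats

from ..phylo_cov import PhyloCovariance
from .bayes import gibbs_fit
from .design import ModelMatrix
from .diagnostics import r_squared, vif
from .reml import build_random_design, reml_fit

__all__ = ["Coefficient", "EquationFit", "FitSettings", "fit_equation"]

RANDOM_COMPONENTS = ("phylo", "species", "paper", "year")


@dataclass
class Coefficient:
    """Standardized coefficient with an equal-tailed 95% interval."""

    name: str
    estimate: float
    lower: float
    upper: float
    se: float | None = None
    p_value: float | None = None
    rhat: float | None = None

    @property
    def significant(self) -> bool:
        """The paper's rule: the 95% interval excludes zero."""
        return self.lower > 0.0 or self.upper < 0.0

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "estimate": float(self.estimate),
            "lower": float(self.lower),
            "upper": float(self.upper),
            "se": None if self.se is None else float(self.se),
            "p_value": None if self.p_value is None else float(self.p_value),
            "rhat": None if self.rhat is None else float(self.rhat),
            "significant": bool(self.significant),
        }


@dataclass
class EquationFit:
    """Fit artefacts for one equation of the piecewise SEM."""

    response: str
    coefficients: dict[str, Coefficient]
    variance_components: dict[str, float]
    r2_marginal: float
    r2_conditional: float
    vif: dict[str, float]
    n_obs: int
    n_species: int
    backend: str
    converged: bool
    rhat: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.coefficients.values():
            if not (c.lower <= c.estimate <= c.upper):
                raise ValueError(
                    f"{self.response}~{c.name}: estimate {c.estimate} outside "
                    f"interval [{c.lower}, {c.upper}]"
                )
        for name, v in self.variance_components.items():
            if v < 0:
                raise ValueError(f"negative variance component {name}={v}")
        if not (0.0 <= self.r2_marginal <= self.r2_conditional <= 1.0):
            raise ValueError(
                f"invalid R2 pair ({self.r2_marginal}, {self.r2_conditional})"
            )

    def to_dict(self) -> dict[str, Any]:
        return {
            "response": self.response,
            "coefficients": {k: c.to_dict() for k, c in self.coefficients.items()},
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "r2_marginal": float(self.r2_marginal),
            "r2_conditional": float(self.r2_conditional),
            "vif": {k: float(v) for k, v in self.vif.items()},
            "n_obs": int(self.n_obs),
            "n_species": int(self.n_species),
            "backend": self.backend,
            "converged": bool(self.converged),
            "rhat": {k: float(v) for k, v in self.rhat.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "EquationFit":
        coefs = {
            k: Coefficient(
                name=v["name"],
                estimate=v["estimate"],
                lower=v["lower"],
                upper=v["upper"],
                se=v.get("se"),
                p_value=v.get("p_value"),
                rhat=v.get("rhat"),
            )
            for k, v in d["coefficients"].items()
        }
        return cls(
            response=d["response"],
            coefficients=coefs,
            variance_components=dict(d["variance_components"]),
            r2_marginal=d["r2_marginal"],
            r2_conditional=d["r2_conditional"],
            vif=dict(d.get("vif", {})),
            n_obs=d["n_obs"],
            n_species=d["n_species"],
            backend=d.get("backend", "unknown"),
            converged=d.get("converged", True),
            rhat=dict(d.get("rhat", {})),
        )

    @classmethod
    def from_coefficients(
        cls, response: str, coefficients: Mapping[str, tuple[float, float, float]]
    ) -> "EquationFit":
        """Build a minimal fit from ``{predictor: (estimate, lo, hi)}``.

        Convenience for path-tracing with externally supplied
        coefficients (e.g. published tables).
        """
        coefs = {
            name: Coefficient(name=name, estimate=est, lower=lo, upper=hi)
            for name, (est, lo, hi) in coefficients.items()
        }
        return cls(
            response=response,
            coefficients=coefs,
            variance_components={},
            r2_marginal=0.0,
            r2_conditional=0.0,
            vif={},
            n_obs=0,
            n_species=0,
            backend="external",
            converged=True,
        )


@dataclass
class FitSettings:
    """Backend selection and sampler configuration.

    The MCMC defaults mirror the published analysis (4 chains of 10,000
    iterations, first 1,000 discarded, convergence declared when every
    split-R-hat is below 1.1); ``backend="reml"`` selects the fast
    profile-REML fitter with Wald intervals instead.
    """

    backend: str = "reml"
    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 1_000
    seed: int | None = None
    prior_beta_sd: float = 2.5
    prior_sd_scale: float = 2.5
    prior_sd_df: float = 3.0
    rhat_threshold: float = 1.1
    include_phylo: bool = True


def fit_equation(
    m: ModelMatrix,
    phylo: PhyloCovariance | None,
    settings: FitSettings | None = None,
) -> EquationFit:
    """Fit one structural equation as a phylogenetic mixed model.

    The phylogenetic correlation matrix is subset to (and ordered by) the
    species present in the model matrix; species absent from it are a
    hard error. Non-convergence (optimizer failure or any R-hat at or
    above the threshold) is recorded on the returned fit, which blocks
    effect decomposition unless forced.
    """
    settings = settings or FitSettings()
    C_corr = None
    if settings.include_phylo:
        if phylo is None:
            raise ValueError("phylogenetic covariance required unless include_phylo=False")
        C_corr = phylo.subset(m.species_levels).C_corr
    design = build_random_design(
        m.species_idx,
        m.n_species,
        m.paper_idx,
        len(m.paper_levels),
        m.year_idx,
        len(m.year_levels),
        C_corr,
    )

    vifs = vif(m.X, m.predictors) if len(m.predictors) >= 2 else {p: 1.0 for p in m.predictors}

    if settings.backend == "reml":
        res = reml_fit(m.y, m.X, design)
        z975 = stats.norm.ppf(0.975)
        coefs = {}
        for j, name in enumerate(m.predictors):
            b, se = float(res.beta[j]), float(res.se[j])
            zstat = b / se if se > 0 else np.inf * np.sign(b)
            coefs[name] = Coefficient(
                name=name,
                estimate=b,
                lower=b - z975 * se,
                upper=b + z975 * se,
                se=se,
                p_value=float(2.0 * stats.norm.sf(abs(zstat))),
            )
        sigma2 = {k: res.sigma2.get(k, 0.0) for k in RANDOM_COMPONENTS}
        var_fixed = float(np.var(m.X @ res.beta))
        converged = res.converged
        rhats: dict[str, float] = {}
        resid = res.sigma2["resid"]
    elif settings.backend == "mcmc":
        res = gibbs_fit(
            m.y,
            m.X,
            design,
            chains=settings.chains,
            iterations=settings.iterations,
            burn_in=settings.burn_in,
            seed=settings.seed,
            prior_beta_sd=settings.prior_beta_sd,
            prior_sd_scale=settings.prior_sd_scale,
            prior_sd_df=settings.prior_sd_df,
            rhat_threshold=settings.rhat_threshold,
        )
        pooled = res.beta_pooled
        est = pooled.mean(axis=0)
        lo, hi = np.percentile(pooled, [2.5, 97.5], axis=0)
        coefs = {
            name: Coefficient(
                name=name,
                estimate=float(est[j]),
                lower=float(lo[j]),
                upper=float(hi[j]),
                se=float(pooled[:, j].std(ddof=1)),
                rhat=float(res.rhat[j]),
            )
            for j, name in enumerate(m.predictors)
        }
        sigma2 = {
            k: float(res.sigma2_draws[k].mean()) if k in res.sigma2_draws else 0.0
            for k in RANDOM_COMPONENTS
        }
        var_fixed = float(np.var(m.X @ est))
        converged = res.converged
        rhats = {name: float(res.rhat[j]) for j, name in enumerate(m.predictors)}
        resid = float(res.sigma2_draws["resid"].mean())
    else:
        raise ValueError(f"unknown backend {settings.backend!r}")

    var_random = sum(sigma2.values())
    r2m, r2c = r_squared(var_fixed, var_random, resid)
    sigma2["resid"] = resid
    return EquationFit(
        response=m.response,
        coefficients=coefs,
        variance_components=sigma2,
        r2_marginal=r2m,
        r2_conditional=r2c,
        vif=vifs,
        n_obs=m.n_obs,
        n_species=m.n_species,
        backend=settings.backend,
        converged=converged,
        rhat=rhats,
    )
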