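import numpy as np
import pandas as pd
import pytest

from migsem.cycle_data import derive_table
from migsem.phylo_cov import parse_newick, vcv_from_tree
from migsem.sem_engine import (
    FitSettings,
    assemble_matrix,
    build_default_dag,
    fit_equation,
    gelman_rubin,
    r_squared,
    vif,
    zscore,
)
from migsem.sem_engine.bayes import gibbs_fit
from migsem.sem_engine.reml import build_random_design, reml_fit
from migsem.synthetic_data import simulate_bundle


# ---------------------------------------------------------------------------
# design / assemble_matrix


class TestAssembleMatrix:
    def test_zscore_closed_form(self):
        np.testing.assert_allclose(
            zscore(np.array([1.0, 2.0, 3.0])), [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_zero_variance_errors_with_name(self):
        with pytest.raises(ValueError, match="constant"):
            zscore(np.ones(5), "constant")

    def test_columns_standardized(self, small_derived, request):
        dag = build_default_dag()
        m = assemble_matrix(small_derived, "ArrB", dag=dag)
        assert abs(m.y.mean()) < 1e-8 and abs(m.y.std() - 1) < 1e-8
        np.testing.assert_allclose(m.X.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(m.X.std(axis=0), 1.0, atol=1e-8)

    def test_southern_latitude_absolute_before_scaling(self):
        # two records identical except for hemisphere of the non-breeding site
        from .test_cycle_data import make_record, TRAITS

        recs = [
            make_record(record_id="a", nb_first_lat=30.0, nb_last_lat=30.0),
            make_record(record_id="b", nb_first_lat=-30.0, nb_last_lat=-30.0),
        ]
        derived = derive_table(recs, {"Sp one": TRAITS})
        assert derived["nonbreed_lat_abs"].tolist() == [30.0, 30.0]

    def test_constant_flight_mode_errors(self, small_derived):
        sub = small_derived[small_derived["flight_mode"] == "flapping"]
        dag = build_default_dag()
        with pytest.raises(ValueError, match="FlightMode"):
            assemble_matrix(sub, "MigDist", dag=dag)

    def test_unknown_sex_rows_dropped_listwise(self, small_derived):
        dag = build_default_dag(include_sex=True)
        m = assemble_matrix(small_derived, "ArrB", dag=dag)
        n_unknown = int((small_derived["sex"] == "unknown").sum())
        assert m.n_dropped == n_unknown
        assert m.n_obs == len(small_derived) - n_unknown

    def test_explicit_predictors_override(self, small_derived):
        m = assemble_matrix(small_derived, "ArrB", predictors=["BodyMass", "DepNB"])
        assert m.predictors == ["BodyMass", "DepNB"]
        assert m.X.shape[1] == 2

    def test_paper_grouping_nested_in_species(self, small_derived):
        dag = build_default_dag()
        m = assemble_matrix(small_derived, "ArrB", dag=dag)
        # every paper level belongs to exactly one species
        assert all(lvl.split(":")[0] in m.species_levels for lvl in m.paper_levels)


# ---------------------------------------------------------------------------
# diagnostics


class TestRSquared:
    def test_closed_form(self):
        assert r_squared(1.0, 1.0, 2.0) == pytest.approx((0.25, 0.50))

    def test_no_random_effects(self):
        r2m, r2c = r_squared(1.0, 0.0, 1.0)
        assert r2m == r2c == pytest.approx(0.5)

    def test_no_fixed_effects(self):
        r2m, _ = r_squared(0.0, 1.0, 1.0)
        assert r2m == 0.0

    def test_negative_input_errors(self):
        with pytest.raises(ValueError):
            r_squared(-0.1, 1.0, 1.0)


class TestVif:
    def test_orthogonal_predictors(self):
        # exactly orthogonal columns
        X = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        out = vif(X, ["a", "b"])
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(1.0)

    def test_duplicated_predictor_is_infinite(self):
        x = np.random.default_rng(0).normal(size=50)
        out = vif(np.column_stack([x, x]))
        assert out["x0"] == np.inf

    def test_correlation_point_six(self):
        # construct sample correlation exactly 0.6 via orthonormal basis
        n = 100
        u1 = np.zeros(n)
        u1[: n // 2] = 1.0
        u1[n // 2 :] = -1.0
        u2 = np.ones(n)
        u2[::2] = -1.0
        assert abs(u1 @ u2) < 1e-12
        x1 = u1
        x2 = 0.6 * u1 + 0.8 * u2
        out = vif(np.column_stack([x1, x2]), ["x1", "x2"])
        assert out["x1"] == pytest.approx(1.5625)
        assert out["x2"] == pytest.approx(1.5625)

    def test_needs_two_predictors(self):
        with pytest.raises(ValueError):
            vif(np.ones((10, 1)))


class TestGelmanRubin:
    def test_identical_constant_chains(self):
        chains = np.ones((4, 100))
        assert gelman_rubin(chains) == 1.0

    def test_divergent_chains(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(chains) > 1.1

    def test_well_mixed_chains(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(4, 5000))
        assert gelman_rubin(chains) < 1.01

    def test_single_chain_errors(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))

    def test_matches_arviz(self):
        # cross-library check of the split-R-hat formula
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(4, 400)) + rng.normal(size=(4, 1)) * 0.3
        ours = gelman_rubin(chains)
        ds = arviz.convert_to_dataset(chains[:, :, None])
        theirs = float(np.asarray(arviz.rhat(ds)["x"].values).ravel()[0])
        assert ours == pytest.approx(theirs, abs=0.005)


# ---------------------------------------------------------------------------
# REML backend


def _iid_design(n, rng, n_groups=8):
    sp = rng.integers(0, n_groups, n)
    pap = sp  # one paper per species
    yr = rng.integers(0, 3, n)
    return build_random_design(sp, n_groups, pap, n_groups, yr, 3, None)


class TestReml:
    def test_matches_ols_when_no_group_structure(self):
        rng = np.random.default_rng(0)
        n = 400
        X = rng.normal(size=(n, 3))
        beta = np.array([0.5, -0.3, 0.0])
        y = X @ beta + rng.normal(0, 0.7, n)
        design = _iid_design(n, rng)
        res = reml_fit(y, X, design)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(res.beta, ols, atol=0.02)
        # group variances estimated near zero
        assert res.sigma2["species"] < 0.02
        assert res.sigma2["resid"] == pytest.approx(0.49, abs=0.08)

    def test_exact_copy_degenerate_limit(self):
        rng = np.random.default_rng(1)
        n = 200
        x = rng.normal(size=n)
        X = np.column_stack([x, rng.normal(size=n)])
        y = x.copy()
        design = _iid_design(n, rng)
        res = reml_fit(y, X, design)
        assert res.beta[0] == pytest.approx(1.0, abs=1e-4)
        assert res.sigma2["resid"] < 1e-6

    def test_recovers_species_variance(self):
        rng = np.random.default_rng(2)
        n_sp, per = 40, 25
        n = n_sp * per
        sp = np.repeat(np.arange(n_sp), per)
        X = rng.normal(size=(n, 2))
        u = rng.normal(0, np.sqrt(0.5), n_sp)
        y = X @ np.array([0.4, 0.0]) + u[sp] + rng.normal(0, np.sqrt(0.5), n)
        design = build_random_design(sp, n_sp, sp, n_sp, np.zeros(n, dtype=int), 1, None)
        res = reml_fit(y, X, design)
        assert res.beta[0] == pytest.approx(0.4, abs=0.06)
        total_group = res.sigma2["species"] + res.sigma2["paper"]  # aliased groups
        assert total_group == pytest.approx(0.5, rel=0.5)
        assert res.sigma2["resid"] == pytest.approx(0.5, abs=0.1)


class TestFitEquation:
    def test_standardization_invariance(self, small_derived, small_phylo):
        dag = build_default_dag()
        settings = FitSettings(backend="reml")
        m1 = assemble_matrix(small_derived, "DepNB", dag=dag)
        fit1 = fit_equation(m1, small_phylo, settings)

        scaled = small_derived.copy()
        scaled["spring_distance"] = scaled["spring_distance"] * 1000.0
        m2 = assemble_matrix(scaled, "DepNB", dag=dag)
        fit2 = fit_equation(m2, small_phylo, settings)
        for name in fit1.coefficients:
            # identical up to optimizer numerics (z-scoring absorbs the scale)
            assert fit1.coefficients[name].estimate == pytest.approx(
                fit2.coefficients[name].estimate, abs=1e-3
            )

    def test_r2_limits_all_variance_in_species(self):
        rng = np.random.default_rng(3)
        n_sp, per = 30, 20
        sp_names = [f"S{i}" for i in range(n_sp)]
        sp = np.repeat(np.arange(n_sp), per)
        u = rng.normal(0, 1, n_sp)
        derived = pd.DataFrame(
            {
                "species": np.array(sp_names)[sp],
                "paper_id": "p1",
                "year": 2000,
                "body_mass": np.exp(rng.normal(0, 1, n_sp * per)),
                "dep_nb_doy": 100 + 10 * u[sp] + rng.normal(0, 0.3, n_sp * per),
            }
        )
        m = assemble_matrix(derived, "DepNB", predictors=["BodyMass"])
        fit = fit_equation(m, None, FitSettings(backend="reml", include_phylo=False))
        assert fit.r2_marginal < 0.05
        assert fit.r2_conditional > 0.9

    def test_equation_fit_serialization_round_trip(self, small_derived, small_phylo):
        from migsem.sem_engine import EquationFit

        dag = build_default_dag()
        m = assemble_matrix(small_derived, "DepB", dag=dag)
        fit = fit_equation(m, small_phylo, FitSettings(backend="reml"))
        back = EquationFit.from_dict(fit.to_dict())
        assert back.response == fit.response
        for k in fit.coefficients:
            assert back.coefficients[k].estimate == fit.coefficients[k].estimate
            assert back.coefficients[k].significant == fit.coefficients[k].significant
        assert back.r2_marginal == fit.r2_marginal

    def test_interval_invariant(self, small_derived, small_phylo):
        dag = build_default_dag()
        m = assemble_matrix(small_derived, "ArrNB", dag=dag)
        fit = fit_equation(m, small_phylo, FitSettings(backend="reml"))
        for c in fit.coefficients.values():
            assert c.lower <= c.estimate <= c.upper
        assert all(v >= 0 for v in fit.variance_components.values())
        assert 0 <= fit.r2_marginal <= fit.r2_conditional <= 1

    def test_phylo_required_unless_disabled(self, small_derived):
        dag = build_default_dag()
        m = assemble_matrix(small_derived, "ArrB", dag=dag)
        with pytest.raises(ValueError, match="phylo"):
            fit_equation(m, None, FitSettings(backend="reml"))


# ---------------------------------------------------------------------------
# Gibbs backend


class TestGibbs:
    def test_simple_recovery_and_rhat(self):
        rng = np.random.default_rng(4)
        n = 300
        x = rng.normal(size=n)
        X = x[:, None]
        y = 0.5 * x + rng.normal(0, 0.8, n)
        design = _iid_design(n, rng)
        res = gibbs_fit(
            y, X, design, chains=2, iterations=600, burn_in=150, seed=0
        )
        pooled = res.beta_pooled[:, 0]
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        assert lo < 0.5 < hi
        assert res.rhat[0] < 1.1

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        n = 120
        X = rng.normal(size=(n, 2))
        y = X[:, 0] * 0.3 + rng.normal(0, 1, n)
        design = _iid_design(n, rng)
        r1 = gibbs_fit(y, X, design, chains=2, iterations=200, burn_in=50, seed=7)
        r2 = gibbs_fit(y, X, design, chains=2, iterations=200, burn_in=50, seed=7)
        np.testing.assert_array_equal(r1.beta_draws, r2.beta_draws)

    def test_backend_agreement_on_synthetic_data(self):
        # likelihood and Bayesian point estimates within 0.05 at n >= 1000
        bundle = simulate_bundle(n_species=40, mean_records_per_species=30, seed=11)
        derived = derive_table(bundle.records, bundle.traits)
        assert len(derived) >= 1000
        phylo = vcv_from_tree(parse_newick(bundle.newick))
        dag = build_default_dag()
        m = assemble_matrix(derived, "ArrB", dag=dag)
        reml = fit_equation(m, phylo, FitSettings(backend="reml"))
        mcmc = fit_equation(
            m,
            phylo,
            FitSettings(backend="mcmc", chains=2, iterations=800, burn_in=200, seed=3),
        )
        for name in reml.coefficients:
            assert reml.coefficients[name].estimate == pytest.approx(
                mcmc.coefficients[name].estimate, abs=0.05
            )
        assert mcmc.converged
        assert all(c.rhat is not None and c.rhat < 1.1 for c in mcmc.coefficients.values())

    def test_requires_two_chains(self):
        rng = np.random.default_rng(6)
        n = 50
        X = rng.normal(size=(n, 1))
        y = rng.normal(size=n)
        design = _iid_design(n, rng)
        with pytest.raises(ValueError):
            gibbs_fit(y, X, design, chains=1, iterations=100, burn_in=10, seed=0)
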