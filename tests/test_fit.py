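"""Maximum-likelihood fitting, standard errors, bootstrap and ranking."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from rmer import (
    ConstraintSet,
    ModelSpec,
    RemovalData,
    RobustDesign,
    bootstrap,
    fit_model,
    hessian_se,
    log_likelihood,
    parse_model_code,
    rank_models,
    run_simulation_study,
    scenario,
    simulate_scenario,
)


def zippin_profile_oracle(counts):
    """Integer-N profile search for the geometric removal MLE.

    For each candidate N the capture probability is profiled numerically on
    the exact multinomial likelihood; returns (N*, p*) at the joint maximum.
    Independent of the package's optimiser and parameterisation.
    """
    counts = np.asarray(counts)
    K, D = counts.size, counts.sum()

    def loglik(N, p):
        cells = p * (1 - p) ** np.arange(K)
        never = (1 - p) ** K
        return (gammaln(N + 1) - gammaln(N - D + 1) - gammaln(counts + 1).sum()
                + counts @ np.log(cells) + (N - D) * np.log(never))

    best = (None, None, -np.inf)
    for N in range(D, 5 * D):
        res = minimize_scalar(lambda p: -loglik(N, p), bounds=(1e-6, 1 - 1e-6),
                              method="bounded")
        if -res.fun > best[2]:
            best = (N, res.x, -res.fun)
    return best[0], best[1]


def zippin_closed_form(counts):
    """Classical Moran-Zippin moment estimator for constant-p removal data.

    Solves q/p - K q^K / (1 - q^K) = sum_m (m-1) n_m / D for p, then
    N = D / (1 - q^K).  Uses the log approximation to the digamma implicit
    in the textbook derivation, so it differs slightly from the exact
    multinomial maximum at small N.
    """
    from scipy.optimize import brentq

    counts = np.asarray(counts)
    K, D = counts.size, counts.sum()
    ratio = (np.arange(K) * counts).sum() / D

    def eqn(p):
        q = 1 - p
        return q / p - K * q ** K / (1 - q ** K) - ratio

    p = brentq(eqn, 1e-6, 1 - 1e-6)
    return D / (1 - (1 - p) ** K), p


class TestFitModel:
    def test_recovers_zippin_closed_population_estimate(self):
        # geometric-depletion data 100, 60, 36: the classical closed form
        # returns exactly (N, p) = (250, 0.4); the exact multinomial
        # profile-search oracle peaks nearby at integer N = 247, and the
        # continuous-n0 fit must agree with the exact oracle
        counts = np.array([100, 60, 36])
        N_cf, p_cf = zippin_closed_form(counts)
        assert N_cf == pytest.approx(250, abs=1e-6)
        assert p_cf == pytest.approx(0.4, abs=1e-9)
        N_star, p_star = zippin_profile_oracle(counts)
        assert abs(N_star - N_cf) <= 5
        from rmer.grm import fit_grm, grm_estimates

        data = RemovalData(RobustDesign((3,)), counts)
        fit = fit_grm(data)
        est = grm_estimates(fit)
        assert est["p"] == pytest.approx(p_star, abs=0.005)
        assert est["n0"] + counts.sum() == pytest.approx(N_star, abs=1.0)

    def test_loglik_at_fixed_truth_matches_direct_evaluation(self, const_s2_dataset):
        scn, data = const_s2_dataset
        spec = parse_model_code("R-SRC", scn.design.k)
        theta = np.array([0.0, -0.5, np.log(20.0)])
        assert fit_model(data, spec, starts=theta, n_restarts=0).loglik >= \
            log_likelihood(theta, spec, data) - 1e-9

    def test_abundance_never_below_removals(self, const_s2_dataset):
        scn, data = const_s2_dataset
        fit = fit_model(data, parse_model_code("R-SRC", scn.design.k), seed=0,
                        n_restarts=2)
        assert fit.N_hat[0] >= data.D

    def test_nested_model_attains_higher_likelihood(self, const_s2_dataset):
        # R-SRC (stationary pi) is nested in R-NRC (free pi)
        scn, data = const_s2_dataset
        small = fit_model(data, parse_model_code("R-SRC", scn.design.k), seed=1,
                          n_restarts=3)
        big = fit_model(data, parse_model_code("R-NRC", scn.design.k), seed=1,
                        n_restarts=3)
        assert big.loglik >= small.loglik - 1e-6

    def test_restarts_never_worsen_reported_optimum(self, const_s2_dataset):
        scn, data = const_s2_dataset
        spec = parse_model_code("R-SRC", scn.design.k)
        few = fit_model(data, spec, seed=3, n_restarts=0)
        many = fit_model(data, spec, seed=3, n_restarts=5)
        assert many.loglik >= few.loglik - 1e-9

    def test_covariate_affine_equivariance(self):
        # rescaling z -> a z + b shifts (alpha, beta) by the exact
        # compensation and leaves the maximised log-likelihood unchanged
        scn = scenario("const-s2", K=10)
        rng = np.random.default_rng(8)
        data0 = simulate_scenario(scn, rng=rng)[0]
        z = np.linspace(-1.5, 1.5, scn.design.K)
        a, b = 2.0, 0.7
        spec = parse_model_code("R-SRZ", scn.design.k)
        d1 = RemovalData(scn.design, data0.counts, covariates=z)
        d2 = RemovalData(scn.design, data0.counts, covariates=a * z + b)
        f1 = fit_model(d1, spec, seed=2, n_restarts=3)
        start2 = f1.theta_free.copy()
        names = [n for n in f1.estimates()]
        ia, ib = names.index("alpha"), names.index("beta")
        start2[ia] = f1.theta_free[ia] - f1.theta_free[ib] * b / a
        start2[ib] = f1.theta_free[ib] / a
        f2 = fit_model(d2, spec, starts=start2, n_restarts=0)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)
        assert f2.theta_free[ib] == pytest.approx(f1.theta_free[ib] / a, abs=1e-3)

    def test_empty_data_rejected(self):
        design = RobustDesign((2, 2))
        data = RemovalData(design, np.zeros(4, dtype=int))
        with pytest.raises(ValueError):
            fit_model(data, parse_model_code("R-SRC", design.k))

    def test_aic_consistent_with_loglik_and_h(self, const_s2_dataset):
        scn, data = const_s2_dataset
        fit = fit_model(data, parse_model_code("R-SRC", scn.design.k), seed=0,
                        n_restarts=1)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.h)
        assert fit.h == 3  # phi12, p, n0


class TestStandardErrors:
    def test_hessian_se_close_to_empirical_sd(self):
        # across replicates, mean Hessian SE of p tracks the empirical SD
        scn = scenario("const-s2", K=20)
        spec = parse_model_code("R-SRC", scn.design.k)
        rng_master = np.random.SeedSequence(99)
        p_hats, p_ses = [], []
        for child in rng_master.spawn(200):
            data = simulate_scenario(scn, rng=np.random.default_rng(child))[0]
            fit = fit_model(data, spec, seed=0, n_restarts=1)
            if fit.converged and fit.se is not None:
                p_hats.append(fit.estimates()["p"])
                p_ses.append(fit.se["p"])
        emp_sd = np.std(p_hats, ddof=1)
        assert np.mean(p_ses) == pytest.approx(emp_sd, rel=0.15)

    def test_boundary_estimate_suppresses_hessian_se(self):
        # geometric data fitted with a free pi drives pi to the boundary
        design = RobustDesign((2,) * 5)
        counts = np.array([120, 96, 61, 49, 31, 25, 16, 13, 8, 6])
        data = RemovalData(design, counts)
        fit = fit_model(data, parse_model_code("R-NRC", design.k), seed=0,
                        n_restarts=5)
        if fit.boundary_flags:
            assert fit.se is None
            assert "bootstrap" in fit.se_reason
        else:  # interior optimum: SEs must then be available
            assert fit.se is not None

    def test_hessian_se_recompute_matches_fit(self, const_s2_dataset):
        scn, data = const_s2_dataset
        fit = fit_model(data, parse_model_code("R-SRC", scn.design.k), seed=0,
                        n_restarts=1)
        se = hessian_se(fit)
        assert se is not None and se.keys() == fit.se.keys()


class TestBootstrap:
    def test_zero_resamples_is_error_free(self, const_s2_dataset):
        scn, data = const_s2_dataset
        spec = parse_model_code("R-SRC", scn.design.k)
        out = bootstrap(data, spec, B=0, seed=0)
        assert out.replicates.empty and out.n_failed == 0

    def test_degenerate_single_cell_data_collapses_to_point_mass(self):
        design = RobustDesign((2,))
        data = RemovalData(design, np.array([25, 0]))
        spec = ModelSpec(design, ConstraintSet(pi="free", phi="random"))
        out = bootstrap(data, spec, B=10, seed=0, n_restarts=0)
        # resampling D identical records reproduces the data every time
        assert len(out.replicates) + out.n_failed == 10
        if len(out.replicates) > 1:
            assert out.replicates["p"].std() == pytest.approx(0.0, abs=1e-6)

    def test_bootstrap_se_consistent_with_hessian(self, const_s2_dataset):
        scn, data = const_s2_dataset
        spec = parse_model_code("R-SRC", scn.design.k)
        fit = fit_model(data, spec, seed=0, n_restarts=1)
        out = bootstrap(data, spec, B=100, seed=4, fit=fit)
        assert out.n_failed <= 5
        ratio = out.se["p"] / fit.se["p"]
        assert 0.5 < ratio < 2.0
        assert out.ci.loc["p", "lower"] < fit.estimates()["p"] < out.ci.loc["p", "upper"]

    def test_parametric_scheme_runs(self, const_s2_dataset):
        scn, data = const_s2_dataset
        spec = parse_model_code("R-SRC", scn.design.k)
        out = bootstrap(data, spec, B=20, seed=5, scheme="parametric")
        assert len(out.replicates) + out.n_failed == 20


class TestModelRanking:
    def test_single_model_has_zero_delta(self, const_s2_dataset):
        scn, data = const_s2_dataset
        table = rank_models(data, [parse_model_code("R-SRC", scn.design.k)],
                            seed=0, n_restarts=1)
        assert table["dAIC"].tolist() == [0.0]

    def test_table_sorted_with_nested_likelihood_ordering(self, const_s2_dataset):
        scn, data = const_s2_dataset
        specs = [parse_model_code(c, scn.design.k)
                 for c in ("R-SRC", "R-NRC", "R-NNC")]
        table = rank_models(data, specs, seed=0, n_restarts=3)
        assert table["AIC"].is_monotonic_increasing
        ll = dict(zip(table.model_code, table.loglik))
        assert ll["R-NNC"] >= ll["R-SRC"] - 1e-6

    def test_generating_structure_usually_ranks_first(self):
        # data simulated under R-SRC should usually prefer R-SRC over the
        # heavily parameterised near-redundant alternative
        scn = scenario("const-s2", K=20)
        wins = 0
        reps = 30
        for child in np.random.SeedSequence(13).spawn(reps):
            data = simulate_scenario(scn, rng=np.random.default_rng(child))[0]
            specs = [parse_model_code(c, scn.design.k) for c in ("R-SRC", "R-NNC")]
            table = rank_models(data, specs, seed=0, n_restarts=2)
            if table.loc[0, "model_code"] == "R-SRC":
                wins += 1
        assert wins > reps / 2


class TestSimulationStudies:
    def test_study_reports_every_replicate(self):
        scn = scenario("const-s2", K=10)
        spec = parse_model_code("R-SRC", scn.design.k)
        res = run_simulation_study(scn, spec, n_replicates=8, seed=21, n_restarts=1)
        assert len(res) == 8
        assert {"p", "phi12", "N_hat", "converged"} <= set(res.columns)

    def test_study_reproducible_for_fixed_seed(self):
        scn = scenario("const-s2", K=10)
        spec = parse_model_code("R-SRC", scn.design.k)
        a = run_simulation_study(scn, spec, n_replicates=4, seed=5, n_restarts=1)
        b = run_simulation_study(scn, spec, n_replicates=4, seed=5, n_restarts=1)
        assert np.allclose(a["p"], b["p"])

    def test_large_population_limit_recovers_truth(self):
        # one huge replicate: MLEs within 1% of the generating values
        scn = scenario("const-s2", K=20)
        design = scn.design
        truth = scn.truths[0]
        rng = np.random.default_rng(17)
        from rmer import simulate_individuals

        counts = simulate_individuals(1_000_000, truth, design, rng)
        data = RemovalData(design, counts)
        fit = fit_model(data, parse_model_code("R-SRC", design.k), seed=0,
                        n_restarts=2)
        est = fit.estimates()
        assert est["p"] == pytest.approx(0.3, rel=0.01)
        assert est["phi12"] == pytest.approx(0.4, rel=0.01)
        assert fit.N_hat[0] == pytest.approx(1_000_000, rel=0.01)
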