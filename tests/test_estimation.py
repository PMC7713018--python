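import numpy as np
import pandas as pd
import pytest

from mvjoint.data_io import JointDataset, ModelSpec
from mvjoint.errors import EstimationError, InitializationError
from mvjoint.estimation import (combine_covariance, combine_pairs,
                                fit_baseline_weibull, fit_pair,
                                fit_univariate_joint, fit_weibull_regression,
                                initialize_params, n_pairs, pairwise_fit,
                                PairFit)
from mvjoint.parameters import ParamSchema
from mvjoint.simulation import SimulationDesign, simulate_dataset


@pytest.fixture(scope="module")
def med_design():
    return SimulationDesign(n_subjects=150, base_seed=42)


@pytest.fixture(scope="module")
def med_dataset(med_design):
    return simulate_dataset(med_design, 7)


@pytest.fixture(scope="module")
def med_spec(med_design):
    return med_design.model_spec()


@pytest.fixture(scope="module")
def med_init(med_dataset, med_spec):
    return initialize_params(med_dataset, med_spec)


class TestInitialize:
    def test_beta_within_ten_percent(self):
        design = SimulationDesign(n_subjects=800, base_seed=17)
        ds = simulate_dataset(design, 17)
        init = initialize_params(ds, design.model_spec())
        for r in design.responses:
            true = np.asarray(design.beta[r])
            got = init.responses[r].beta
            assert np.all(np.abs(got - true) <= 0.10 * np.abs(true))

    def test_theta_starts_at_zero(self, med_init):
        for p in med_init.responses.values():
            assert p.theta[0] == 0.0

    def test_rho_clipped_to_interval(self):
        design = SimulationDesign(
            n_subjects=200, responses=("y1", "y2"),
            beta={"y1": (1.0, 0.1, 0.0), "y2": (1.0, 0.1, 0.0)},
            sigma={"y1": 0.05, "y2": 0.05}, d={"y1": 1.0, "y2": 1.0},
            rho={("y1", "y2"): 0.99}, theta={"y1": 0.0, "y2": 0.0},
            base_seed=3)
        ds = simulate_dataset(design, 12)
        init = initialize_params(ds, design.model_spec())
        assert abs(init.rho[("y1", "y2")]) <= 0.9

    def test_degenerate_data_raises(self, tiny_dataset, tiny_spec):
        lon = tiny_dataset.longitudinal.copy()
        lon["value"] = 1.0  # constant response
        ds = JointDataset(lon, tiny_dataset.survival, ("a", "b"),
                          survival_time_mode="shared")
        with pytest.raises(InitializationError):
            initialize_params(ds, tiny_spec)


class TestFitPair:
    def test_recovery_within_three_se(self):
        design = SimulationDesign(n_subjects=500, base_seed=314)
        ds = simulate_dataset(design, 314)
        spec = design.model_spec()
        fit = fit_pair(ds, "y1", "y2", spec)
        assert fit.converged
        truth = design.true_params().subset(("y1", "y2"))
        sch = ParamSchema.for_model(truth)
        tv = dict(zip(sch.labels, sch.pack(truth)))
        se = np.sqrt(np.diag(np.linalg.inv(fit.info)))
        for label, est, s in zip(fit.labels, fit.estimates, se):
            assert abs(est - tv[label]) < 3.0 * s, label

    def test_theta_rho_fixed_at_zero_matches_lmm_oracle(self, med_dataset,
                                                        med_spec, med_init):
        """With association and cross-correlation switched off the pair
        likelihood factorizes and β, σ, d must match a standalone
        random-intercept linear mixed model fit."""
        sm = pytest.importorskip("statsmodels.api")
        fixed = {("theta", "y1", 0): 0.0, ("theta", "y2", 0): 0.0,
                 ("rho", "y1", "y2"): 0.0}
        fit = fit_pair(med_dataset, "y1", "y2", med_spec, init=med_init,
                       fixed=fixed)
        assert fit.converged
        lon = med_dataset.longitudinal
        for r in ("y1", "y2"):
            sub = lon[lon.response == r]
            X = np.column_stack([np.ones(len(sub)), sub["time"], sub["male"]])
            lmm = sm.MixedLM(sub["value"].to_numpy(), X,
                             groups=sub["subject_id"].to_numpy())
            res = lmm.fit(reml=False)
            p = fit.pv.responses[r]
            np.testing.assert_allclose(p.beta, res.fe_params, atol=1e-3)
            np.testing.assert_allclose(p.sigma, np.sqrt(res.scale), atol=1e-3)
            d_lmm = np.sqrt(float(np.asarray(res.cov_re)[0, 0]))
            np.testing.assert_allclose(p.d[0], d_lmm, atol=2e-3)

    def test_same_optimum_from_perturbed_init(self, med_dataset, med_spec,
                                              med_init):
        fit1 = fit_pair(med_dataset, "y1", "y2", med_spec, init=med_init,
                        compute_info=False)
        shaken = med_init.copy()
        rng = np.random.default_rng(1)
        for p in shaken.responses.values():
            p.beta = p.beta * (1 + 0.2 * rng.uniform(-1, 1, p.beta.shape))
            p.sigma *= 1.15
            p.d = p.d * 0.85
        fit2 = fit_pair(med_dataset, "y1", "y2", med_spec, init=shaken,
                        compute_info=False)
        assert abs(fit1.loglik - fit2.loglik) < 1e-6
        np.testing.assert_allclose(fit1.estimates, fit2.estimates, atol=2e-4)


class TestPairwise:
    def test_pair_count_formula(self):
        assert n_pairs(4) == 6
        assert n_pairs(3) == 3
        assert n_pairs(2) == 1

    def test_k2_combined_equals_single_pair(self, design2):
        ds = simulate_dataset(design2.with_(n_subjects=120), 55)
        spec = design2.model_spec()
        comb = pairwise_fit(ds, spec)
        single = comb.pair_fits[0]
        np.testing.assert_array_equal(comb.estimates, single.estimates)
        # averaging matrix is the identity, so the covariance is the pair's
        # own sandwich J⁻¹KJ⁻¹
        sandwich = combine_covariance([single], np.eye(len(single.keys)))
        np.testing.assert_allclose(comb.cov, sandwich, rtol=1e-12)

    def test_pair_order_invariance(self, med_dataset, med_spec, med_init):
        fits = [fit_pair(med_dataset, r, s, med_spec, init=med_init)
                for r, s in (("y1", "y2"), ("y1", "y3"), ("y2", "y3"))]
        a = combine_pairs(fits, med_spec)
        b = combine_pairs(fits[::-1], med_spec)
        assert a.keys == b.keys
        np.testing.assert_allclose(a.estimates, b.estimates, rtol=1e-12)
        np.testing.assert_allclose(a.cov, b.cov, rtol=1e-10)
        for key, n_copy in zip(a.keys, a.n_copies):
            assert n_copy == (1 if key[0] == "rho" else 2)

    def test_failed_pair_excluded_with_nan_rho(self, med_dataset, med_spec,
                                               med_init, caplog):
        fits = [fit_pair(med_dataset, r, s, med_spec, init=med_init)
                for r, s in (("y1", "y2"), ("y1", "y3"), ("y2", "y3"))]
        fits[2].converged = False
        with caplog.at_level("WARNING"):
            comb = combine_pairs(fits, med_spec)
        assert "did not converge" in caplog.text
        assert not comb.converged
        assert comb.n_converged_pairs == 2
        assert np.isnan(comb.corr_matrix[1, 2])
        # y2 parameters survive through pair (y1, y2) with one copy
        i = comb.keys.index(("sigma", "y2"))
        assert comb.n_copies[i] == 1

    def test_all_pairs_failing_for_a_response_raises(self, med_dataset,
                                                     med_spec, med_init):
        fits = [fit_pair(med_dataset, r, s, med_spec, init=med_init)
                for r, s in (("y1", "y2"), ("y1", "y3"), ("y2", "y3"))]
        fits[1].converged = False
        fits[2].converged = False  # y3 loses every copy
        with pytest.raises(EstimationError, match="lost all"):
            combine_pairs(fits, med_spec)


class TestCombineCovariance:
    def test_zeroed_cross_blocks_never_shrink_se(self):
        """On a fixture with positively correlated pair scores, ignoring the
        between-pair dependence must not enlarge the implied SEs."""
        rng = np.random.default_rng(8)
        N, p = 400, 2
        base = rng.normal(size=(N, p))
        s1 = base + 0.3 * rng.normal(size=(N, p))
        s2 = base + 0.3 * rng.normal(size=(N, p))  # shared-subject dependence
        J1 = s1.T @ s1
        J2 = s2.T @ s2
        f1 = _stub_fit(("beta", "x", 0), s1, J1)
        f2 = _stub_fit(("beta", "x", 0), s2, J2)
        A = np.full((p, 2 * p), 0.0)
        A[0, 0] = A[0, p] = 0.5
        A[1, 1] = A[1, p + 1] = 0.5
        cov_full = combine_covariance([f1, f2], A)
        S = np.hstack([s1, s2])
        K_block = S.T @ S
        K_block[:p, p:] = 0.0
        K_block[p:, :p] = 0.0
        Jinv = np.zeros((2 * p, 2 * p))
        Jinv[:p, :p] = np.linalg.inv(J1)
        Jinv[p:, p:] = np.linalg.inv(J2)
        cov_indep = A @ Jinv @ K_block @ Jinv @ A.T
        assert np.all(np.diag(cov_full) >= np.diag(cov_indep) - 1e-12)

    def test_singular_information_names_pair(self):
        s = np.ones((5, 1))
        f = _stub_fit(("beta", "x", 0), s, np.zeros((1, 1)))
        with pytest.raises(EstimationError, match="singular"):
            combine_covariance([f], np.eye(1))


def _stub_fit(key, scores, info):
    n, p = scores.shape
    keys = tuple((key[0], key[1], j) for j in range(p))
    return PairFit(responses=("x",), keys=keys,
                   labels=tuple(str(k) for k in keys),
                   pv=None, estimates=np.zeros(p), info=info, scores=scores,
                   subjects=tuple(range(n)), loglik=0.0, converged=True,
                   n_iter=0, grad_norm=0.0)


class TestUnivariateJoint:
    def test_intercept_only_recovery(self):
        design = SimulationDesign(n_subjects=400, base_seed=77)
        ds = simulate_dataset(design, 78)
        spec = design.model_spec()
        fit = fit_univariate_joint(ds, "y1", spec)
        assert fit.converged
        truth = design.true_params().subset(("y1",))
        sch = ParamSchema.for_model(truth)
        tv = dict(zip(sch.labels, sch.pack(truth)))
        for label, est, se in zip(fit.labels, fit.estimates, fit.se):
            assert abs(est - tv[label]) < 3.0 * se, label

    def test_intercept_slope_matches_random_slope_lmm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(15)
        N, times = 200, np.arange(5.0)
        D = np.array([[0.49, -0.3 * 0.7 * 0.25], [-0.3 * 0.7 * 0.25, 0.0625]])
        b = rng.multivariate_normal([0, 0], D, size=N)
        male = (rng.random(N) < 0.5).astype(float)
        rows = []
        for i in range(N):
            mu = 2.0 + 0.5 * times - 0.3 * male[i] + b[i, 0] + b[i, 1] * times
            y = mu + 0.6 * rng.standard_normal(len(times))
            for t, v in zip(times, y):
                rows.append({"subject_id": i, "response": "y", "time": t,
                             "value": v, "male": male[i]})
        lon = pd.DataFrame(rows)
        sur = pd.DataFrame({"subject_id": np.arange(N),
                            "time": rng.exponential(size=N) + 1e-3,
                            "event": 1, "male": male})
        ds = JointDataset(lon, sur, ("y",), survival_time_mode="shared")
        spec = ModelSpec(responses=("y",), fixed_effects={"y": ("time", "male")},
                         survival_covariates=("male",),
                         random_effects="intercept_slope",
                         survival_time_mode="shared")
        fixed = {("theta", "y", 0): 0.0, ("theta", "y", 1): 0.0}
        fit = fit_univariate_joint(ds, "y", spec, fixed=fixed)
        assert fit.converged
        X = np.column_stack([np.ones(len(lon)), lon["time"], lon["male"]])
        lmm = sm.MixedLM(lon["value"].to_numpy(), X,
                         groups=lon["subject_id"].to_numpy(),
                         exog_re=np.column_stack([np.ones(len(lon)),
                                                  lon["time"]]))
        res = lmm.fit(reml=False)
        p = fit.pair_fits[0].pv.responses["y"]
        np.testing.assert_allclose(p.beta, res.fe_params, atol=1e-3)
        np.testing.assert_allclose(p.sigma, np.sqrt(res.scale), atol=1e-3)
        cov_re = np.asarray(res.cov_re) * 1.0
        np.testing.assert_allclose(p.d[0], np.sqrt(cov_re[0, 0]), atol=2e-3)
        np.testing.assert_allclose(p.d[1], np.sqrt(cov_re[1, 1]), atol=2e-3)
        rho_lmm = cov_re[0, 1] / np.sqrt(cov_re[0, 0] * cov_re[1, 1])
        np.testing.assert_allclose(p.rho_within, rho_lmm, atol=5e-3)

    def test_vanishing_slope_variance_flags_flat_theta2(self, med_dataset,
                                                        med_design):
        # data carry no random slope; with d₁ pinned near zero the slope
        # association θ₂ is unidentifiable and must be reported as flat
        spec = med_design.model_spec().with_(random_effects="intercept_slope",
                                             responses=("y1",))
        lon = med_dataset.longitudinal
        sur = med_dataset.survival
        ds = JointDataset(lon[lon.response == "y1"],
                          sur[sur.response == "y1"], ("y1",))
        fixed = {("d", "y1", 1): 1e-5, ("rho_within", "y1"): 0.0}
        fit = fit_univariate_joint(ds, "y1", spec, fixed=fixed)
        flat = fit.pair_fits[0].flat_directions
        assert any("theta[y1][1]" in f for f in flat)


class TestBaselineWeibull:
    def test_exponential_regression_matches_closed_form(self):
        # two-group exponential MLE: rate per group = events / exposure
        rng = np.random.default_rng(2)
        N = 4000
        male = (rng.random(N) < 0.5).astype(float)
        lam = np.exp(0.4 - 0.7 * male)
        t = rng.exponential(1.0 / lam)
        X = np.column_stack([np.ones(N), male])
        coef, alpha, ok, _ = fit_weibull_regression(
            t, np.ones(N), X, alpha_fixed=True)
        assert ok and alpha == 1.0
        lam0 = male[male == 0].size / t[male == 0].sum()
        lam1 = male[male == 1].size / t[male == 1].sum()
        assert coef[0] == pytest.approx(np.log(lam0), abs=1e-6)
        assert coef[0] + coef[1] == pytest.approx(np.log(lam1), abs=1e-6)

    def test_attenuated_association_on_joint_data(self, med_dataset, med_spec):
        bf = fit_baseline_weibull(med_dataset, "y1", med_spec)
        assert bf.converged
        # measurement error in the baseline value attenuates θ toward zero
        assert -0.8 < bf.theta < 0.0

    def test_constant_baseline_covariate_flagged(self, tiny_spec):
        from conftest import tiny_tables
        lon, sur = tiny_tables()
        lon.loc[lon.time == 0.0, "value"] = 2.0  # identical baselines
        ds = JointDataset(lon, sur, ("a", "b"), survival_time_mode="shared")
        bf = fit_baseline_weibull(ds, "a", tiny_spec)
        assert not bf.converged
        assert any("baseline" in name for name in bf.inestimable)
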