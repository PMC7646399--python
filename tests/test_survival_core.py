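"""Cox machinery: partial likelihood, Newton MLE, lasso, CV/EBIC tuning."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

import impcox as ic
from impcox.survival_core import breslow_loglik_batch, null_gradient


class TestNegLogPartialLikelihood:
    def test_beta_zero_reduces_to_log_risk_set_sizes(self):
        # three distinct event times: log 3 + log 2 + log 1
        ds = ic.SurvivalDataset(np.arange(3.0)[:, None], [1, 2, 3], [1, 1, 1], ["g"])
        assert ic.neg_log_partial_likelihood([0.0], ds) == pytest.approx(
            np.log(3) + np.log(2), abs=1e-12
        )
        # events only at the first of 5 distinct times: a single risk set of 5
        ds5 = ic.SurvivalDataset(
            np.arange(5.0)[:, None], [1, 2, 3, 4, 5], [1, 0, 0, 0, 0], ["g"]
        )
        assert ic.neg_log_partial_likelihood([0.0], ds5) == pytest.approx(
            np.log(5), abs=1e-12
        )

    def test_beta_zero_with_ties_equals_sum_d_log_risk(self, make_survival):
        ds = make_survival(40, 2, seed=5, ties=True)
        expected = 0.0
        for t in np.unique(ds.time[ds.event == 1]):
            d = int(((ds.time == t) & (ds.event == 1)).sum())
            expected += d * np.log((ds.time >= t).sum())
        got = ic.neg_log_partial_likelihood([0.0, 0.0], ds)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_hand_worked_four_sample_example(self):
        # x=(0,1,0,1), all events at times 1<2<3<4, beta=0.5: value frozen
        # from a term-by-term evaluation of the risk-set sum
        ds = ic.SurvivalDataset(
            np.array([[0.0], [1.0], [0.0], [1.0]]), [1, 2, 3, 4], [1, 1, 1, 1], ["x"]
        )
        assert ic.neg_log_partial_likelihood([0.5], ds) == pytest.approx(
            3.5993212368671923, abs=1e-12
        )

    @pytest.mark.parametrize("seed,ties", [(0, False), (1, True), (2, False), (3, True)])
    def test_matches_naive_oracle(self, make_survival, naive_nlpl, seed, ties):
        ds = make_survival(25, 3, seed=seed, ties=ties)
        beta = np.random.default_rng(seed).normal(size=3)
        got = ic.neg_log_partial_likelihood(beta, ds)
        want = naive_nlpl(beta, ds.X, ds.time, ds.event)
        assert got == pytest.approx(want, rel=1e-10)

    @given(perm_seed=st.integers(0, 10_000))
    def test_invariant_to_joint_sample_permutation(self, perm_seed):
        ds = _fixed_dataset()
        beta = np.array([0.4, -0.7])
        perm = np.random.default_rng(perm_seed).permutation(ds.n)
        ds_p = ic.SurvivalDataset(
            ds.X[perm], ds.time[perm], ds.event[perm], ds.covariate_names
        )
        assert ic.neg_log_partial_likelihood(beta, ds_p) == pytest.approx(
            ic.neg_log_partial_likelihood(beta, ds), rel=1e-12
        )

    def test_no_events_raises(self):
        ds = ic.SurvivalDataset(np.ones((3, 1)) * [[1], [2], [3]], [1, 2, 3], [0, 0, 0], ["g"])
        with pytest.raises(ValueError, match="no observed events"):
            ic.neg_log_partial_likelihood([0.0], ds)

    def test_dimension_mismatch_raises(self, make_survival):
        ds = make_survival(10, 3)
        with pytest.raises(ValueError):
            ic.neg_log_partial_likelihood([0.0, 0.0], ds)


def _fixed_dataset():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(30, 2))
    T = rng.exponential(1, 30) / np.exp(0.5 * X[:, 0])
    C = rng.exponential(2, 30)
    return ic.SurvivalDataset(
        X, np.minimum(T, C), (T <= C).astype(int), ["a", "b"]
    )


class TestFitCox:
    def test_constant_covariate_gets_zero_beta_unit_p(self, make_survival):
        ds = make_survival(20, 2, seed=3)
        ds.X[:, 1] = 4.2
        ds2 = ic.SurvivalDataset(ds.X, ds.time, ds.event, ds.covariate_names)
        fit = ic.fit_cox(ds2)
        assert fit.beta[1] == 0.0
        assert fit.wald_p[1] == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_one_covariate_matches_brute_force(self, make_survival, seed):
        ds = make_survival(8, 1, beta=[0.6], seed=seed, censor_scale=0)
        fit = ic.fit_cox(ds)
        res = optimize.minimize_scalar(
            lambda b: ic.neg_log_partial_likelihood([b], ds),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-8},
        )
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-4)

    @pytest.mark.parametrize("seed", range(4))
    def test_two_covariates_match_grid_refinement(self, make_survival, seed):
        ds = make_survival(10, 2, beta=[0.5, -0.5], seed=10 + seed, censor_scale=0)
        fit = ic.fit_cox(ds)
        # nested 2-D grid oracle
        center, width = np.zeros(2), 10.0
        for _ in range(8):
            g0 = np.linspace(center[0] - width, center[0] + width, 21)
            g1 = np.linspace(center[1] - width, center[1] + width, 21)
            vals = np.array(
                [[ic.neg_log_partial_likelihood([a, b], ds) for b in g1] for a in g0]
            )
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            center, width = np.array([g0[i], g1[j]]), width * 0.15
        assert fit.beta == pytest.approx(center, abs=1e-3)

    def test_binary_covariate_all_events(self, make_survival):
        # interleaved groups, all events: against a 1-D brute-force oracle
        X = np.array([0, 1, 0, 1, 0, 1], dtype=float)[:, None]
        ds = ic.SurvivalDataset(X, [1, 2, 3, 4, 5, 6], [1] * 6, ["g"])
        fit = ic.fit_cox(ds)
        res = optimize.minimize_scalar(
            lambda b: ic.neg_log_partial_likelihood([b], ds),
            bounds=(-10, 10), method="bounded", options={"xatol": 1e-8},
        )
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-4)

    def test_agrees_with_independent_breslow_implementation(self, make_survival):
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        from sksurv.util import Surv

        ds = make_survival(60, 3, beta=[0.7, -0.4, 0.0], seed=11)
        fit = ic.fit_cox(ds)
        ref = CoxPHSurvivalAnalysis(ties="breslow").fit(
            ds.X, Surv.from_arrays(event=ds.event.astype(bool), time=ds.time)
        )
        assert fit.beta == pytest.approx(ref.coef_, abs=1e-5)

    def test_loglik_never_below_null(self, make_survival):
        for seed in range(3):
            ds = make_survival(25, 2, seed=seed)
            fit = ic.fit_cox(ds)
            null = -ic.neg_log_partial_likelihood([0.0, 0.0], ds)
            assert fit.loglik >= null - 1e-10

    def test_duplicate_columns_raise_singular_advice(self, make_survival):
        ds = make_survival(20, 1, seed=2)
        X = np.column_stack([ds.X[:, 0], ds.X[:, 0]])
        dup = ic.SurvivalDataset(X, ds.time, ds.event, ["a", "b"])
        with pytest.raises(np.linalg.LinAlgError, match="ridge_eps"):
            ic.fit_cox(dup)

    def test_empty_subset_returns_null_fit(self, make_survival):
        ds = make_survival(15, 2, seed=4)
        fit = ic.fit_cox(ds, subset=[])
        assert fit.beta.size == 0
        assert fit.loglik == pytest.approx(
            -ic.neg_log_partial_likelihood([0.0, 0.0], ds), rel=1e-12
        )


class TestFitCoxLasso:
    def test_zero_lambda_matches_unpenalized(self, make_survival):
        ds = make_survival(40, 3, beta=[0.8, 0, 0], seed=6)
        assert ic.fit_cox_lasso(ds, lam=0.0).beta == pytest.approx(
            ic.fit_cox(ds).beta, abs=1e-4
        )

    def test_all_zero_at_lambda_max(self, make_survival):
        ds = make_survival(30, 5, beta=[1, 0, 0, 0, 0], seed=8)
        lam = ic.lambda_max(ds)
        assert np.all(ic.fit_cox_lasso(ds, lam=lam).beta == 0)
        assert np.all(ic.fit_cox_lasso(ds, lam=2 * lam).beta == 0)
        # just below lambda_max something enters
        assert ic.fit_cox_lasso(ds, lam=0.8 * lam).support.size >= 1

    def test_objective_beats_mle_and_null(self, make_survival):
        ds = make_survival(20, 5, beta=[0.9, -0.6, 0, 0, 0], seed=9)
        lam = 0.5 * ic.lambda_max(ds)
        from impcox.survival_core import _standardize

        Z, _, sd = _standardize(ds.X)
        dz = ic.SurvivalDataset(Z, ds.time, ds.event, ds.covariate_names)

        def objective(beta_std):
            return ic.neg_log_partial_likelihood(beta_std, dz) + lam * np.abs(
                beta_std
            ).sum()

        beta_std = ic.fit_cox_lasso(ds, lam=lam).beta * sd
        mle_std = ic.fit_cox(dz).beta
        tol = 1e-6 * ds.n
        assert objective(beta_std) <= objective(mle_std) + tol
        assert objective(beta_std) <= objective(np.zeros(5)) + tol

    def test_kkt_conditions_at_solution(self, make_survival):
        from impcox.survival_core import _derivs, _standardize

        ds = make_survival(60, 8, beta=[1, -1, 0, 0, 0, 0, 0, 0], seed=12)
        lam = 0.3 * ic.lambda_max(ds)
        fit = ic.fit_cox_lasso(ds, lam=lam)
        Z, _, sd = _standardize(ds.X)
        cache = ds.breslow_cache()
        bstd = fit.beta * sd
        _, g, _ = _derivs(Z[cache["order"]], (Z @ bstd)[cache["order"]], cache, False)
        act = bstd != 0
        slack = 0.02 * lam
        if act.any():
            assert np.abs(g[act] - lam * np.sign(bstd[act])).max() < slack
        assert np.abs(g[~act]).max() < lam + slack

    def test_support_monotone_nonincreasing_in_lambda(self, make_survival):
        ds = make_survival(50, 10, beta=[1, -0.8, 0.5] + [0] * 7, seed=13)
        lmax = ic.lambda_max(ds)
        sizes = [
            ic.fit_cox_lasso(ds, lam=l).support.size
            for l in np.geomspace(lmax, 0.05 * lmax, 12)
        ]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_negative_lambda_rejected(self, make_survival):
        with pytest.raises(ValueError):
            ic.fit_cox_lasso(make_survival(10, 2), lam=-1.0)


class TestSelectLambdaCV:
    def test_deterministic_given_seed(self, make_survival):
        ds = make_survival(50, 10, beta=[1] + [0] * 9, seed=20)
        assert ic.select_lambda_cv(ds, seed=5) == ic.select_lambda_cv(ds, seed=5)

    def test_signal_covariate_active_at_selected_lambda(self, make_survival):
        ds = make_survival(80, 10, beta=[1.5] + [0] * 9, seed=21, censor_scale=0)
        lam = ic.select_lambda_cv(ds, seed=0)
        assert 0 in ic.fit_cox_lasso(ds, lam=lam).support

    def test_pure_noise_selects_sparse_models(self, make_survival):
        hits = 0
        for rep in range(20):
            ds = make_survival(60, 30, seed=1000 + rep)
            lam = ic.select_lambda_cv(ds, seed=rep)
            hits += ic.fit_cox_lasso(ds, lam=lam).support.size <= 2
        assert hits >= 16  # >= 80% of replicates near-null

    def test_fold_count_validation(self, make_survival):
        ds = make_survival(10, 2)
        with pytest.raises(ValueError):
            ic.select_lambda_cv(ds, n_folds=1)
        with pytest.raises(ValueError):
            ic.select_lambda_cv(ds, n_folds=11)


class TestSelectLambdaEBIC:
    def test_recovers_small_true_support(self, make_survival):
        ds = make_survival(100, 20, beta=[1.2, -1.2] + [0] * 18, seed=30,
                           censor_scale=0)
        lam = ic.select_lambda_ebic(ds)
        support = set(ic.fit_cox_lasso(ds, lam=lam).support.tolist())
        assert support == {0, 1}

    def test_null_data_selects_near_empty_model(self, make_survival):
        # at p this small the combinatorial penalty is mild; a stray noise
        # covariate or two can survive, but not a dense model
        ds = make_survival(60, 40, seed=31)
        lam = ic.select_lambda_ebic(ds)
        assert ic.fit_cox_lasso(ds, lam=lam).support.size <= 2


def test_null_gradient_matches_numerical_derivative(make_survival):
    ds = make_survival(20, 3, seed=40)
    g = null_gradient(ds, standardize=False)
    eps = 1e-6
    for j in range(3):
        e = np.zeros(3)
        e[j] = eps
        num = (
            ic.neg_log_partial_likelihood(e, ds)
            - ic.neg_log_partial_likelihood(-e, ds)
        ) / (2 * eps)
        assert g[j] == pytest.approx(-num, abs=1e-4)


def test_batched_loglik_agrees_with_scalar(make_survival):
    ds = make_survival(30, 4, seed=41)
    B = np.random.default_rng(0).normal(size=(4, 6))
    batch = breslow_loglik_batch(ds.X @ B, ds)
    singles = [-ic.neg_log_partial_likelihood(B[:, j], ds) for j in range(6)]
    assert batch == pytest.approx(singles, rel=1e-12)
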