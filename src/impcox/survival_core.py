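"""Cox proportional-hazards machinery shared by every selection stage.

Implements the Breslow partial likelihood (tied event times share one
risk-set denominator), an unpenalized Newton-Raphson maximizer with Wald
inference from the observed information, an L1-penalized (lasso) fit, and
cross-validated penalty selection in the Verweij-van Houwelingen form
(held-out contribution = full-data minus training-data partial likelihood).

The penalized path solver is scikit-survival's Coxnet coordinate descent;
everything here works on the *sum* scale of the log partial likelihood

    l(beta) = sum_{k in D} [ eta_k - d_k * log sum_{j in R_k} exp(eta_j) ]

where D indexes distinct event times, d_k counts tied events, and R_k is
the risk set (observed time >= t_k).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the log-likelihood trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message} (loglik trace: {trace})")
        self.trace = trace


@dataclasses.dataclass
class SurvivalDataset:
    """Expression matrix aligned with right-censored survival outcomes.

    Parameters
    ----------
    X : (n, p) array of covariate values (samples x genes), no missing values.
    time : (n,) strictly positive event or censoring times.
    event : (n,) indicators, 1 = event observed, 0 = censored.
    covariate_names : p unique identifiers aligned with the columns of X.
    """

    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    covariate_names: list[str]
    _cache: dict | None = dataclasses.field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.event = np.asarray(self.event).ravel().astype(int)
        self.covariate_names = list(self.covariate_names)
        n, p = self.X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 samples and p >= 1 covariates, got {n} x {p}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if len(self.time) != n or len(self.event) != n:
            raise ValueError("time/event length does not match number of rows of X")
        if np.any(self.time <= 0) or not np.all(np.isfinite(self.time)):
            raise ValueError("times must be strictly positive and finite")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if len(self.covariate_names) != p:
            raise ValueError("covariate_names length does not match columns of X")
        if len(set(self.covariate_names)) != p:
            raise ValueError("covariate_names must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def take_covariates(self, indices) -> "SurvivalDataset":
        """Column subset (new dataset, survival vectors shared by copy)."""
        indices = np.asarray(indices, dtype=int)
        return SurvivalDataset(
            self.X[:, indices],
            self.time.copy(),
            self.event.copy(),
            [self.covariate_names[i] for i in indices],
        )

    def take_samples(self, rows) -> "SurvivalDataset":
        rows = np.asarray(rows, dtype=int)
        return SurvivalDataset(
            self.X[rows], self.time[rows], self.event[rows], list(self.covariate_names)
        )

    def name_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.covariate_names)}
        try:
            return np.array([lookup[g] for g in names], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"covariate {exc.args[0]!r} not in dataset") from exc

    def breslow_cache(self) -> dict:
        """Sorted-order bookkeeping for risk-set sums (built once, reused)."""
        if self._cache is None:
            order = np.argsort(self.time, kind="stable")
            t = self.time[order]
            e = self.event[order].astype(bool)
            uniq, d = np.unique(t[e], return_counts=True)
            first = np.searchsorted(t, uniq, side="left")
            self._cache = {
                "order": order,
                "event_rows": np.flatnonzero(e),
                "uniq": uniq,
                "d": d.astype(float),
                "first": first,
            }
        return self._cache


@dataclasses.dataclass
class CoxFit:
    """Result of one Cox fit over an explicit covariate subset.

    ``beta`` is aligned with ``covariate_index``; ``wald_p`` is present only
    for unpenalized Newton fits; ``lam`` is the L1 penalty (0 = unpenalized).
    ``loglik`` is always the *unpenalized* Breslow log partial likelihood at
    the returned coefficients.
    """

    covariate_index: np.ndarray
    beta: np.ndarray
    loglik: float
    wald_p: np.ndarray | None = None
    lam: float = 0.0
    n_iter: int = 0
    converged: bool = True
    names: list[str] | None = None

    def __post_init__(self):
        self.covariate_index = np.asarray(self.covariate_index, dtype=int)
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != len(self.covariate_index):
            raise ValueError("beta and covariate_index lengths differ")
        if self.wald_p is not None:
            self.wald_p = np.asarray(self.wald_p, dtype=float)
            if np.any((self.wald_p < 0) | (self.wald_p > 1)):
                raise ValueError("wald_p must lie in [0, 1]")

    @property
    def support(self) -> np.ndarray:
        """Indices (into the original covariate space) with nonzero beta."""
        return self.covariate_index[self.beta != 0]


def _column_sd(X: np.ndarray) -> np.ndarray:
    """Column SDs with exact zeros for (numerically) constant columns."""
    sd = X.std(axis=0)
    degenerate = (np.ptp(X, axis=0) == 0) | (
        sd < 1e-10 * np.maximum(1.0, np.abs(X).max(axis=0))
    )
    return np.where(degenerate, 0.0, sd)


def _reverse_cumsum(a: np.ndarray) -> np.ndarray:
    return np.flip(np.cumsum(np.flip(a, axis=0), axis=0), axis=0)


def _check_events(dataset: SurvivalDataset) -> None:
    if dataset.n_events == 0:
        raise ValueError("no observed events")


def _subset_array(dataset: SurvivalDataset, subset) -> np.ndarray:
    if subset is None:
        return np.arange(dataset.p)
    subset = np.asarray(subset, dtype=int)
    if subset.ndim != 1:
        raise ValueError("subset must be one-dimensional")
    if subset.size and (subset.min() < 0 or subset.max() >= dataset.p):
        raise ValueError("subset indices out of range")
    return subset


def breslow_loglik_batch(eta: np.ndarray, dataset: SurvivalDataset) -> np.ndarray:
    """Log partial likelihood for one or many linear predictors.

    ``eta`` has shape (n,) or (n, L); returns a scalar array of shape () or (L,).
    """
    cache = dataset.breslow_cache()
    eta = np.asarray(eta, dtype=float)
    squeeze = eta.ndim == 1
    if squeeze:
        eta = eta[:, None]
    eta_s = eta[cache["order"]]
    m = eta_s.max(axis=0)
    w = np.exp(eta_s - m)
    log_s0 = np.log(_reverse_cumsum(w)[cache["first"]]) + m  # (T, L)
    ll = eta_s[cache["event_rows"]].sum(axis=0) - (cache["d"][:, None] * log_s0).sum(axis=0)
    return ll[0] if squeeze else ll


def neg_log_partial_likelihood(beta, dataset: SurvivalDataset, subset=None) -> float:
    """Negative Breslow log partial likelihood at ``beta`` over ``subset``."""
    _check_events(dataset)
    subset = _subset_array(dataset, subset)
    beta = np.asarray(beta, dtype=float).ravel()
    if len(beta) != len(subset):
        raise ValueError(
            f"beta has length {len(beta)} but subset has {len(subset)} covariates"
        )
    eta = dataset.X[:, subset] @ beta if len(subset) else np.zeros(dataset.n)
    return float(-breslow_loglik_batch(eta, dataset))


def _derivs(Xs: np.ndarray, eta_s: np.ndarray, cache: dict, need_info: bool):
    """(loglik, gradient, observed information) in the sorted frame."""
    d, first, event_rows = cache["d"], cache["first"], cache["event_rows"]
    m = eta_s.max() if eta_s.size else 0.0
    w = np.exp(eta_s - m)
    s0 = _reverse_cumsum(w)[first]
    loglik = float(eta_s[event_rows].sum() - (d * (np.log(s0) + m)).sum())
    wx = w[:, None] * Xs
    s1 = _reverse_cumsum(wx)[first]
    mu = s1 / s0[:, None]
    grad = Xs[event_rows].sum(axis=0) - (d[:, None] * mu).sum(axis=0)
    info = None
    if need_info:
        s2 = _reverse_cumsum(wx[:, :, None] * Xs[:, None, :])[first]
        info = (
            d[:, None, None] * (s2 / s0[:, None, None] - mu[:, :, None] * mu[:, None, :])
        ).sum(axis=0)
    return loglik, grad, info


def fit_cox(
    dataset: SurvivalDataset,
    subset=None,
    ridge_eps: float = 0.0,
    tol: float = 1e-9,
    max_iter: int = 100,
    warm_start: np.ndarray | None = None,
) -> CoxFit:
    """Unpenalized Newton-Raphson Cox MLE with Wald p-values.

    Zero-variance covariates are assigned beta = 0, p = 1 rather than
    erroring; a small ridge (``ridge_eps``) stabilizes near-singular
    information matrices. Convergence: relative log-likelihood change < tol.
    """
    _check_events(dataset)
    subset = _subset_array(dataset, subset)
    k = len(subset)
    names = [dataset.covariate_names[i] for i in subset]
    if k == 0:
        ll0 = float(breslow_loglik_batch(np.zeros(dataset.n), dataset))
        return CoxFit(subset, np.zeros(0), ll0, np.zeros(0), names=names)

    Xsub = dataset.X[:, subset]
    active = _column_sd(Xsub) > 0
    if k >= dataset.n_events:
        warnings.warn(
            f"{k} covariates but only {dataset.n_events} events; "
            "applying ridge_eps stabilizer",
            stacklevel=2,
        )
    cache = dataset.breslow_cache()
    Xa = Xsub[:, active][cache["order"]]
    ka = int(active.sum())

    beta = np.zeros(ka)
    if warm_start is not None:
        ws = np.asarray(warm_start, dtype=float)
        if len(ws) == k:
            beta = ws[active].copy()
        elif len(ws) == ka:
            beta = ws.copy()
        else:
            raise ValueError("warm_start length mismatch")

    def objective(b):
        ll, g, info = _derivs(Xa, Xa @ b, cache, need_info=True)
        pen = 0.5 * ridge_eps * float(b @ b)
        return ll - pen, g - ridge_eps * b, info + ridge_eps * np.eye(ka)

    f, g, H = objective(beta)
    trace = [f]
    converged = ka == 0
    it = 0
    for it in range(1, max_iter + 1):
        if ka == 0:
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix; retry with ridge_eps > 0"
            ) from exc
        if not np.all(np.isfinite(step)):
            raise np.linalg.LinAlgError(
                "singular information matrix; retry with ridge_eps > 0"
            )
        s = 1.0
        for _ in range(40):
            cand = beta + s * step
            f_new, g_new, H_new = objective(cand)
            if f_new >= f - 1e-12:
                break
            s *= 0.5
        else:  # pragma: no cover - pathological
            raise ConvergenceError("line search failed", trace)
        beta, rel = cand, abs(f_new - f) / (abs(f) + 1.0)
        f, g, H = f_new, g_new, H_new
        trace.append(f)
        if rel < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence after {max_iter} iterations", trace)

    # Wald inference from the observed information at the optimum.
    p_act = np.ones(ka)
    if ka:
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(se > 0, beta / se, 0.0)
            p_act = 2.0 * stats.norm.sf(np.abs(z))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix; retry with ridge_eps > 0"
            ) from exc

    beta_full = np.zeros(k)
    p_full = np.ones(k)
    beta_full[active] = beta
    p_full[active] = p_act
    eta = Xsub @ beta_full
    loglik = float(breslow_loglik_batch(eta, dataset))
    return CoxFit(subset, beta_full, loglik, p_full, n_iter=it, names=names)


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = _column_sd(X)
    scale = np.where(sd > 0, sd, 1.0)
    return (X - mu) / scale, mu, sd


def null_gradient(dataset: SurvivalDataset, subset=None, standardize: bool = True):
    """Gradient of the log partial likelihood at beta = 0 (optionally on
    standardized columns); its max |component| is lambda_max for the lasso."""
    _check_events(dataset)
    subset = _subset_array(dataset, subset)
    cache = dataset.breslow_cache()
    Xsub = dataset.X[:, subset]
    if standardize:
        Xsub, _, _ = _standardize(Xsub)
    Xs = Xsub[cache["order"]]
    _, g, _ = _derivs(Xs, np.zeros(dataset.n), cache, need_info=False)
    return g


def lambda_max(dataset: SurvivalDataset, subset=None) -> float:
    """Smallest penalty with an all-zero lasso solution (KKT at the null)."""
    g = null_gradient(dataset, subset, standardize=True)
    return float(np.max(np.abs(g))) if g.size else 0.0


def _coxnet_path(Z: np.ndarray, time, event, lams: np.ndarray, n: int) -> np.ndarray:
    """Solve the lasso Cox path at the requested penalties (sum-loglik scale).

    Coxnet minimizes -(2/n) loglik + 2*alpha*||beta||_1 in glmnet's
    parameterization, so alpha = lam / n maps our sum-scale penalty onto
    its grid. Returns a (p, len(lams)) coefficient matrix on the scale of Z.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    lams = np.asarray(lams, dtype=float)
    order = np.argsort(-lams, kind="stable")
    alphas = np.maximum(lams[order] / n, 1e-12)
    # strictly decreasing, as the path solver requires
    alphas = np.minimum.accumulate(alphas * (1 - 1e-12 * np.arange(len(alphas))))
    y = Surv.from_arrays(event=np.asarray(event, dtype=bool), time=time)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        alphas=alphas,
        normalize=False,
        fit_baseline_model=False,
        tol=1e-7,
        max_iter=200000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Z, y)
    coefs = np.zeros((Z.shape[1], len(lams)))
    fitted = np.asarray(model.alphas_)
    # map each requested alpha to the closest fitted one (solver may drop some)
    for out_pos, a in zip(order, alphas):
        j = int(np.argmin(np.abs(fitted - a)))
        coefs[:, out_pos] = model.coef_[:, j]
    return coefs


def fit_cox_lasso(
    dataset: SurvivalDataset,
    subset=None,
    lam: float = 0.0,
) -> CoxFit:
    """L1-penalized Cox fit: minimize neg-loglik + lam * sum |beta_j|.

    Covariates are standardized internally; the returned coefficients are on
    the original covariate scale with exact zeros preserved. ``lam`` lives on
    the sum-log-likelihood scale (compare :func:`lambda_max`). ``lam = 0``
    delegates to the unpenalized Newton fit.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    _check_events(dataset)
    subset = _subset_array(dataset, subset)
    if lam == 0:
        return fit_cox(dataset, subset)
    k = len(subset)
    names = [dataset.covariate_names[i] for i in subset]
    Xsub = dataset.X[:, subset]
    Z, _, sd = _standardize(Xsub)
    active = sd > 0
    beta_full = np.zeros(k)
    lmax = lambda_max(dataset, subset)
    if lam < lmax and active.any():
        # short warm-start path down to the target penalty for stability
        path = np.geomspace(lmax, lam, num=12)
        coefs = _coxnet_path(Z[:, active], dataset.time, dataset.event, path, dataset.n)
        beta_std = coefs[:, -1]
        beta_full[active] = beta_std / sd[active]
    eta = Xsub @ beta_full
    loglik = float(breslow_loglik_batch(eta, dataset))
    return CoxFit(subset, beta_full, loglik, wald_p=None, lam=lam, names=names)


def _stratified_folds(event: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic event-stratified fold assignment (0..n_folds-1 per sample)."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(event), dtype=int)
    for value in (1, 0):
        idx = np.flatnonzero(event == value)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def select_lambda_cv(
    dataset: SurvivalDataset,
    subset=None,
    n_lambda: int = 100,
    n_folds: int = 5,
    seed: int = 0,
    lambda_min_ratio: float = 0.01,
) -> float:
    """Pick the lasso penalty maximizing the cross-validated partial likelihood.

    Uses the Verweij-van Houwelingen criterion: for each fold, the held-out
    contribution is loglik(full data) - loglik(training data), both evaluated
    at the training-fold path coefficients. Grid: ``n_lambda`` log-spaced
    values from lambda_max down to ``lambda_min_ratio * lambda_max``.
    Deterministic given ``seed``; folds are event-stratified.
    """
    _check_events(dataset)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > dataset.n:
        raise ValueError("n_folds exceeds the number of samples")
    if dataset.n_events < n_folds:
        raise ValueError(
            f"cannot build {n_folds} event-stratified folds from "
            f"{dataset.n_events} events"
        )
    subset = _subset_array(dataset, subset)
    lmax = lambda_max(dataset, subset)
    if lmax == 0:
        return 0.0
    grid = np.geomspace(lmax, lambda_min_ratio * lmax, num=n_lambda)
    folds = _stratified_folds(dataset.event, n_folds, seed)
    Xsub = dataset.X[:, subset]
    cv = np.zeros(n_lambda)
    for f in range(n_folds):
        train = np.flatnonzero(folds != f)
        ds_train = SurvivalDataset(
            Xsub[train],
            dataset.time[train],
            dataset.event[train],
            [dataset.covariate_names[i] for i in subset],
        )
        Z, _, sd = _standardize(ds_train.X)
        act = sd > 0
        coefs_std = np.zeros((len(subset), n_lambda))
        if act.any():
            coefs_std[act] = _coxnet_path(
                Z[:, act], ds_train.time, ds_train.event, grid, ds_train.n
            )
        beta_orig = coefs_std / np.where(sd > 0, sd, 1.0)[:, None]
        ll_full = breslow_loglik_batch(Xsub @ beta_orig, dataset)
        ll_train = breslow_loglik_batch(ds_train.X @ beta_orig, ds_train)
        cv += np.asarray(ll_full) - np.asarray(ll_train)
    return float(grid[int(np.argmax(cv))])


def select_lambda_ebic(
    dataset: SurvivalDataset,
    subset=None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    gamma: float = 0.5,
    ambient_p: int | None = None,
    max_df_frac: float = 1 / 3,
) -> float:
    """Pick the lasso penalty minimizing the extended BIC along the path.

    Each distinct support S encountered on the ``n_lambda``-point path is
    refit without penalty (lasso selects, MLE estimates) and scored with

        EBIC(S) = -2 loglik_MLE(S) + |S| log d + 2 gamma log C(P, |S|)

    where d is the event count (the effective sample size of a partial
    likelihood) and P = ``ambient_p`` is the size of the search space the
    support was drawn from (defaults to the number of columns in
    ``subset``/the dataset). Supports larger than ``max_df_frac * d`` are
    skipped as ill-posed. Returns the largest penalty whose support attains
    the minimum. Unlike cross-validated tuning, which targets out-of-sample
    prediction and systematically overselects, this criterion targets
    recovery of the true support.
    """
    _check_events(dataset)
    subset = _subset_array(dataset, subset)
    if ambient_p is None:
        ambient_p = len(subset)
    lmax = lambda_max(dataset, subset)
    if lmax == 0:
        return 0.0
    grid = np.geomspace(lmax, lambda_min_ratio * lmax, num=n_lambda)
    Xsub = dataset.X[:, subset]
    Z, _, sd = _standardize(Xsub)
    act = sd > 0
    coefs = np.zeros((len(subset), n_lambda))
    if act.any():
        coefs[act] = _coxnet_path(Z[:, act], dataset.time, dataset.event, grid, dataset.n)
    d_events = dataset.n_events
    ll0 = float(breslow_loglik_batch(np.zeros(dataset.n), dataset))
    best_lam, best_crit, seen = float(grid[0]), np.inf, set()
    for j in range(n_lambda):
        support = tuple(np.flatnonzero(coefs[:, j]))
        if support in seen:
            continue
        seen.add(support)
        k = len(support)
        if k > max(1, int(max_df_frac * d_events)):
            continue
        if k == 0:
            ll = ll0
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ll = fit_cox(dataset, subset[list(support)]).loglik
            except (np.linalg.LinAlgError, RuntimeError):
                continue
        lchoose = (
            gammaln(ambient_p + 1) - gammaln(k + 1) - gammaln(ambient_p - k + 1)
        )
        crit = -2.0 * ll + k * np.log(d_events) + 2.0 * gamma * lchoose
        if crit < best_crit - 1e-10:
            best_crit, best_lam = crit, float(grid[j])
    return best_lam
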