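"""Risk-score discrimination: time-dependent ROC curves and AUC.

A fitted model scores each sample with its linear predictor eta. At a
horizon t*, cases are samples with an observed event by t* and controls are
samples still under observation beyond t*. Samples censored before t* are
either reweighted away (inverse probability of censoring weighting, the
cumulative/dynamic estimator) or discarded. The ROC sweeps every score
threshold; tied scores are averaged over orderings (diagonal ROC
segments), and the AUC is the trapezoidal area.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .selection import (
    ALGORITHMS,
    SelectionConfig,
    SelectionResult,
    run_comparator,
)
from .survival_core import CoxFit, SurvivalDataset, _stratified_folds

ROC_METHODS = ("ipcw", "discard_ambiguous")


@dataclasses.dataclass
class RiskScoreEvaluation:
    """ROC at one horizon: ordered (FPR, TPR) pairs and the area under them."""

    horizon: float
    roc_points: np.ndarray  # (k, 2) columns FPR, TPR
    auc: float
    n_evaluable: int
    n_cases: int
    n_controls: int


def risk_score(fit, dataset: SurvivalDataset) -> np.ndarray:
    """Linear predictor per sample for a CoxFit or a SelectionResult.

    For a SelectionResult the model columns (including interaction products)
    are rebuilt from the training-time standardization recorded in its terms.
    """
    if isinstance(fit, SelectionResult):
        if fit.final_fit is None or len(fit.terms) == 0:
            return np.zeros(dataset.n)
        design = np.column_stack([t.column(dataset) for t in fit.terms])
        return design @ fit.final_fit.beta
    if isinstance(fit, CoxFit):
        if len(fit.covariate_index) == 0:
            return np.zeros(dataset.n)
        return dataset.X[:, fit.covariate_index] @ fit.beta
    raise TypeError("fit must be a CoxFit or SelectionResult")


def _censoring_survival(dataset: SurvivalDataset, times: np.ndarray) -> np.ndarray:
    """Kaplan-Meier estimate of the censoring survival function G at
    ``times`` (left limits: evaluated just before each time)."""
    from sksurv.nonparametric import kaplan_meier_estimator

    cens_event = dataset.event == 0
    if not cens_event.any():
        return np.ones_like(times, dtype=float)
    uniq, surv = kaplan_meier_estimator(cens_event, dataset.time)
    # right-continuous step function; left limit = value at the previous step
    idx = np.searchsorted(uniq, times, side="left") - 1
    G = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
    return np.clip(G, 1e-12, None)


def time_dependent_roc(
    scores,
    dataset: SurvivalDataset,
    horizon: float,
    method: str = "ipcw",
) -> RiskScoreEvaluation:
    """Cumulative/dynamic ROC of ``scores`` for events by ``horizon``."""
    if method not in ROC_METHODS:
        raise ValueError(f"method must be one of {ROC_METHODS}")
    scores = np.asarray(scores, dtype=float).ravel()
    if len(scores) != dataset.n:
        raise ValueError("scores length does not match dataset")
    if not dataset.time.min() <= horizon <= dataset.time.max():
        raise ValueError("horizon outside the observed time range")
    cases = (dataset.event == 1) & (dataset.time <= horizon)
    controls = dataset.time > horizon
    n_cases, n_controls = int(cases.sum()), int(controls.sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"cannot form ROC at horizon {horizon}: "
            f"{n_cases} cases, {n_controls} controls"
        )
    w_case = np.ones(n_cases)
    if method == "ipcw":
        G = _censoring_survival(dataset, dataset.time[cases])
        w_case = 1.0 / G  # the common control weight 1/G(horizon) cancels
    w_ctrl = np.ones(n_controls)

    s_case, s_ctrl = scores[cases], scores[controls]
    thresholds = np.unique(np.concatenate([s_case, s_ctrl]))[::-1]
    tp = np.array([w_case[s_case >= c].sum() for c in thresholds])
    fp = np.array([w_ctrl[s_ctrl >= c].sum() for c in thresholds])
    tpr = np.concatenate([[0.0], tp / w_case.sum(), [1.0]])
    fpr = np.concatenate([[0.0], fp / w_ctrl.sum(), [1.0]])
    roc = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return RiskScoreEvaluation(
        horizon=float(horizon),
        roc_points=roc,
        auc=auc,
        n_evaluable=n_cases + n_controls,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def stratified_split(
    dataset: SurvivalDataset, test_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Event-stratified train/test row split, deterministic per seed."""
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for value in (1, 0):
        idx = np.flatnonzero(dataset.event == value)
        rng.shuffle(idx)
        k = int(round(test_frac * len(idx)))
        test.extend(idx[:k])
        train.extend(idx[k:])
    return np.sort(np.array(train)), np.sort(np.array(test))


@dataclasses.dataclass
class ComparisonResult:
    """Held-out AUC of several algorithms over repeated train/test splits."""

    per_split: pd.DataFrame  # columns: algorithm, split, auc
    horizon: float
    rocs: dict  # (algorithm, split) -> RiskScoreEvaluation

    @property
    def summary(self) -> pd.DataFrame:
        g = self.per_split.groupby("algorithm", sort=False)["auc"]
        return pd.DataFrame({"mean_auc": g.mean(), "sd_auc": g.std(ddof=1)})


def compare_algorithms(
    dataset: SurvivalDataset,
    algorithms=("ImpCoxSisLasso", "CoxLasso"),
    n_splits: int = 20,
    seed: int = 0,
    test_frac: float = 0.3,
    horizon: float | None = None,
    roc_method: str = "ipcw",
    config: SelectionConfig | None = None,
) -> ComparisonResult:
    """Train each algorithm on repeated stratified 70/30 splits and score
    the held-out samples with the time-dependent AUC at ``horizon``
    (default: median observed follow-up of the full dataset)."""
    if len(algorithms) < 2:
        raise ValueError("need at least two algorithms to compare")
    for a in algorithms:
        if a not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {a!r}")
    base = config or SelectionConfig()
    if horizon is None:
        horizon = float(np.median(dataset.time))
    rows, rocs = [], {}
    for s in range(n_splits):
        split_seed = int(np.random.SeedSequence([seed, s]).generate_state(1)[0] % 2**31)
        train, test = stratified_split(dataset, test_frac, split_seed)
        ds_train = dataset.take_samples(train)
        ds_test = dataset.take_samples(test)
        for algo in algorithms:
            cfg = dataclasses.replace(base, seed=split_seed)
            try:
                result = run_comparator(ds_train, algo, cfg)
                scores = risk_score(result, ds_test)
                ev = time_dependent_roc(scores, ds_test, horizon, roc_method)
            except Exception as exc:
                raise RuntimeError(f"{algo} failed on split {s}: {exc}") from exc
            rows.append({"algorithm": algo, "split": s, "auc": ev.auc})
            rocs[(algo, s)] = ev
    return ComparisonResult(
        per_split=pd.DataFrame(rows), horizon=horizon, rocs=rocs
    )


def plot_roc(evaluations: dict, path: str) -> None:
    """Save ROC curves (one per labelled evaluation) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, ev in evaluations.items():
        ax.plot(ev.roc_points[:, 0], ev.roc_points[:, 1],
                label=f"{label} (AUC={ev.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
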