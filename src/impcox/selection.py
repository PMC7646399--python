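"""The four-stage ImpCoxSisLasso gene-selection pipeline and its comparators.

Stage 1 (lasso screen): L1-penalized Cox fit over all genes; the support is
C0. Stage 2 (conditional screen): for every gene m outside C0, jointly
refit the Cox model on C0 + {m} and keep m when the Wald p-value of its
coefficient falls below a threshold (default 1/p) — a sure-independence
screening variant conditioned on the lasso picks. Stage 3 (lasso refit):
a fresh penalized fit restricted to Theta = C0 U C1; the support is the
final main-effect set C. Stage 4 (interaction fit): unpenalized Cox fit of
all main effects in C plus every unordered pairwise product of their
standardized expression values, with an L1 fallback when the parameter
count reaches the event count.

Comparators: CoxLasso (stage 1 only), CoxSis (marginal screening followed
by a Cox fit on the survivors), and CoxSisLasso (stages 1-3, no
interactions).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import warnings
from typing import Sequence

import numpy as np

from .survival_core import (
    CoxFit,
    SurvivalDataset,
    fit_cox,
    fit_cox_lasso,
    lambda_max,
    select_lambda_cv,
    select_lambda_ebic,
)

logger = logging.getLogger(__name__)

ALGORITHMS = ("CoxLasso", "CoxSis", "CoxSisLasso", "ImpCoxSisLasso")


@dataclasses.dataclass
class SelectionConfig:
    """Tunable knobs shared by all pipeline stages.

    ``screen_threshold`` defaults to 1/p (p = covariate count of the dataset
    being screened) when left as None. ``lambda_rule`` chooses the penalty
    for the selection stages 1 and 3: "ebic" (default; extended BIC on
    unpenalized refits along the path, targets support recovery) or "cv"
    (Verweij-van Houwelingen cross-validated partial likelihood, targets
    prediction). Prediction fallbacks always use CV, seeded
    deterministically per stage from ``seed``.
    """

    seed: int = 0
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    n_folds: int = 5
    screen_threshold: float | None = None
    lambda_rule: str = "ebic"
    ebic_gamma: float = 0.5
    stage1_lambda: float | None = None
    stage3_lambda: float | None = None

    def __post_init__(self):
        if self.lambda_rule not in ("ebic", "cv"):
            raise ValueError("lambda_rule must be 'ebic' or 'cv'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ModelTerm:
    """One column of a final risk model: a main effect or a pairwise product.

    ``center``/``scale`` record the training-time standardization applied to
    each constituent gene (identity transform = 0/1), so the column can be
    rebuilt exactly on new samples.
    """

    name: str
    kind: str  # "main" | "interaction"
    genes: tuple[str, ...]
    center: tuple[float, ...]
    scale: tuple[float, ...]

    def column(self, dataset: SurvivalDataset) -> np.ndarray:
        idx = dataset.name_index(self.genes)
        cols = (dataset.X[:, idx] - np.array(self.center)) / np.array(self.scale)
        return cols.prod(axis=1)


@dataclasses.dataclass
class SelectionResult:
    """Everything produced by one algorithm run: the intermediate index sets
    C0 (stage-1 lasso support), C1 (stage-2 screen picks), Theta = C0 U C1,
    the final main-effect set C, the interaction pairs, and the final fit."""

    algorithm: str
    C0: np.ndarray
    C1: np.ndarray
    theta: np.ndarray
    C: np.ndarray
    interaction_pairs: list[tuple[int, int]]
    final_fit: CoxFit | None
    main_effect_names: list[str]
    interaction_names: list[str]
    terms: list[ModelTerm]
    penalized_fallback: bool = False
    config: SelectionConfig | None = None
    seed: int = 0

    def __post_init__(self):
        self.C0 = np.asarray(self.C0, dtype=int)
        self.C1 = np.asarray(self.C1, dtype=int)
        self.theta = np.asarray(self.theta, dtype=int)
        self.C = np.asarray(self.C, dtype=int)
        if np.intersect1d(self.C0, self.C1).size:
            raise ValueError("C0 and C1 must be disjoint")
        if not np.isin(self.C, self.theta).all():
            raise ValueError("C must be a subset of theta")
        cset = set(self.C.tolist())
        for i, j in self.interaction_pairs:
            if i == j or i not in cset or j not in cset:
                raise ValueError("interaction pairs must be distinct members of C")

    def to_dict(self) -> dict:
        fit = self.final_fit
        return {
            "algorithm": self.algorithm,
            "seed": int(self.seed),
            "C0": self.C0.tolist(),
            "C1": self.C1.tolist(),
            "theta": self.theta.tolist(),
            "C": self.C.tolist(),
            "interaction_pairs": [list(p) for p in self.interaction_pairs],
            "main_effect_names": self.main_effect_names,
            "interaction_names": self.interaction_names,
            "penalized_fallback": self.penalized_fallback,
            "config": self.config.to_dict() if self.config else None,
            "final_fit": None
            if fit is None
            else {
                "names": fit.names,
                "beta": fit.beta.tolist(),
                "loglik": fit.loglik,
                "wald_p": None if fit.wald_p is None else fit.wald_p.tolist(),
                "lambda": fit.lam,
            },
            "terms": [dataclasses.asdict(t) for t in self.terms],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _cv_lambda(dataset, subset, config: SelectionConfig, seed: int) -> float:
    return select_lambda_cv(
        dataset,
        subset=subset,
        n_lambda=config.n_lambda,
        n_folds=config.n_folds,
        seed=seed,
        lambda_min_ratio=config.lambda_min_ratio,
    )


def _selection_lambda(
    dataset, subset, config: SelectionConfig, seed: int, ambient_p: int
) -> float:
    """Penalty for the *selection* stages (1 and 3), per config.lambda_rule."""
    if config.lambda_rule == "cv":
        return _cv_lambda(dataset, subset, config, seed)
    return select_lambda_ebic(
        dataset,
        subset=subset,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
        gamma=config.ebic_gamma,
        ambient_p=ambient_p,
    )


def stage1_lasso(
    dataset: SurvivalDataset, config: SelectionConfig | None = None
) -> tuple[np.ndarray, CoxFit]:
    """Stage 1: lasso Cox over all genes; C0 = nonzero support."""
    config = config or SelectionConfig()
    lam = config.stage1_lambda
    if lam is None:
        lam = _selection_lambda(dataset, None, config, config.seed, dataset.p)
    fit = fit_cox_lasso(dataset, lam=lam)
    C0 = fit.support
    if C0.size == 0:
        warnings.warn("stage-1 lasso selected no covariates", stacklevel=2)
    return C0, fit


def stage2_conditional_screen(
    dataset: SurvivalDataset,
    C0,
    threshold: float | None = None,
    return_pvalues: bool = False,
):
    """Stage 2: conditional sure-independence screen given the lasso picks.

    For each gene m outside C0, the Cox model on C0 + {m} is maximized
    jointly (C0 coefficients re-estimated, not frozen) and m enters C1 when
    the two-sided Wald p-value of its coefficient is < ``threshold``
    (default 1/p). Per-gene fit failures are logged and excluded, not fatal.
    """
    C0 = np.asarray(C0, dtype=int)
    if threshold is None:
        threshold = 1.0 / dataset.p
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    warm = None
    if C0.size:
        base = fit_cox(dataset, C0)
        warm = np.append(base.beta, 0.0)
    picks, pvals = [], {}
    for m in range(dataset.p):
        if m in C0:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_cox(dataset, np.append(C0, m), warm_start=warm)
            p_m = float(fit.wald_p[-1])
        except (np.linalg.LinAlgError, RuntimeError) as exc:
            logger.warning("conditional fit failed for covariate %d: %s", m, exc)
            continue
        pvals[m] = p_m
        if p_m < threshold:
            picks.append(m)
    C1 = np.array(sorted(picks), dtype=int)
    return (C1, pvals) if return_pvalues else C1


def stage3_lasso_refit(
    dataset: SurvivalDataset, theta, config: SelectionConfig | None = None
) -> tuple[np.ndarray, CoxFit | None]:
    """Stage 3: lasso refit restricted to Theta (own CV for the penalty)."""
    config = config or SelectionConfig()
    theta = np.asarray(theta, dtype=int)
    if theta.size == 0:
        return np.array([], dtype=int), None
    lam = config.stage3_lambda
    if lam is None:
        # EBIC's combinatorial term uses the ambient gene count: Theta was
        # searched out of all p genes, not drawn from a fixed small pool.
        lam = _selection_lambda(dataset, theta, config, config.seed + 1, dataset.p)
    fit = fit_cox_lasso(dataset, subset=theta, lam=lam)
    return fit.support, fit


def _interaction_pairs(dataset: SurvivalDataset, C: np.ndarray):
    """Unordered gene pairs from C, lexicographic by gene name ('A_B' == 'B_A')."""
    by_name = sorted(C.tolist(), key=lambda i: dataset.covariate_names[i])
    return list(itertools.combinations(by_name, 2))


def build_interaction_terms(
    dataset: SurvivalDataset, C: np.ndarray
) -> tuple[list[ModelTerm], list[tuple[int, int]]]:
    """Main-effect terms (standardized) plus products of standardized pairs."""
    names = dataset.covariate_names
    mains_order = sorted(C.tolist(), key=lambda i: names[i])
    stats = {
        i: (float(dataset.X[:, i].mean()), float(dataset.X[:, i].std() or 1.0))
        for i in mains_order
    }
    terms = [
        ModelTerm(names[i], "main", (names[i],), (stats[i][0],), (stats[i][1],))
        for i in mains_order
    ]
    pairs = _interaction_pairs(dataset, C)
    for i, j in pairs:
        terms.append(
            ModelTerm(
                f"{names[i]}_{names[j]}",
                "interaction",
                (names[i], names[j]),
                (stats[i][0], stats[j][0]),
                (stats[i][1], stats[j][1]),
            )
        )
    return terms, pairs


def _design_dataset(dataset: SurvivalDataset, terms: list[ModelTerm]) -> SurvivalDataset:
    cols = np.column_stack([t.column(dataset) for t in terms])
    return SurvivalDataset(cols, dataset.time, dataset.event, [t.name for t in terms])


def stage4_interaction_fit(
    dataset: SurvivalDataset, C, config: SelectionConfig | None = None
):
    """Stage 4: unpenalized Cox MLE over main effects + all pairwise products.

    When the parameter count reaches the event count the written MLE is
    ill-posed, so an L1 penalty with CV replaces it (flagged in the result).
    Returns (interaction_pairs, CoxFit, terms, penalized_flag).
    """
    config = config or SelectionConfig()
    C = np.asarray(C, dtype=int)
    if C.size == 0:
        return [], None, [], False
    terms, pairs = build_interaction_terms(dataset, C)
    design = _design_dataset(dataset, terms)
    if design.p < dataset.n_events:
        fit = fit_cox(design)
        return pairs, fit, terms, False
    # re-standardize product columns for the penalized fallback
    lam = _cv_lambda(design, None, config, config.seed + 2)
    fit = fit_cox_lasso(design, lam=lam)
    return pairs, fit, terms, True


def _raw_terms(dataset: SurvivalDataset, indices: np.ndarray) -> list[ModelTerm]:
    names = dataset.covariate_names
    return [
        ModelTerm(names[i], "main", (names[i],), (0.0,), (1.0,)) for i in indices
    ]


def run_impcoxsislasso(
    dataset: SurvivalDataset, config: SelectionConfig | None = None
) -> SelectionResult:
    """Chain stages 1 -> 2 -> 3 -> 4; fully reproducible given config.seed."""
    config = config or SelectionConfig()
    try:
        C0, _ = stage1_lasso(dataset, config)
    except Exception as exc:
        raise RuntimeError(f"stage 1 (lasso screen) failed: {exc}") from exc
    try:
        C1 = stage2_conditional_screen(dataset, C0, config.screen_threshold)
    except Exception as exc:
        raise RuntimeError(f"stage 2 (conditional screen) failed: {exc}") from exc
    theta = np.union1d(C0, C1)
    try:
        C, _ = stage3_lasso_refit(dataset, theta, config)
    except Exception as exc:
        raise RuntimeError(f"stage 3 (lasso refit) failed: {exc}") from exc
    try:
        pairs, fit, terms, flagged = stage4_interaction_fit(dataset, C, config)
    except Exception as exc:
        raise RuntimeError(f"stage 4 (interaction fit) failed: {exc}") from exc
    names = dataset.covariate_names
    return SelectionResult(
        algorithm="ImpCoxSisLasso",
        C0=C0,
        C1=C1,
        theta=theta,
        C=np.sort(C),
        interaction_pairs=pairs,
        final_fit=fit,
        main_effect_names=[names[i] for i in np.sort(C)],
        interaction_names=[t.name for t in terms if t.kind == "interaction"],
        terms=terms,
        penalized_fallback=flagged,
        config=config,
        seed=config.seed,
    )


def run_comparator(
    dataset: SurvivalDataset, which: str, config: SelectionConfig | None = None
) -> SelectionResult:
    """CoxLasso (stage 1 only), CoxSis (marginal screen + Cox fit on
    survivors), or CoxSisLasso (stages 1-3, no interaction stage)."""
    config = config or SelectionConfig()
    names = dataset.covariate_names
    empty = np.array([], dtype=int)

    if which == "CoxLasso":
        C0, fit = stage1_lasso(dataset, config)
        C = np.sort(C0)
        active = fit.support
        terms = _raw_terms(dataset, active)
        final = CoxFit(
            active,
            fit.beta[fit.beta != 0],
            fit.loglik,
            lam=fit.lam,
            names=[names[i] for i in active],
        )
        return SelectionResult(
            "CoxLasso", C0, empty, C0, C, [], final,
            [names[i] for i in C], [], terms, False, config, config.seed,
        )

    if which == "CoxSis":
        survivors = stage2_conditional_screen(dataset, empty, config.screen_threshold)
        flagged = False
        if survivors.size == 0:
            fit, terms = None, []
        elif survivors.size < dataset.n_events:
            fit = fit_cox(dataset, survivors)
            terms = _raw_terms(dataset, survivors)
        else:
            lam = _cv_lambda(dataset, survivors, config, config.seed + 3)
            fit = fit_cox_lasso(dataset, subset=survivors, lam=lam)
            terms = _raw_terms(dataset, survivors)
            flagged = True
        return SelectionResult(
            "CoxSis", empty, survivors, survivors, survivors, [], fit,
            [names[i] for i in survivors], [], terms, flagged, config, config.seed,
        )

    if which == "CoxSisLasso":
        C0, _ = stage1_lasso(dataset, config)
        C1 = stage2_conditional_screen(dataset, C0, config.screen_threshold)
        theta = np.union1d(C0, C1)
        C, fit = stage3_lasso_refit(dataset, theta, config)
        C = np.sort(C)
        terms = _raw_terms(dataset, C)
        final = None
        if fit is not None:
            active = fit.support
            final = CoxFit(
                active,
                fit.beta[fit.beta != 0],
                fit.loglik,
                lam=fit.lam,
                names=[names[i] for i in active],
            )
        return SelectionResult(
            "CoxSisLasso", C0, C1, theta, C, [], final,
            [names[i] for i in C], [], terms, False, config, config.seed,
        )

    if which == "ImpCoxSisLasso":
        return run_impcoxsislasso(dataset, config)
    raise ValueError(f"unknown algorithm {which!r}; choose from {ALGORITHMS}")


def venn_intersection(results: Sequence[SelectionResult]) -> set[str]:
    """Genes selected as main effects by every algorithm (interaction terms
    excluded, matching a gene-level Venn diagram)."""
    if len(results) < 2:
        raise ValueError("need at least two results to intersect")
    sets = [set(r.main_effect_names) for r in results]
    return set.intersection(*sets)
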