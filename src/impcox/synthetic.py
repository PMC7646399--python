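"""Seeded generators for survival and RPPA data with known ground truth.

The survival generator emulates a P >> N expression-survival matrix:
block-correlated standard-normal gene values, a sparse linear predictor
with main effects and pairwise gene-gene interaction products, event times
from an exponential or Weibull baseline hazard multiplied by exp(eta), and
independent exponential censoring whose rate is root-found so the expected
censoring fraction matches the target. The RPPA generator draws log-normal
replicate intensities around protein-specific baselines, with a chosen set
of proteins shifted multiplicatively in the experimental group.

Default survival scale: n = 200 samples, p = 1000 genes, five main effects
of size |beta| = 0.8 in distinct correlation blocks, two interactions of
size |beta| = 0.6 between main-effect genes, equicorrelation rho = 0.3 in
blocks of 10, exponential baseline with median just under a year (time unit
months), 30% censoring.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import optimize

from .rppa import RPPAExperiment
from .survival_core import SurvivalDataset


def _default_main() -> dict[int, float]:
    return {0: 0.8, 10: -0.8, 20: 0.8, 30: -0.8, 40: 0.8}


def _default_interactions() -> dict[tuple[int, int], float]:
    return {(0, 10): 0.6, (20, 30): -0.6}


@dataclasses.dataclass
class SurvivalSimSpec:
    """Parameters of one simulated expression-survival dataset."""

    n: int = 200
    p: int = 1000
    true_main: dict[int, float] = dataclasses.field(default_factory=_default_main)
    true_interactions: dict[tuple[int, int], float] = dataclasses.field(
        default_factory=_default_interactions
    )
    rho: float = 0.3
    block_size: int = 10
    baseline: tuple = ("exponential", 0.06)
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        for i in self.true_main:
            if not 0 <= i < self.p:
                raise ValueError(f"main-effect index {i} out of range")
        for i, j in self.true_interactions:
            if i == j or not (0 <= i < self.p and 0 <= j < self.p):
                raise ValueError(f"bad interaction pair ({i}, {j})")
        if self.baseline[0] not in ("exponential", "weibull"):
            raise ValueError("baseline must be exponential(rate) or weibull(shape, scale)")


@dataclasses.dataclass
class SimTruth:
    """Ground-truth record sufficient to score support recovery."""

    main: dict[str, float]
    interactions: dict[tuple[str, str], float]
    eta: np.ndarray
    censoring_target: float
    censoring_achieved: float

    @property
    def main_names(self) -> set[str]:
        return set(self.main)

    @property
    def interaction_name_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted(p)) for p in self.interactions}


def gene_names(p: int) -> list[str]:
    width = max(4, len(str(p - 1)))
    return [f"G{i:0{width}d}" for i in range(p)]


def simulate_survival(spec: SurvivalSimSpec) -> tuple[SurvivalDataset, SimTruth]:
    """Draw one dataset and its truth record; bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    n, p, b = spec.n, spec.p, spec.block_size
    n_blocks = math.ceil(p / b)
    z = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, p))
    block_of = np.arange(p) // b
    X = math.sqrt(spec.rho) * z[:, block_of] + math.sqrt(1 - spec.rho) * eps

    eta = np.zeros(n)
    for j, beta in spec.true_main.items():
        eta += beta * X[:, j]
    for (i, j), beta in spec.true_interactions.items():
        eta += beta * X[:, i] * X[:, j]

    E = rng.exponential(1.0, n)
    if spec.baseline[0] == "exponential":
        rate = spec.baseline[1]
        T = E / (rate * np.exp(eta))
    else:
        shape, scale = spec.baseline[1], spec.baseline[2]
        T = scale * (E / np.exp(eta)) ** (1.0 / shape)

    if spec.censoring_rate == 0:
        time, event = T, np.ones(n, dtype=int)
    else:
        # expected censoring fraction given the drawn T's, as a function of
        # the exponential censoring rate theta: mean(1 - exp(-theta * T))
        def gap(theta):
            return np.mean(1.0 - np.exp(-theta * T)) - spec.censoring_rate

        hi = 1.0
        while gap(hi) < 0:
            hi *= 10.0
            if hi > 1e12:  # pragma: no cover
                break
        theta = optimize.brentq(gap, 1e-15, hi)
        Cens = rng.exponential(1.0 / theta, n)
        event = (T <= Cens).astype(int)
        time = np.minimum(T, Cens)

    achieved = 1.0 - float(event.mean())
    if abs(achieved - spec.censoring_rate) > 0.05:
        warnings.warn(
            f"achieved censoring rate {achieved:.3f} misses target "
            f"{spec.censoring_rate:.3f} by more than 0.05",
            stacklevel=2,
        )
    names = gene_names(p)
    dataset = SurvivalDataset(X, time, event, names)
    truth = SimTruth(
        main={names[j]: v for j, v in spec.true_main.items()},
        interactions={
            tuple(sorted((names[i], names[j]))): v
            for (i, j), v in spec.true_interactions.items()
        },
        eta=eta,
        censoring_target=spec.censoring_rate,
        censoring_achieved=achieved,
    )
    return dataset, truth


def score_support(selected, truth_names) -> tuple[float, float, float]:
    """(precision, recall, F1) of a selected name set against the truth."""
    selected, truth_names = set(selected), set(truth_names)
    tp = len(selected & truth_names)
    precision = tp / len(selected) if selected else 0.0
    recall = tp / len(truth_names) if truth_names else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def simulate_rppa(
    n_proteins: int = 300,
    m: int = 2,
    shifted: dict[int, float] | None = None,
    noise_cv: float = 0.1,
    seed: int = 0,
    direction: str = "Up",
) -> tuple[RPPAExperiment, dict[str, float]]:
    """Replicated RPPA tables with a known set of shifted proteins.

    Control intensities are log-normal around protein-specific baselines
    (median 1000 a.u., log-scale SD 1 across proteins); experimental values
    multiply the baseline by the protein's shift (1 = null) before applying
    independent log-normal replicate noise of coefficient of variation
    ``noise_cv``.
    """
    if noise_cv <= 0:
        raise ValueError("noise_cv must be positive")
    shifted = shifted or {}
    if any(s <= 0 for s in shifted.values()):
        raise ValueError("shifts must be positive")
    rng = np.random.default_rng(seed)
    names = [f"P{i:04d}" for i in range(n_proteins)]
    baseline = np.exp(rng.normal(math.log(1000.0), 1.0, n_proteins))
    shift = np.ones(n_proteins)
    for i, s in shifted.items():
        shift[i] = s
    sigma = noise_cv  # log-normal sigma ~ CV for small CV
    ctrl = baseline[:, None] * np.exp(rng.normal(0, sigma, (n_proteins, m)))
    exp_ = (baseline * shift)[:, None] * np.exp(rng.normal(0, sigma, (n_proteins, m)))
    experiment = RPPAExperiment(direction, names, exp_, ctrl)
    truth = {names[i]: s for i, s in shifted.items()}
    return experiment, truth
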