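"""Differential-protein calling from replicated RPPA experiments.

A reverse-phase protein array (RPPA) run yields one intensity per protein
per replicate for an experimental group (here, a gene perturbation) and a
control group. The fold change for protein i is the ratio of replicate
sums,

    FC_i = sum_j ExP_ij / sum_j CoP_ij,

labelled UP when FC_i > 1 and DOWN when FC_i <= 1 (boundary on DOWN).
A two-sample t-test per protein (equal-variance Student by default, Welch
optional) supplies p-values; candidates significant at a raw p < alpha are
reported. No multiple-testing correction is applied by default; a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

DIRECTIONS = ("Up", "Down")


@dataclasses.dataclass
class RPPAExperiment:
    """Paired experimental/control replicate matrices for one perturbation
    direction (overexpression = "Up", knockdown = "Down")."""

    direction: str
    protein_names: list[str]
    exp_values: np.ndarray
    ctrl_values: np.ndarray

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        self.exp_values = np.atleast_2d(np.asarray(self.exp_values, dtype=float))
        self.ctrl_values = np.atleast_2d(np.asarray(self.ctrl_values, dtype=float))
        self.protein_names = list(self.protein_names)
        if self.exp_values.shape != self.ctrl_values.shape:
            raise ValueError("experimental and control matrices differ in shape")
        if self.exp_values.shape[0] != len(self.protein_names):
            raise ValueError("protein_names length does not match matrix rows")
        if len(set(self.protein_names)) != len(self.protein_names):
            raise ValueError("protein names must be unique")
        if self.exp_values.shape[1] < 1:
            raise ValueError("need at least one replicate")
        if np.any(self.exp_values <= 0) or np.any(self.ctrl_values <= 0):
            raise ValueError("intensities must be strictly positive")

    @property
    def n_proteins(self) -> int:
        return self.exp_values.shape[0]

    @property
    def m(self) -> int:
        return self.exp_values.shape[1]


@dataclasses.dataclass
class ProteinCall:
    protein_name: str
    fc: float
    judgement: str  # "UP" | "DOWN"
    p_value: float
    significant: bool

    def __post_init__(self):
        expected = judge(self.fc)
        if self.judgement != expected:
            raise ValueError(
                f"judgement {self.judgement} inconsistent with fc={self.fc}"
            )


def fold_change(experiment: RPPAExperiment) -> np.ndarray:
    """FC_i = ratio of replicate sums, experimental over control."""
    denom = experiment.ctrl_values.sum(axis=1)
    bad = np.flatnonzero(denom <= 0)
    if bad.size:  # unreachable through the validated type; guards raw arrays
        raise ValueError(
            f"non-positive control sum for protein {experiment.protein_names[bad[0]]}"
        )
    return experiment.exp_values.sum(axis=1) / denom


def judge(fc: float) -> str:
    """UP iff fc > 1; DOWN iff fc <= 1 (boundary inclusive on DOWN)."""
    if fc <= 0:
        raise ValueError("fold change must be positive")
    return "UP" if fc > 1 else "DOWN"


def _ttest_rows(exp_values, ctrl_values, variant: str) -> np.ndarray:
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    res = stats.ttest_ind(
        exp_values, ctrl_values, axis=1, equal_var=(variant == "student")
    )
    p = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance in both groups: p = 1 when means agree,
    # p = 0 for a deterministic separation
    ve = exp_values.var(axis=1)
    vc = ctrl_values.var(axis=1)
    degenerate = (ve == 0) & (vc == 0)
    same_mean = np.isclose(exp_values.mean(axis=1), ctrl_values.mean(axis=1))
    p = np.where(degenerate & same_mean, 1.0, p)
    p = np.where(degenerate & ~same_mean, 0.0, p)
    return np.nan_to_num(p, nan=1.0)


def ttest_proteins(
    experiment: RPPAExperiment,
    alpha: float = 0.05,
    variant: str = "student",
    bh_correct: bool = False,
) -> list[ProteinCall]:
    """Per-protein two-sided two-sample t-test plus fold-change judgement."""
    if experiment.m < 2:
        raise ValueError("need m >= 2 replicates for a t-test")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    fc = fold_change(experiment)
    p = _ttest_rows(experiment.exp_values, experiment.ctrl_values, variant)
    if bh_correct:
        p = stats.false_discovery_control(p, method="bh")
    return [
        ProteinCall(name, float(f), judge(float(f)), float(pv), bool(pv < alpha))
        for name, f, pv in zip(experiment.protein_names, fc, p)
    ]


@dataclasses.dataclass
class CandidateSets:
    """Promoted/inhibited candidates with their significant sublists."""

    promoted: list[ProteinCall]
    inhibited: list[ProteinCall]
    promoted_significant: list[ProteinCall]
    inhibited_significant: list[ProteinCall]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "promoted": len(self.promoted),
            "inhibited": len(self.inhibited),
            "promoted_significant": len(self.promoted_significant),
            "inhibited_significant": len(self.inhibited_significant),
        }


def candidate_sets(
    up_experiment: RPPAExperiment,
    down_experiment: RPPAExperiment,
    alpha: float = 0.05,
    variant: str = "student",
    bh_correct: bool = False,
) -> CandidateSets:
    """Promoted = UP-judged proteins in the overexpression experiment;
    inhibited = DOWN-judged proteins in the knockdown experiment; each also
    filtered to t-test significance at ``alpha``."""
    up_calls = ttest_proteins(up_experiment, alpha, variant, bh_correct)
    down_calls = ttest_proteins(down_experiment, alpha, variant, bh_correct)
    promoted = [c for c in up_calls if c.judgement == "UP"]
    inhibited = [c for c in down_calls if c.judgement == "DOWN"]
    return CandidateSets(
        promoted=promoted,
        inhibited=inhibited,
        promoted_significant=[c for c in promoted if c.significant],
        inhibited_significant=[c for c in inhibited if c.significant],
    )
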