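"""Delimited-text readers/writers and run configuration.

Dialect: tab-separated for .tsv/.txt, comma-separated for .csv, UTF-8,
header row mandatory; gene/protein identifiers are never parsed as numbers.
Expression matrices may be stored samples-by-genes or genes-by-samples
(orientation flag). Survival tables need columns sample_id, time, event.
RPPA tables have one row per protein with replicate columns whose names
start with "exp" or "ctrl" (case-insensitive).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from .rppa import ProteinCall, RPPAExperiment
from .selection import SelectionConfig
from .survival_core import SurvivalDataset

logger = logging.getLogger(__name__)

ORIENTATIONS = ("samples_by_genes", "genes_by_samples")


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), index_col=0)


def _to_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().any().any():
        bad = np.argwhere(out.isna().values)[0]
        raise ValueError(
            f"non-numeric cell in {what} at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    return out


def read_expression_survival(
    matrix_path, survival_path, orientation: str = "samples_by_genes"
) -> SurvivalDataset:
    """Inner-join an expression matrix with a survival table on sample ID."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    mat = _read_table(matrix_path)
    if orientation == "genes_by_samples":
        mat = mat.T
    mat = _to_numeric(mat, "expression matrix")
    surv = pd.read_csv(survival_path, sep=_sep(survival_path))
    surv.columns = [c.lower() for c in surv.columns]
    for col in ("sample_id", "time", "event"):
        if col not in surv.columns:
            raise ValueError(f"survival table lacks required column {col!r}")
    surv = surv.set_index("sample_id")
    surv = _to_numeric(surv[["time", "event"]], "survival table")
    common = mat.index.intersection(surv.index)
    if len(common) == 0:
        raise ValueError("no overlapping sample IDs between matrix and survival table")
    dropped = (set(mat.index) | set(surv.index)) - set(common)
    if dropped:
        logger.warning("dropped %d sample(s) without both records: %s",
                       len(dropped), sorted(dropped)[:10])
    mat = mat.loc[common]
    surv = surv.loc[common]
    return SurvivalDataset(
        mat.values,
        surv["time"].values,
        surv["event"].values,
        [str(c) for c in mat.columns],
    )


def write_expression_survival(
    dataset: SurvivalDataset,
    matrix_path,
    survival_path,
    orientation: str = "samples_by_genes",
    sample_ids=None,
) -> None:
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    ids = list(sample_ids) if sample_ids is not None else [
        f"S{i:04d}" for i in range(dataset.n)
    ]
    mat = pd.DataFrame(dataset.X, index=ids, columns=dataset.covariate_names)
    if orientation == "genes_by_samples":
        mat = mat.T
    mat.index.name = "id"
    mat.to_csv(matrix_path, sep=_sep(matrix_path))
    surv = pd.DataFrame(
        {"sample_id": ids, "time": dataset.time, "event": dataset.event}
    )
    surv.to_csv(survival_path, sep=_sep(survival_path), index=False)


def read_rppa(path, direction: str) -> RPPAExperiment:
    """Read a replicate table: protein IDs in the first column, replicate
    columns named exp*/ctrl* (case-insensitive)."""
    df = _read_table(path)
    exp_cols = [c for c in df.columns if str(c).lower().startswith("exp")]
    ctrl_cols = [c for c in df.columns if str(c).lower().startswith("ctrl")]
    if not exp_cols or not ctrl_cols:
        raise ValueError("RPPA table needs exp* and ctrl* replicate columns")
    df = _to_numeric(df, "RPPA table")
    return RPPAExperiment(
        direction,
        [str(i) for i in df.index],
        df[exp_cols].values,
        df[ctrl_cols].values,
    )


def write_rppa(experiment: RPPAExperiment, path) -> None:
    cols = {f"Exp_{j+1}": experiment.exp_values[:, j] for j in range(experiment.m)}
    cols |= {f"Ctrl_{j+1}": experiment.ctrl_values[:, j] for j in range(experiment.m)}
    df = pd.DataFrame(cols, index=experiment.protein_names)
    df.index.name = "protein"
    df.to_csv(path, sep=_sep(path))


def write_protein_calls(calls: list[ProteinCall], path) -> None:
    df = pd.DataFrame(
        {
            "protein": [c.protein_name for c in calls],
            "fc": [c.fc for c in calls],
            "judgement": [c.judgement for c in calls],
            "p_value": [c.p_value for c in calls],
            "significant": [c.significant for c in calls],
        }
    )
    df.to_csv(path, sep=_sep(path), index=False)


@dataclasses.dataclass
class RunConfig:
    """Full run configuration; round-trips losslessly through YAML."""

    seed: int = 0
    iqr_mode: str = "top_k"
    iqr_value: float | int | None = None
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    n_folds: int = 5
    screen_threshold: float | None = None
    lambda_rule: str = "ebic"
    ebic_gamma: float = 0.5
    ttest_variant: str = "student"
    alpha: float = 0.05
    roc_method: str = "ipcw"
    horizon: float | None = None
    outdir: str = "."

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            seed=self.seed,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            n_folds=self.n_folds,
            screen_threshold=self.screen_threshold,
            lambda_rule=self.lambda_rule,
            ebic_gamma=self.ebic_gamma,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_config(config: RunConfig, path) -> None:
    pathlib.Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(pathlib.Path(path).read_text())
    return RunConfig(**data)


def write_provenance(path, command: str, params: dict, seed: int | None) -> None:
    """Record enough to regenerate a result file bit-identically."""
    from . import __version__

    block = {
        "command": command,
        "params": params,
        "seed": seed,
        "version": __version__,
    }
    pathlib.Path(path).write_text(json.dumps(block, indent=2, default=str) + "\n")
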