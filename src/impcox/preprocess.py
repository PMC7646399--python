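"""Variance-based gene prefiltering.

Microarray expression matrices carry tens of thousands of probes, most of
which barely vary across tumors; an interquartile-range (IQR) filter drops
low-spread genes before any model fitting. Quantiles use linear
interpolation (type 7), the numpy default.
"""

from __future__ import annotations

import numpy as np

from .survival_core import SurvivalDataset

MODES = ("quantile", "absolute", "top_k")


def gene_iqr(dataset: SurvivalDataset) -> np.ndarray:
    """Per-gene IQR (Q3 - Q1) across samples, linear-interpolation quantiles."""
    q1, q3 = np.percentile(dataset.X, [25, 75], axis=0)
    return q3 - q1


def iqr_filter(
    dataset: SurvivalDataset, mode: str = "top_k", value: float | int = None
) -> tuple[SurvivalDataset, list[str]]:
    """Keep genes whose IQR exceeds a cutoff; samples and survival untouched.

    mode="absolute": cutoff is ``value`` itself.
    mode="quantile": cutoff is the cross-gene IQR quantile at ``value``.
    mode="top_k":    keep exactly the ``value`` genes of largest IQR
                     (ties broken by column order).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if value is None:
        raise ValueError("a cutoff value is required")
    iqrs = gene_iqr(dataset)
    if mode == "top_k":
        k = int(value)
        if k < 1:
            raise ValueError("top_k value must be >= 1")
        k = min(k, dataset.p)
        order = np.argsort(-iqrs, kind="stable")[:k]
        keep = np.sort(order)
    else:
        cutoff = (
            float(np.quantile(iqrs, float(value))) if mode == "quantile" else float(value)
        )
        keep = np.flatnonzero(iqrs > cutoff)
    if keep.size == 0:
        raise ValueError("empty matrix after IQR filter")
    filtered = dataset.take_covariates(keep)
    return filtered, list(filtered.covariate_names)
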