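"""Differential-expression calling on top of the NB-GLM engine.

Implements the Benjamini-Hochberg step-up FDR and the calling rule used
throughout the analysis: a gene is differentially expressed when its
fold change exceeds 2 (|log2 FC| > 1) and its BH-adjusted P-value (FDR)
is below 0.05, both strict inequalities. Fold changes come from the GLM
contrast coefficient, not from ratios of raw means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .countdata import CountMatrix
from .nbglm import estimate_dispersion, fit_nb_glm, lrt_contrast
from .tmm import tmm_factors

__all__ = ["bh_adjust", "call_de", "differential_expression", "cell_means_design"]

LN2 = np.log(2.0)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values.

    NaN entries propagate as NaN and are excluded from the number of
    tests m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(valid):
        out[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return out


def call_de(
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag rows with |log2fc| > log2(fc_threshold) and fdr < fdr_threshold.

    ``results`` must carry columns ``log2fc`` and ``fdr``; a boolean
    ``is_de`` column is added (NaN statistics are never flagged).
    """
    if not {"log2fc", "fdr"} <= set(results.columns):
        raise ValueError("results must have columns 'log2fc' and 'fdr'")
    out = results.copy()
    lfc = out["log2fc"].to_numpy(dtype=float)
    fdr = out["fdr"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out["is_de"] = (np.abs(lfc) > np.log2(fc_threshold)) & (fdr < fdr_threshold)
    return out


def cell_means_design(levels: list[str], level_order: list[str] | None = None):
    """Cell-means (one indicator column per factor level) design matrix.

    Returns (design, level_order); every level must have >= 1 sample.
    """
    if level_order is None:
        seen: dict[str, None] = {}
        for lv in levels:
            seen.setdefault(lv)
        level_order = list(seen)
    missing = set(levels) - set(level_order)
    if missing:
        raise ValueError(f"samples with undeclared levels: {sorted(missing)}")
    design = np.zeros((len(levels), len(level_order)))
    for i, lv in enumerate(levels):
        design[i, level_order.index(lv)] = 1.0
    if np.any(design.sum(axis=0) == 0):
        empty = [lv for j, lv in enumerate(level_order) if design[:, j].sum() == 0]
        raise ValueError(f"factor levels without samples: {empty}")
    return design, level_order


def differential_expression(
    cm: CountMatrix,
    condition: str,
    control: str,
    species: str | None = None,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    dispersion: float | np.ndarray | None = None,
    dispersion_method: str = "common",
) -> pd.DataFrame:
    """Within-species DE of ``condition`` vs ``control``.

    Fits a cell-means NB-GLM over the sample conditions (optionally
    restricted to one species), tests condition - control by LRT, and
    applies the 2-fold/FDR rule. Returns a frame with columns gene_id,
    log2fc, pvalue, fdr, is_de.
    """
    if species is not None:
        cm = cm.subset_samples([s.species == species for s in cm.samples])
    conds = [s.condition for s in cm.samples]
    for needed in (condition, control):
        if needed not in conds:
            raise ValueError(f"condition {needed!r} has no samples")
    design, order = cell_means_design(conds)
    lib = cm.library_sizes
    offsets = np.log(lib * tmm_factors(cm.counts, lib))
    if dispersion is None:
        dispersion = estimate_dispersion(
            cm.counts, design, offsets, method=dispersion_method
        )
    fit = fit_nb_glm(cm.counts, design, offsets, dispersion)
    contrast = np.zeros(len(order))
    contrast[order.index(condition)] = 1.0
    contrast[order.index(control)] = -1.0
    _, pval = lrt_contrast(fit, contrast)
    est, _ = fit.contrast_estimate(contrast)
    res = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "log2fc": est / LN2,
            "pvalue": pval,
            "fdr": bh_adjust(pval),
        }
    )
    return call_de(res, fc_threshold, fdr_threshold)
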