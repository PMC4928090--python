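"""Replicate-consistency QC on log-CPM profiles."""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .countdata import CountMatrix

__all__ = ["qc_replicate_correlation"]

log = logging.getLogger(__name__)


def qc_replicate_correlation(cm: CountMatrix, prior: float = 1.0) -> pd.DataFrame:
    """Mean pairwise Pearson r of replicates, per species:condition.

    Computed on log2(CPM + prior). Conditions with a single replicate are
    skipped with a warning. The returned frame has one row per level plus
    an "overall" row carrying the mean across levels.
    """
    logcpm = cm.cpm(log=True, prior=prior).to_numpy()
    levels = np.array(cm.levels)
    rows = []
    for level in dict.fromkeys(levels):
        cols = np.flatnonzero(levels == level)
        if cols.size < 2:
            log.warning("condition %s has a single replicate; skipped", level)
            continue
        rs = [
            np.corrcoef(logcpm[:, i], logcpm[:, j])[0, 1]
            for i, j in itertools.combinations(cols, 2)
        ]
        rows.append({"level": level, "n_replicates": int(cols.size),
                     "mean_pearson_r": float(np.mean(rs))})
    out = pd.DataFrame(rows, columns=["level", "n_replicates", "mean_pearson_r"])
    if len(out):
        out.loc[len(out)] = {
            "level": "overall",
            "n_replicates": int(out["n_replicates"].sum()),
            "mean_pearson_r": float(out["mean_pearson_r"].mean()),
        }
    return out
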