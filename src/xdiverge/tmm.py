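"""Trimmed mean of M-values (TMM) between-sample normalization.

Compositional normalization for count libraries: for each sample a scaling
factor is computed from the doubly trimmed, precision-weighted mean of the
per-gene log2 expression ratios (M-values) against a reference sample, so
that a minority of very highly expressed genes cannot drag apparent
expression of everything else. Effective library size = library size x
factor; factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tmm_factors", "tmm_pair_factor"]


def tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """TMM factor of one sample against a reference column.

    M-values are trimmed by ``trim_m`` on each side, A-values by ``trim_a``;
    the surviving M-values are averaged with inverse-variance (delta-method
    binomial) weights.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:  # identical up to depth: factor exactly 1
        return 1.0
    n = m.size
    # rank-based double trim, keeping the central mass on both axes
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = _rank(m)
    rank_a = _rank(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 1.0
    with np.errstate(divide="ignore"):
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks, 1-based."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, x.size + 1)
    # average ties
    _, inv, cnt = np.unique(x, return_inverse=True, return_counts=True)
    sums = np.zeros(cnt.size)
    np.add.at(sums, inv, ranks)
    return sums[inv] / cnt[inv]


def tmm_factors(
    counts: np.ndarray,
    lib_sizes: np.ndarray | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_column: int | None = None,
) -> np.ndarray:
    """Per-sample TMM normalization factors for a genes x samples matrix.

    The reference column is the sample whose 0.75 expression quantile is
    closest to the across-sample mean, unless given. Returned factors have
    geometric mean 1.

    Raises
    ------
    ValueError
        If any sample has an all-zero column (no library to normalize).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be genes x samples")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    zero = np.flatnonzero(lib_sizes <= 0)
    if zero.size:
        raise ValueError(f"sample column {zero[0]} has zero library size")
    if ref_column is None:
        f75 = np.array(
            [np.quantile(counts[:, j] / lib_sizes[j], 0.75) for j in range(counts.shape[1])]
        )
        if np.median(f75) < 1e-20:
            ref_column = int(np.argmax(counts.sum(axis=0)))
        else:
            ref_column = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            tmm_pair_factor(
                counts[:, j], counts[:, ref_column], lib_sizes[j], lib_sizes[ref_column],
                trim_m=trim_m, trim_a=trim_a,
            )
            for j in range(counts.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors
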