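"""Hypergeometric over-representation analysis for gene sets.

For a universe of N genes of which n are in the query (e.g. divergently
expressed ortholog pairs) and a term annotating M universe genes of
which i are in the query, the enrichment P-value is the upper tail
including the observed count,

    p = sum_{j=i}^{min(n, M)} C(M, j) C(N-M, n-j) / C(N, n),

evaluated in log space for stability. Terms are flagged enriched at raw
p < alpha (no multiplicity adjustment by default; BH available via a
flag). The same machinery applies unchanged to any gene-set collection
(GO terms, pathway gene sets, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = [
    "GOQuery",
    "GeneSetAnnotation",
    "read_annotation",
    "hypergeom_pvalue",
    "enrich_terms",
]


@dataclass(frozen=True)
class GOQuery:
    """Counts entering one hypergeometric test.

    N: universe size; n: query (divergent) genes; M: genes annotated to
    the term; i: query genes annotated to the term.
    """

    N: int
    n: int
    M: int
    i: int

    def __post_init__(self):
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N):
            raise ValueError("need 0 <= M, n <= N")
        if not (0 <= self.i <= min(self.n, self.M)):
            raise ValueError("need 0 <= i <= min(n, M)")
        if self.i < self.n - (self.N - self.M):
            raise ValueError("i below the feasible support of the table")


@dataclass(frozen=True)
class GeneSetAnnotation:
    term_id: str
    term_name: str
    members: frozenset[str]


def read_annotation(path: str | Path) -> list[GeneSetAnnotation]:
    """Read a gene->term TSV with columns gene_id, term_id[, term_name]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError("annotation needs columns gene_id, term_id")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    out = []
    for (tid, tname), grp in df.groupby(["term_id", "term_name"], sort=True):
        out.append(GeneSetAnnotation(tid, tname, frozenset(grp["gene_id"])))
    return out


def hypergeom_pvalue(q: GOQuery) -> float:
    """Upper-tail hypergeometric P(X >= i), including the observed count.

    Evaluated as the survival function at i-1; when that underflows to
    zero the tail is re-summed in log space.
    """
    hi = min(q.n, q.M)
    if q.i > hi:
        return 1.0  # empty sum cannot occur under the invariants; guard anyway
    p = float(hypergeom.sf(q.i - 1, q.N, q.M, q.n))
    if p == 0.0:
        logp = hypergeom.logpmf(np.arange(q.i, hi + 1), q.N, q.M, q.n)
        p = float(np.exp(logsumexp(logp)))
    return min(1.0, max(p, 5e-324))


def enrich_terms(
    divergent: set[str],
    universe: set[str],
    annotation: list[GeneSetAnnotation],
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Test every term with >= 1 universe member; rank ascending by p.

    ``divergent`` must be a subset of ``universe``. Term memberships are
    restricted to the universe before counting. The ``enriched`` flag is
    raw p < alpha unless ``adjust`` turns on BH correction of the term
    P-values.
    """
    if not universe:
        raise ValueError("universe is empty")
    extra = set(divergent) - set(universe)
    if extra:
        raise ValueError(f"divergent genes outside universe: {sorted(extra)[:5]}")
    N, n = len(universe), len(divergent)
    rows = []
    for term in annotation:
        members = term.members & universe
        M = len(members)
        if M == 0:
            continue
        i = len(members & divergent)
        p = hypergeom_pvalue(GOQuery(N=N, n=n, M=M, i=i))
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "N": N,
                "n": n,
                "M": M,
                "i": i,
                "pvalue": p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "N", "n", "M", "i", "pvalue"]
    )
    if len(table):
        table = table.sort_values("pvalue", kind="mergesort", ignore_index=True)
    if adjust:
        from .de import bh_adjust

        table["fdr"] = bh_adjust(table["pvalue"].to_numpy()) if len(table) else []
        table["enriched"] = table["fdr"] < alpha if len(table) else []
    else:
        table["enriched"] = table["pvalue"] < alpha if len(table) else []
    return table
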