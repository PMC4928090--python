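"""Cross-species TFBS enrichment in promoters of divergent orthologs.

For each motif, an ortholog pair "contains" the motif when at least one
hit passed the scan threshold in either species' promoter (the
either-species presence rule). Within a scope gene set, motif presence
is cross-tabulated against the divergent/non-divergent status of the
pairs and tested with Fisher's exact test (two-sided, point-probability
rule); the reported odds ratio is the conditional maximum-likelihood
estimate under the noncentral hypergeometric model - the estimator
standard exact-test implementations print, which shrinks toward 1
relative to the sample cross-product ratio.

Also here: the TF catalog helpers (keyword definition of
apoptosis-related TFs from GO term names) and induced-subnetwork
extraction from a user-supplied interaction edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from scipy.stats.contingency import odds_ratio as _sp_odds_ratio

__all__ = [
    "ContingencyTable",
    "fisher_pvalue",
    "fisher_exact",
    "build_presence",
    "enrich_tfbs",
    "define_apoptosis_tfs",
    "extract_subnetwork",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 motif-presence x divergence counts.

    a: divergent & present, b: divergent & absent,
    c: non-divergent & present, d: non-divergent & absent.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be nonnegative integers")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def cross_product_or(self) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            return float(self.a * self.d) / (self.b * self.c) if self.b * self.c else np.inf


_TIE_TOL = 1e-12  # separates exact probability ties (float error ~1e-14)
# from genuinely distinct support probabilities (>= 1/C(40,20) relative)


def fisher_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P by the point-probability rule.

    Sums, over the full conditional support at the observed margins, the
    probabilities of all tables whose point probability does not exceed
    the observed one. Vectorized over the support. Zero-margin tables
    are degenerate and return 1.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    pmf = hypergeom.pmf(np.arange(lo, hi + 1), n, r1, c1)
    p_obs = pmf[a - lo]
    take = pmf <= p_obs * (1.0 + _TIE_TOL)
    if np.all(take):
        return 1.0
    return float(min(1.0, pmf[take].sum()))


def fisher_exact(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher exact P and conditional-MLE odds ratio.

    A zero margin makes the table degenerate: p = 1 and the OR is NaN.
    """
    t = table.as_array
    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        return 1.0, float("nan")
    p = fisher_pvalue(table.a, table.b, table.c, table.d)
    orr = float(_sp_odds_ratio(t, kind="conditional").statistic)
    return p, orr


def build_presence(
    hits_a: pd.DataFrame,
    hits_b: pd.DataFrame,
    pairs: pd.DataFrame,
    promoters_a: set[str] | None = None,
    promoters_b: set[str] | None = None,
) -> pd.DataFrame:
    """Pair x motif boolean presence under the either-species rule.

    ``hits_a``/``hits_b`` are scan tables (columns gene_id, motif_id);
    ``pairs`` maps gene_a to gene_b (columns gene_a, gene_b, indexed by
    pair id). When promoter sets are given, pairs missing a promoter in
    either species are excluded with a log message. Entry True iff >= 1
    hit in the A promoter or in the B promoter.
    """
    motifs = sorted(set(hits_a.get("motif_id", pd.Series(dtype=str)))
                    | set(hits_b.get("motif_id", pd.Series(dtype=str))))
    keep = []
    for pair_id, row in pairs.iterrows():
        if promoters_a is not None and row["gene_a"] not in promoters_a:
            log.info("pair %s excluded: no promoter for %s", pair_id, row["gene_a"])
            continue
        if promoters_b is not None and row["gene_b"] not in promoters_b:
            log.info("pair %s excluded: no promoter for %s", pair_id, row["gene_b"])
            continue
        keep.append(pair_id)
    kept = pairs.loc[keep]
    present = pd.DataFrame(False, index=kept.index, columns=motifs)
    sets_a = hits_a.groupby("motif_id")["gene_id"].agg(set) if len(hits_a) else pd.Series(dtype=object)
    sets_b = hits_b.groupby("motif_id")["gene_id"].agg(set) if len(hits_b) else pd.Series(dtype=object)
    for motif in motifs:
        ga = sets_a.get(motif, set())
        gb = sets_b.get(motif, set())
        present[motif] = kept["gene_a"].isin(ga).to_numpy() | kept["gene_b"].isin(gb).to_numpy()
    return present


def enrich_tfbs(
    presence: pd.DataFrame,
    divergent_pairs: set[str],
    scope: set[str] | None = None,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-motif 2x2 Fisher enrichment within a scope pair set.

    ``presence`` is the pair x motif boolean matrix; ``scope`` restricts
    rows (default: all rows). Output columns mirror the published table
    layout: motif_id, a, b, c, d, odds_ratio, pvalue, plus an enrichment
    flag at raw p < alpha (BH-adjusted when ``adjust``).
    """
    if scope is None:
        scope_idx = presence.index
    else:
        missing = set(scope) - set(presence.index)
        if missing:
            raise ValueError(f"scope pairs without presence rows: {sorted(missing)[:5]}")
        scope_idx = presence.index.intersection(list(scope))
    if len(scope_idx) == 0:
        raise ValueError("empty scope")
    sub = presence.loc[scope_idx]
    is_div = sub.index.isin(list(divergent_pairs))
    rows = []
    for motif in sub.columns:
        pres = sub[motif].to_numpy(dtype=bool)
        tab = ContingencyTable(
            a=int(np.sum(is_div & pres)),
            b=int(np.sum(is_div & ~pres)),
            c=int(np.sum(~is_div & pres)),
            d=int(np.sum(~is_div & ~pres)),
        )
        p, orr = fisher_exact(tab)
        rows.append({"motif_id": motif, "a": tab.a, "b": tab.b, "c": tab.c,
                     "d": tab.d, "odds_ratio": orr, "pvalue": p})
    table = pd.DataFrame(rows, columns=["motif_id", "a", "b", "c", "d", "odds_ratio", "pvalue"])
    table = table.sort_values("pvalue", kind="mergesort", ignore_index=True)
    if adjust:
        from .de import bh_adjust

        table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
        table["enriched"] = table["fdr"] < alpha
    else:
        table["enriched"] = table["pvalue"] < alpha
    return table


def define_apoptosis_tfs(
    tf_ids: list[str],
    go_descriptions: dict[str, list[str]],
) -> pd.DataFrame:
    """TF catalog with the apoptosis keyword rule.

    A TF is apoptosis-related when at least one of its GO term names
    contains the substring "apoptosis" or "apoptotic"
    (case-insensitive). The rule is literal: e.g. "programmed cell
    death" does not match.
    """
    rows = []
    for tf in tf_ids:
        terms = go_descriptions.get(tf, [])
        hit = any(
            "apoptosis" in t.lower() or "apoptotic" in t.lower() for t in terms
        )
        rows.append({"gene_id": tf, "is_tf": True, "is_apoptosis_related": hit})
    return pd.DataFrame(rows, columns=["gene_id", "is_tf", "is_apoptosis_related"])


def extract_subnetwork(
    edges: pd.DataFrame,
    nodes: set[str],
    intermediates: set[str] | None = None,
):
    """Induced interaction subgraph on query nodes (plus intermediates).

    ``edges`` has columns source, target[, type] with type in
    {physical, colocalization, genetic}. Returns (graph, summary) where
    the summary reports the fraction of query nodes inside the largest
    connected component of the induced subgraph.
    """
    import networkx as nx

    keep = set(nodes) | (set(intermediates) if intermediates else set())
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if intermediates:
        g.add_nodes_from(intermediates)
    for row in edges.itertuples(index=False):
        src, tgt = str(row.source), str(row.target)
        if src in keep and tgt in keep:
            etype = getattr(row, "type", "physical")
            g.add_edge(src, tgt, type=etype)
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    if components:
        largest = max(components, key=lambda c: len(c & set(nodes)))
        in_largest = len(largest & set(nodes))
    else:
        in_largest = 0
    summary = {
        "n_query": len(nodes),
        "n_query_in_largest_component": in_largest,
        "fraction_connected": in_largest / len(nodes) if nodes else float("nan"),
        "n_edges": g.number_of_edges(),
    }
    return g, summary
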