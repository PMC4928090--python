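"""Cross-species expression-divergence analysis of one-to-one orthologs.

Two species are profiled under a shared cold-exposure design (a control
temperature plus cold timepoints). For each ortholog pair a single
NB-GLM is fitted over the combined species:condition factor in
cell-means coding, and divergence at a timepoint is the
difference-of-differences contrast

    (B:timepoint - B:control) - (A:timepoint - A:control),

i.e. the interaction between species and cold response. Normalizing each
species' cold response to its own control is done entirely by the
contrast; counts are never pre-divided. A pair is called divergently
expressed at a timepoint when |log2 contrast| > 1 and BH-FDR < 0.05
(strict, per-timepoint adjustment by default).

Sign convention: positive contrast = larger cold response in species B
(the second species); swapping the species labels flips the sign
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .countdata import CountMatrix, SampleInfo
from .de import LN2, bh_adjust, call_de, cell_means_design
from .nbglm import NBFit, estimate_dispersion, fit_nb_glm, lrt_contrast
from .tmm import tmm_factors

__all__ = [
    "OrthologMap",
    "read_ortholog_map",
    "merge_ortholog_counts",
    "divergence_contrast",
    "DivergenceModel",
    "DivergenceResults",
    "call_divergent",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one ortholog pairs: columns ``gene_a``, ``gene_b``."""

    pairs: pd.DataFrame

    def __post_init__(self):
        df = self.pairs
        if not {"gene_a", "gene_b"} <= set(df.columns):
            raise ValueError("ortholog map needs columns gene_a, gene_b")
        for col in ("gene_a", "gene_b"):
            dup = df[col][df[col].duplicated()]
            if len(dup):
                raise ValueError(f"gene appears in more than one pair: {dup.iloc[0]!r}")

    def __len__(self) -> int:
        return len(self.pairs)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("ortholog map must have two columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_a", "gene_b"]
    return OrthologMap(df)


def merge_ortholog_counts(
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    orthologs: OrthologMap,
    min_count: int = 1,
    min_samples: int = 3,
) -> CountMatrix:
    """Join two species' counts into one matrix over expressed pairs.

    One row per ortholog pair whose both members pass the expression
    filter (>= ``min_count`` reads in >= ``min_samples`` samples of the
    species); columns are the union of both species' samples. Pairs with
    a gene absent from its count matrix are dropped with a log message.
    """
    rows_a, rows_b, pair_ids, kept = [], [], [], []
    idx_a = {g: i for i, g in enumerate(counts_a.gene_ids)}
    idx_b = {g: i for i, g in enumerate(counts_b.gene_ids)}
    for ga, gb in orthologs.pairs[["gene_a", "gene_b"]].itertuples(index=False):
        ia, ib = idx_a.get(ga), idx_b.get(gb)
        if ia is None or ib is None:
            log.info("ortholog pair (%s, %s) dropped: gene absent from counts", ga, gb)
            continue
        ya, yb = counts_a.counts[ia], counts_b.counts[ib]
        if (ya >= min_count).sum() < min_samples or (yb >= min_count).sum() < min_samples:
            continue
        rows_a.append(ya)
        rows_b.append(yb)
        pair_ids.append(f"{ga}|{gb}")
        kept.append((ga, gb))
    if not rows_a:
        raise ValueError("no expressed ortholog pairs after filtering")
    joint = np.hstack([np.vstack(rows_a), np.vstack(rows_b)])
    samples = list(counts_a.samples) + list(counts_b.samples)
    cm = CountMatrix(joint, samples, pair_ids)
    cm.pair_genes = pd.DataFrame(kept, columns=["gene_a", "gene_b"], index=pair_ids)
    return cm


def divergence_contrast(
    level_order: list[str],
    timepoint: str,
    control: str,
    species: tuple[str, str] = ("A", "B"),
) -> np.ndarray:
    """The +-1 interaction contrast on cell-means coefficients.

    (B:timepoint - B:control) - (A:timepoint - A:control); entries sum
    to zero. Raises naming the first missing level.
    """
    a, b = species
    weights = {
        f"{b}:{timepoint}": 1.0,
        f"{b}:{control}": -1.0,
        f"{a}:{timepoint}": -1.0,
        f"{a}:{control}": 1.0,
    }
    vec = np.zeros(len(level_order))
    for level, w in weights.items():
        if level not in level_order:
            raise ValueError(f"design has no level {level!r}")
        vec[level_order.index(level)] = w
    return vec


class DivergenceModel:
    """NB-GLM over the combined species:condition factor for ortholog pairs.

    Parameters
    ----------
    counts
        Joint pair x sample matrix (see :func:`merge_ortholog_counts`);
        samples of both species, each carrying species and condition.
    control
        Baseline condition (e.g. "28C").
    timepoints
        Cold timepoints to test; default = all non-control conditions in
        declared order.
    """

    def __init__(
        self,
        counts: CountMatrix,
        control: str,
        timepoints: list[str] | None = None,
    ):
        self.counts = counts
        self.control = control
        conds_seen: dict[str, None] = {}
        for s in counts.samples:
            conds_seen.setdefault(s.condition)
        if control not in conds_seen:
            raise ValueError(f"control condition {control!r} has no samples")
        if timepoints is None:
            timepoints = [c for c in conds_seen if c != control]
        for tp in timepoints:
            if tp not in conds_seen:
                raise ValueError(f"timepoint {tp!r} has no samples")
        self.timepoints = list(timepoints)
        sp_seen: dict[str, None] = {}
        for s in counts.samples:
            sp_seen.setdefault(s.species)
        if len(sp_seen) != 2:
            raise ValueError(f"exactly two species required, got {list(sp_seen)}")
        self.species = tuple(sp_seen)
        self.design, self.level_order = cell_means_design(counts.levels)
        self.offsets = self._species_offsets()

    @classmethod
    def from_counts(
        cls,
        counts_a: CountMatrix,
        counts_b: CountMatrix,
        orthologs: OrthologMap,
        control: str,
        timepoints: list[str] | None = None,
        min_count: int = 1,
        min_samples: int = 3,
    ) -> "DivergenceModel":
        joint = merge_ortholog_counts(counts_a, counts_b, orthologs, min_count, min_samples)
        return cls(joint, control, timepoints)

    def _species_offsets(self) -> np.ndarray:
        """log effective library sizes, TMM within each species block."""
        lib = self.counts.library_sizes
        offsets = np.empty(len(lib))
        sp = np.array([s.species for s in self.counts.samples])
        for species in self.species:
            cols = np.flatnonzero(sp == species)
            factors = tmm_factors(self.counts.counts[:, cols], lib[cols])
            offsets[cols] = np.log(lib[cols] * factors)
        return offsets

    def fit(
        self,
        dispersion: float | np.ndarray | None = None,
        dispersion_method: str = "common",
        fc_threshold: float = 2.0,
        fdr_threshold: float = 0.05,
        pool_fdr: bool = False,
    ) -> "DivergenceResults":
        """Fit the GLM and test the divergence contrast at each timepoint."""
        if dispersion is None:
            dispersion = estimate_dispersion(
                self.counts.counts, self.design, self.offsets, method=dispersion_method
            )
        fit = fit_nb_glm(self.counts.counts, self.design, self.offsets, dispersion)
        frames = []
        genes = getattr(self.counts, "pair_genes", None)
        for tp in self.timepoints:
            c = divergence_contrast(self.level_order, tp, self.control, self.species)
            stat, pval = lrt_contrast(fit, c)
            est, se = fit.contrast_estimate(c)
            df = pd.DataFrame(
                {
                    "pair_id": self.counts.gene_ids,
                    "timepoint": tp,
                    "log2fc": est / LN2,
                    "se_log2fc": se / LN2,
                    "statistic": stat,
                    "pvalue": pval,
                }
            )
            if genes is not None:
                df.insert(1, "gene_a", genes["gene_a"].to_numpy())
                df.insert(2, "gene_b", genes["gene_b"].to_numpy())
            frames.append(df)
        table = pd.concat(frames, ignore_index=True)
        if pool_fdr:
            table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
        else:
            table["fdr"] = np.nan
            for tp in self.timepoints:
                mask = table["timepoint"] == tp
                table.loc[mask, "fdr"] = bh_adjust(table.loc[mask, "pvalue"].to_numpy())
        table = call_de(table, fc_threshold, fdr_threshold).rename(
            columns={"is_de": "is_divergent"}
        )
        return DivergenceResults(self, fit, table, fc_threshold, fdr_threshold)


class DivergenceResults:
    """Per-pair, per-timepoint divergence contrasts with uncertainties."""

    def __init__(
        self,
        model: DivergenceModel,
        fit: NBFit,
        table: pd.DataFrame,
        fc_threshold: float,
        fdr_threshold: float,
    ):
        self.model = model
        self.fit = fit
        self.table = table
        self.fc_threshold = fc_threshold
        self.fdr_threshold = fdr_threshold

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def divergent_pairs(self, timepoint: str | None = None) -> set[str]:
        """Flagged pair ids at one timepoint, or the union over all."""
        t = self.table
        if timepoint is not None:
            t = t[t["timepoint"] == timepoint]
        return set(t.loc[t["is_divergent"], "pair_id"])

    def summary(self) -> pd.DataFrame:
        """Divergent-pair counts per timepoint plus the union row."""
        n_pairs = self.table["pair_id"].nunique()
        rows = []
        for tp in self.model.timepoints:
            sub = self.table[self.table["timepoint"] == tp]
            n = int(sub["is_divergent"].sum())
            rows.append({"timepoint": tp, "n_divergent": n, "n_pairs": n_pairs,
                         "fraction": n / n_pairs})
        union = len(self.divergent_pairs())
        rows.append({"timepoint": "union", "n_divergent": union, "n_pairs": n_pairs,
                     "fraction": union / n_pairs})
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def plot_ma(self, timepoint: str, ax=None):
        """MA-style scatter: mean log2 CPM vs divergence contrast."""
        import matplotlib.pyplot as plt

        sub = self.table[self.table["timepoint"] == timepoint]
        base = self.model.counts.cpm(log=True).mean(axis=1).reindex(sub["pair_id"]).to_numpy()
        if ax is None:
            _, ax = plt.subplots()
        flagged = sub["is_divergent"].to_numpy(dtype=bool)
        ax.scatter(base[~flagged], sub["log2fc"][~flagged], s=4, c="0.6")
        ax.scatter(base[flagged], sub["log2fc"][flagged], s=6, c="crimson")
        ax.axhline(0, lw=0.5, c="k")
        ax.set_xlabel("mean log2 CPM")
        ax.set_ylabel("divergence contrast (log2)")
        ax.set_title(f"divergence at {timepoint}")
        return ax


def call_divergent(
    joint_counts: CountMatrix,
    control: str,
    timepoints: list[str] | None = None,
    fc: float = 2.0,
    fdr: float = 0.05,
    dispersion: float | np.ndarray | None = None,
) -> DivergenceResults:
    """One-call wrapper: build the model over the combined design and fit."""
    model = DivergenceModel(joint_counts, control, timepoints)
    return model.fit(dispersion=dispersion, fc_threshold=fc, fdr_threshold=fdr)
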