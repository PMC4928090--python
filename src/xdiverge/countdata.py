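"""Gene-level count matrices with sample metadata.

The pipeline's entry point is a genes x samples matrix of nonnegative
integer read counts plus a sample sheet assigning each column a species,
a temperature/time condition and a replicate index. Counts are assumed to
be the output of a read-counting step (e.g. HTSeq-count); producing them
is outside the scope of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SampleInfo", "CountMatrix", "read_counts", "read_sample_sheet"]


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sequencing library (one count-matrix column)."""

    sample: str
    species: str
    condition: str
    replicate: int
    library_size: int | None = None

    @property
    def level(self) -> str:
        """Combined species:condition factor level, e.g. ``"B:8C_0h"``."""
        return f"{self.species}:{self.condition}"


class CountMatrix:
    """Integer gene x sample count matrix with per-sample metadata.

    Parameters
    ----------
    counts
        Nonnegative integer array, shape (n_genes, n_samples), or a
        DataFrame indexed by gene id with sample-name columns.
    samples
        One :class:`SampleInfo` per column, in column order.
    gene_ids
        Required when ``counts`` is a bare array.
    """

    def __init__(
        self,
        counts: np.ndarray | pd.DataFrame,
        samples: Sequence[SampleInfo],
        gene_ids: Sequence[str] | None = None,
    ):
        if isinstance(counts, pd.DataFrame):
            gene_ids = counts.index.to_list()
            matrix = counts.to_numpy()
            names = counts.columns.to_list()
        else:
            matrix = np.asarray(counts)
            if gene_ids is None:
                raise ValueError("gene_ids required when counts is an array")
            names = [s.sample for s in samples]
        matrix = np.asarray(matrix)
        if matrix.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        if np.any(matrix < 0):
            raise ValueError("negative counts are not allowed")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("non-finite counts are not allowed")
        if len(samples) != matrix.shape[1]:
            raise ValueError(
                f"{matrix.shape[1]} count columns but {len(samples)} sample records"
            )
        ids = pd.Index(gene_ids, name="gene_id")
        if ids.has_duplicates:
            dup = ids[ids.duplicated()][0]
            raise ValueError(f"duplicated gene id: {dup!r}")
        order = {s.sample: i for i, s in enumerate(samples)}
        if list(order) != list(names):
            # reorder metadata to column order when given in any order
            try:
                samples = [samples[order[n]] for n in names]
            except KeyError as e:
                raise ValueError(f"sample sheet is missing column {e.args[0]!r}") from None
        self.counts = matrix.astype(np.int64)
        self.gene_ids = ids
        self.samples = list(samples)

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_names(self) -> list[str]:
        return [s.sample for s in self.samples]

    @property
    def library_sizes(self) -> np.ndarray:
        """Column sums unless overridden per sample."""
        sums = self.counts.sum(axis=0)
        return np.array(
            [s.library_size if s.library_size is not None else sums[i]
             for i, s in enumerate(self.samples)],
            dtype=float,
        )

    @property
    def levels(self) -> list[str]:
        return [s.level for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_names)

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        idx = self.gene_ids.get_indexer(list(gene_ids))
        if np.any(idx < 0):
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"gene ids not in matrix: {missing[:5]}")
        return CountMatrix(self.counts[idx], self.samples, list(gene_ids))

    def subset_samples(self, keep: Sequence[bool] | Sequence[int]) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.counts[:, keep],
            [self.samples[i] for i in keep],
            self.gene_ids.to_list(),
        )

    def check_replicates(self, minimum: int = 2) -> None:
        """Raise if any condition has fewer than ``minimum`` replicates."""
        tab = pd.Series(self.levels).value_counts()
        bad = tab[tab < minimum]
        if len(bad):
            raise ValueError(
                f"conditions with <{minimum} replicates: {', '.join(bad.index)}"
            )

    def cpm(self, log: bool = False, prior: float = 1.0) -> pd.DataFrame:
        """Counts per million; ``log`` gives log2(CPM + prior)."""
        c = self.counts / self.library_sizes * 1e6
        if log:
            c = np.log2(c + prior)
        return pd.DataFrame(c, index=self.gene_ids, columns=self.sample_names)


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a count TSV (first column gene_id) and a sample sheet TSV.

    The sample sheet needs columns ``sample``, ``species``, ``condition``,
    ``replicate`` and optionally ``library_size``.
    """
    table = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = read_sample_sheet(samples_path)
    by_name = {s.sample: s for s in samples}
    ordered = [by_name[c] for c in table.columns if c in by_name]
    missing = [c for c in table.columns if c not in by_name]
    if missing:
        raise ValueError(f"count columns absent from sample sheet: {missing}")
    return CountMatrix(table, ordered)


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "species", "condition", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        lib = int(row["library_size"]) if "library_size" in df.columns and pd.notna(row.get("library_size")) else None
        out.append(
            SampleInfo(
                sample=str(row["sample"]),
                species=str(row["species"]),
                condition=str(row["condition"]),
                replicate=int(row["replicate"]),
                library_size=lib,
            )
        )
    return out
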