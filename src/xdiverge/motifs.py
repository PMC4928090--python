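"""PWM scanning of promoter sequences with exact score P-values.

A position frequency matrix (PFM, base counts per motif column) is
converted to a log2 log-odds position weight matrix against a 0-order
background, with a pseudocount distributed by background frequency:

    PWM[x][j] = log2( (count[x][j] + pc * b_x) / (total_j + pc) / b_x ).

Scores are discretized to a fixed granularity and the exact distribution
of the score of a background-random k-mer is computed by dynamic
programming (column-wise convolution), giving the exact tail probability
P(score >= s) for any window score. A window is a motif hit when its
P-value is below the threshold (default 1e-4); both strands are scanned
and windows containing N are skipped. Because window scores are computed
from the same discretized matrix that the DP uses, scan P-values and the
null distribution are mutually exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PFM",
    "PWMModel",
    "MotifHit",
    "read_jaspar",
    "write_jaspar",
    "estimate_background",
    "pfm_to_pwm",
    "scan_promoter",
    "scan_promoter_set",
]

BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

UNIFORM = np.array([0.25, 0.25, 0.25, 0.25])


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: motif id/name and a 4 x L count matrix
    (rows A, C, G, T)."""

    motif_id: str
    name: str
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4 or c.shape[1] < 1:
            raise ValueError("PFM counts must be 4 x L with L >= 1")
        if np.any(c < 0):
            raise ValueError("PFM counts must be nonnegative")
        if np.any(c.sum(axis=0) == 0):
            raise ValueError(f"PFM {self.motif_id}: all-zero column")
        object.__setattr__(self, "counts", c)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


def read_jaspar(path: str | Path) -> list[PFM]:
    """Parse a JASPAR-format PFM file (one or more motifs)."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as handle:
        for m in bio_motifs.parse(handle, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            out.append(PFM(m.matrix_id or m.name, m.name or m.matrix_id, counts))
    if not out:
        raise ValueError(f"no motifs found in {path}")
    return out


def write_jaspar(pfms: list[PFM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p.motif_id} {p.name}\n")
            for b, row in zip(BASES, p.counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{b} [ {vals} ]\n")


def estimate_background(sequences, symmetrize: bool = True) -> np.ndarray:
    """0-order base frequencies over a collection of sequences (N ignored).

    ``symmetrize`` averages complementary bases (A with T, C with G), the
    appropriate null for double-strand scanning: the same tail table then
    serves both strands exactly.
    """
    counts = np.zeros(4)
    for seq in sequences:
        codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        valid = codes[codes >= 0]
        if valid.size:
            counts += np.bincount(valid, minlength=4)
    if counts.sum() == 0:
        return UNIFORM.copy()
    counts = np.maximum(counts, 1.0)  # guard degenerate alphabets
    if symmetrize:
        counts = (counts + counts[::-1]) / 2.0  # rows A,C,G,T: reverse pairs complements
    return counts / counts.sum()


class PWMModel:
    """Discretized log-odds matrix with its exact null score distribution.

    ``matrix`` holds log2 odds; ``bins`` the integer-discretized matrix
    (units of ``granularity``). ``tail[k]`` is P(score_int >= min_score_int
    + k) for a background-random k-mer.
    """

    def __init__(
        self,
        motif_id: str,
        matrix: np.ndarray,
        background: np.ndarray,
        granularity: float = 1e-3,
    ):
        self.motif_id = motif_id
        self.matrix = np.asarray(matrix, dtype=float)
        self.background = np.asarray(background, dtype=float)
        self.granularity = float(granularity)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM must have 4 rows")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PWM entries must be finite (apply a floor first)")
        self.bins = np.rint(self.matrix / self.granularity).astype(np.int64)
        self._min_int, self._tail = _score_distribution(self.bins, self.background)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def min_score_int(self) -> int:
        return self._min_int

    @property
    def max_score_int(self) -> int:
        return self._min_int + len(self._tail) - 1

    def pvalue_int(self, score_int: np.ndarray | int) -> np.ndarray | float:
        """Exact P(score >= score_int) for integer-bin scores."""
        s = np.asarray(score_int)
        idx = np.clip(s - self._min_int, 0, len(self._tail) - 1)
        out = self._tail[idx]
        out = np.where(s > self.max_score_int, 0.0, out)
        out = np.where(s <= self._min_int, 1.0, out)
        if np.ndim(score_int) == 0:
            return float(out)
        return out

    def pvalue(self, score: float) -> float:
        """P(score >= s); ``s`` in log2 units, rounded to the grid."""
        return float(self.pvalue_int(int(np.rint(score / self.granularity))))

    def reverse_complement(self) -> "PWMModel":
        """PWM scoring the reverse strand (rows and columns reversed).

        The null distribution is recomputed against the same background;
        it coincides with this model's when the background is
        complement-symmetric.
        """
        rc = PWMModel.__new__(PWMModel)
        rc.motif_id = self.motif_id
        rc.matrix = self.matrix[::-1, ::-1].copy()
        rc.background = self.background
        rc.granularity = self.granularity
        rc.bins = self.bins[::-1, ::-1].copy()
        rc._min_int, rc._tail = _score_distribution(rc.bins, rc.background)
        return rc


def _score_distribution(bins: np.ndarray, background: np.ndarray):
    """Exact distribution of the integer score of a random background
    k-mer, by column-wise convolution. Returns (min_total, tail)."""
    mins = bins.min(axis=0)
    maxs = bins.max(axis=0)
    dist = np.array([1.0])
    for j in range(bins.shape[1]):
        span = maxs[j] - mins[j]
        new = np.zeros(dist.size + span)
        for x in range(4):
            off = bins[x, j] - mins[j]
            new[off : off + dist.size] += background[x] * dist
        dist = new
    tail = np.cumsum(dist[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return int(mins.sum()), tail


def pfm_to_pwm(
    pfm: PFM,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
    granularity: float = 1e-3,
    floor: float = -64.0,
) -> PWMModel:
    """Log2 log-odds PWM with background-distributed pseudocount.

    With ``pseudocount=0`` a zero count would give -inf; such entries
    are floored at ``floor`` (log2 units) so downstream arithmetic stays
    finite.
    """
    b = UNIFORM if background is None else np.asarray(background, dtype=float)
    if b.shape != (4,) or np.any(b <= 0) or abs(b.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    totals = pfm.counts.sum(axis=0)
    with np.errstate(divide="ignore"):
        prob = (pfm.counts + pseudocount * b[:, None]) / (totals + pseudocount)
        matrix = np.log2(prob / b[:, None])
    matrix = np.maximum(matrix, floor)
    return PWMModel(pfm.motif_id, matrix, b, granularity)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    strand: str
    offset: int  # window start, 0-based on the forward promoter sequence
    score: float  # log2 log-odds of the window
    pvalue: float


def encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, bins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    L = bins.shape[1]
    win = sliding_window_view(codes, L)
    valid = np.all(win >= 0, axis=1)
    scores = np.zeros(win.shape[0], dtype=np.int64)
    if np.any(valid):
        idx = win[valid]
        scores[valid] = bins[idx, np.arange(L)].sum(axis=1)
    return scores, valid


def scan_promoter(
    sequence: str,
    pwm: PWMModel,
    threshold: float = 1e-4,
) -> list[MotifHit]:
    """Scan both strands of one sequence; emit windows with p < threshold.

    The reverse strand is scanned by scoring forward windows with the
    reverse-complemented matrix, so reported offsets are always on the
    forward sequence. Sequences shorter than the motif give no hits.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    L = pwm.length
    if len(sequence) < L:
        return []
    codes = encode(sequence)
    hits: list[MotifHit] = []
    for strand, model in (("+", pwm), ("-", pwm.reverse_complement())):
        scores, valid = _window_scores(codes, model.bins)
        pvals = model.pvalue_int(scores)
        take = valid & (pvals < threshold)
        for off in np.flatnonzero(take):
            hits.append(
                MotifHit(
                    motif_id=pwm.motif_id,
                    strand=strand,
                    offset=int(off),
                    score=float(scores[off] * pwm.granularity),
                    pvalue=float(pvals[off]),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoter_set(
    promoters: dict[str, str],
    pfms: list[PFM],
    threshold: float = 1e-4,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
    granularity: float = 1e-3,
):
    """Scan a promoter set with a motif collection; tabulated hits.

    The background defaults to the 0-order composition of the scanned
    promoter set itself. Returns a DataFrame with columns gene_id,
    motif_id, strand, offset, score, pvalue.
    """
    import pandas as pd

    if background is None:
        background = estimate_background(promoters.values())
    rows = []
    for pfm in pfms:
        pwm = pfm_to_pwm(pfm, background, pseudocount, granularity)
        rc = pwm.reverse_complement()
        for gene, seq in promoters.items():
            if len(seq) < pwm.length:
                continue
            codes = encode(seq)
            for strand, model in (("+", pwm), ("-", rc)):
                scores, valid = _window_scores(codes, model.bins)
                pvals = model.pvalue_int(scores)
                take = valid & (pvals < threshold)
                for off in np.flatnonzero(take):
                    rows.append(
                        (gene, pfm.motif_id, strand, int(off),
                         float(scores[off] * pwm.granularity), float(pvals[off]))
                    )
    return pd.DataFrame(
        rows, columns=["gene_id", "motif_id", "strand", "offset", "score", "pvalue"]
    )
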