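"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates a two-species cold-exposure RNA-seq design (control 28C plus
cold timepoints 8C/0h, 8C/6h, 8C/12h, 3 biological replicates each):
counts are negative binomial around log-normal baseline means with a
shared per-gene cold response, and a planted species x condition
interaction for a configured fraction of "divergent" ortholog pairs.
Promoters are i.i.d. background sequence with motif instances planted at
group-dependent probabilities, and gene-set annotations carry planted
enriched terms. Every generator records its ground truth so recovery can
be scored exactly, and all output is a deterministic function of the
seed: one global seed expands to per-component seeds through fixed spawn
keys (counts=0, promoters=1, annotation=2), so adding a generator never
perturbs existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .countdata import CountMatrix, SampleInfo
from .motifs import BASES, PFM

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "demo_motif",
    "simulate_counts",
    "simulate_promoters",
    "simulate_go",
    "simulate_all",
]

_SPAWN_COUNTS, _SPAWN_PROMOTERS, _SPAWN_GO = 0, 1, 2


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 2 species x 4 temperature/time
    conditions x 3 replicates, NB counts with baseline means around 200
    (log-normal), common dispersion 0.05, 10% of pairs carrying a
    |log2| = 2.5 species-by-cold interaction, 1 kb promoters, and motif
    planting at 60% (divergent) vs 10% (non-divergent) of pairs.
    """

    seed: int
    n_pairs: int = 2000
    conditions: tuple[str, ...] = ("28C", "8C_0h", "8C_6h", "8C_12h")
    control: str = "28C"
    replicates: int = 3
    baseline_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    fraction_divergent: float = 0.10
    effect_size: float = 2.5  # |log2| of the planted interaction
    divergent_timepoints: str | tuple[str, ...] = "all"
    species_sd: float = 0.3
    condition_sd: float = 0.5
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    promoter_length: int = 1000
    background: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    planted_motif: PFM | None = None
    plant_prob_divergent: float = 0.6
    plant_prob_nondivergent: float = 0.1
    n_null_motifs: int = 0
    n_go_terms: int = 200
    term_size_range: tuple[int, int] = (10, 300)
    n_planted_terms: int = 1
    planted_term_size: int = 50
    planted_odds: float = 8.0

    def __post_init__(self):
        for p in (self.fraction_divergent, self.plant_prob_divergent,
                  self.plant_prob_nondivergent):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.control not in self.conditions:
            raise ValueError("control must be one of the conditions")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def rng(self, component: int) -> np.random.Generator:
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=(component,)))
        )

    @property
    def timepoints(self) -> list[str]:
        return [c for c in self.conditions if c != self.control]

    @property
    def pair_ids(self) -> list[str]:
        width = len(str(self.n_pairs))
        return [f"gA{i:0{width}d}|gB{i:0{width}d}" for i in range(1, self.n_pairs + 1)]


@dataclass
class SyntheticTruth:
    """Planted signal: per-pair per-timepoint true contrast (log2),
    motif placements, and planted enriched terms."""

    divergent: pd.DataFrame = field(default_factory=pd.DataFrame)
    placements: pd.DataFrame = field(default_factory=pd.DataFrame)
    enriched_terms: list[str] = field(default_factory=list)

    @property
    def divergent_pairs(self) -> set[str]:
        if self.divergent.empty:
            return set()
        nonzero = self.divergent[self.divergent["true_log2"] != 0.0]
        return set(nonzero["pair_id"])


def demo_motif(motif_id: str = "MX0001", length: int = 10, strength: float = 97.0,
               rng: np.random.Generator | None = None) -> PFM:
    """A synthetic, strongly informative PFM for simulations and demos.

    Not a database motif: a fixed consensus (or a random one when given
    an rng) with ``strength`` counts on the consensus base and 1 on each
    other base per column.
    """
    if rng is None:
        consensus = [(7 * i + 3) % 4 for i in range(length)]
    else:
        consensus = rng.integers(0, 4, size=length)
    counts = np.ones((4, length))
    for j, x in enumerate(consensus):
        counts[x, j] = strength
    name = "".join(BASES[x] for x in consensus)
    return PFM(motif_id, name, counts)


def _split_pair(pair_id: str) -> tuple[str, str]:
    a, b = pair_id.split("|")
    return a, b


def simulate_counts(cfg: SimulationConfig):
    """Draw NB counts for both species under the shared design.

    Returns (counts_a, counts_b, samples, truth): two CountMatrix
    objects (species "A" and "B"), the concatenated sample sheet, and
    the planted truth. Divergent pairs carry a +-effect_size (log2)
    interaction on species B at the configured cold timepoints.
    """
    rng = cfg.rng(_SPAWN_COUNTS)
    g = cfg.n_pairs
    conds = list(cfg.conditions)
    tps = cfg.timepoints if cfg.divergent_timepoints == "all" else list(cfg.divergent_timepoints)

    base = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=g)
    species_shift = rng.normal(0.0, cfg.species_sd, size=g)
    cond_effect = {c: (np.zeros(g) if c == cfg.control
                       else rng.normal(0.0, cfg.condition_sd, size=g))
                   for c in conds}

    n_div = int(round(cfg.fraction_divergent * g))
    div_idx = rng.choice(g, size=n_div, replace=False) if n_div else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_div)
    effect_ln = np.zeros(g)
    effect_ln[div_idx] = signs * cfg.effect_size * np.log(2.0)

    pair_ids = cfg.pair_ids
    truth_rows = []
    for tp in cfg.timepoints:
        active = tp in tps
        for k, i in enumerate(div_idx):
            truth_rows.append({
                "pair_id": pair_ids[i], "timepoint": tp,
                "true_log2": float(signs[k] * cfg.effect_size) if active else 0.0,
            })
    truth = SyntheticTruth(
        divergent=pd.DataFrame(truth_rows, columns=["pair_id", "timepoint", "true_log2"])
    )

    lo, hi = cfg.lib_size_range
    blocks: dict[str, tuple[list[SampleInfo], list[np.ndarray]]] = {"A": ([], []), "B": ([], [])}
    for species in ("A", "B"):
        for cond in conds:
            for rep in range(1, cfg.replicates + 1):
                libfac = rng.uniform(lo, hi)
                log_mu = base + cond_effect[cond]
                if species == "B":
                    log_mu = log_mu + species_shift
                    if cond in tps:
                        log_mu = log_mu + effect_ln
                mu = np.exp(log_mu) * libfac
                if cfg.dispersion > 0:
                    r = 1.0 / cfg.dispersion
                    counts = rng.negative_binomial(r, r / (r + mu))
                else:
                    counts = rng.poisson(mu)
                info = SampleInfo(
                    sample=f"{species}_{cond}_r{rep}", species=species,
                    condition=cond, replicate=rep,
                )
                blocks[species][0].append(info)
                blocks[species][1].append(counts)

    gene_a = [_split_pair(p)[0] for p in pair_ids]
    gene_b = [_split_pair(p)[1] for p in pair_ids]
    counts_a = CountMatrix(np.column_stack(blocks["A"][1]), blocks["A"][0], gene_a)
    counts_b = CountMatrix(np.column_stack(blocks["B"][1]), blocks["B"][0], gene_b)
    samples = blocks["A"][0] + blocks["B"][0]
    return counts_a, counts_b, samples, truth


def _draw_motif_instance(pfm: PFM, rng: np.random.Generator) -> str:
    probs = pfm.counts / pfm.counts.sum(axis=0)
    return "".join(BASES[rng.choice(4, p=probs[:, j])] for j in range(pfm.length))


def simulate_promoters(cfg: SimulationConfig, truth: SyntheticTruth):
    """Background promoters with group-dependent motif planting.

    Every pair gets one promoter per species of i.i.d. background
    sequence. With probability plant_prob_divergent (divergent pairs) or
    plant_prob_nondivergent (others), one sampled instance of the
    planted motif is inserted at a random offset in one randomly chosen
    species' promoter (the either-species rule of the downstream
    presence matrix). Placements are appended to the truth. Additional
    ``n_null_motifs`` unplanted decoy motifs are returned for null
    calibration.
    """
    rng = cfg.rng(_SPAWN_PROMOTERS)
    motif = cfg.planted_motif if cfg.planted_motif is not None else demo_motif()
    if motif.length > cfg.promoter_length:
        raise ValueError("planted motif is longer than the promoter")
    b = np.asarray(cfg.background, dtype=float)
    b = b / b.sum()
    div = truth.divergent_pairs
    promoters_a: dict[str, str] = {}
    promoters_b: dict[str, str] = {}
    placements = []
    w = cfg.promoter_length
    for pair in cfg.pair_ids:
        ga, gb = _split_pair(pair)
        seq_a = rng.choice(4, size=w, p=b)
        seq_b = rng.choice(4, size=w, p=b)
        p_plant = cfg.plant_prob_divergent if pair in div else cfg.plant_prob_nondivergent
        if rng.uniform() < p_plant:
            inst = _draw_motif_instance(motif, rng)
            offset = int(rng.integers(0, w - motif.length + 1))
            target, gene = (seq_a, ga) if rng.uniform() < 0.5 else (seq_b, gb)
            species = "A" if gene == ga else "B"
            target[offset : offset + motif.length] = [BASES.index(c) for c in inst]
            placements.append({"pair_id": pair, "motif_id": motif.motif_id,
                               "species": species, "offset": offset, "instance": inst})
        promoters_a[ga] = "".join(BASES[x] for x in seq_a)
        promoters_b[gb] = "".join(BASES[x] for x in seq_b)
    truth.placements = pd.DataFrame(
        placements, columns=["pair_id", "motif_id", "species", "offset", "instance"]
    )
    motifs = [motif]
    for k in range(cfg.n_null_motifs):
        motifs.append(demo_motif(f"NULL{k + 1:04d}", rng=rng))
    return promoters_a, promoters_b, motifs, truth


def simulate_go(cfg: SimulationConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Random term memberships over the pair universe with planted terms.

    Background term sizes are log-uniform over ``term_size_range``. The
    first ``n_planted_terms`` terms have ``planted_term_size`` members
    sampled with weight ``planted_odds`` on divergent pairs and 1
    elsewhere; the rest are uniform. Returns a gene_id/term_id/term_name
    annotation frame and records planted term ids in the truth.
    """
    rng = cfg.rng(_SPAWN_GO)
    pair_ids = np.array(cfg.pair_ids)
    div_mask = np.isin(pair_ids, list(truth.divergent_pairs))
    lo, hi = cfg.term_size_range
    hi = min(hi, cfg.n_pairs)
    rows = []
    planted = []
    for t in range(cfg.n_go_terms):
        term_id = f"TERM:{t + 1:04d}"
        if t < cfg.n_planted_terms:
            size = min(cfg.planted_term_size, cfg.n_pairs)
        else:
            size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if t < cfg.n_planted_terms:
            weights = np.where(div_mask, cfg.planted_odds, 1.0)
            weights = weights / weights.sum()
            members = rng.choice(cfg.n_pairs, size=size, replace=False, p=weights)
            planted.append(term_id)
            name = f"planted enriched process {t + 1}"
        else:
            members = rng.choice(cfg.n_pairs, size=size, replace=False)
            name = f"background process {t + 1}"
        for m in members:
            rows.append({"gene_id": pair_ids[m], "term_id": term_id, "term_name": name})
    truth.enriched_terms = planted
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])


def simulate_all(cfg: SimulationConfig):
    """Counts, promoters, motifs and annotation from one config/seed."""
    counts_a, counts_b, samples, truth = simulate_counts(cfg)
    promoters_a, promoters_b, motifs, truth = simulate_promoters(cfg, truth)
    annotation = simulate_go(cfg, truth)
    return {
        "counts_a": counts_a,
        "counts_b": counts_b,
        "samples": samples,
        "promoters_a": promoters_a,
        "promoters_b": promoters_b,
        "motifs": motifs,
        "annotation": annotation,
        "truth": truth,
    }
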