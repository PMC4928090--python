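"""End-to-end orchestration: counts -> divergence -> GO -> TFBS.

``run_pipeline`` executes the stages in order on file inputs (or on a
synthetic bundle), writes the standard TSV/FASTA outputs into an output
directory, and finishes with a JSON run manifest recording the package
version, seed, thresholds and per-stage row counts. The manifest is a
pure function of inputs and configuration, so reruns with the same
config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .countdata import read_counts
from .divergence import DivergenceModel, read_ortholog_map
from .enrich import enrich_terms, read_annotation
from .motifs import read_jaspar, scan_promoter_set
from .promoters import read_fasta, write_fasta
from .qc import qc_replicate_correlation
from .simulate import SimulationConfig, simulate_all
from .tfbs import build_presence, enrich_tfbs, extract_subnetwork

__all__ = ["PipelineConfig", "run_pipeline", "write_synthetic_inputs"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run.

    Thresholds default to the analysis' standard cutoffs: fold change 2,
    FDR 0.05, raw GO alpha 0.05, motif scan P < 1e-4, 1 kb promoters.
    """

    counts_a: str
    counts_b: str
    samples: str
    orthologs: str
    out_dir: str
    control: str = "28C"
    timepoints: tuple[str, ...] | None = None
    promoters_a: str | None = None
    promoters_b: str | None = None
    motifs: str | None = None
    annotation: str | None = None
    edges: str | None = None
    scope: str | None = None
    fc: float = 2.0
    fdr: float = 0.05
    go_alpha: float = 0.05
    motif_p: float = 1e-4
    promoter_len: int = 1000
    min_count: int = 1
    min_samples: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (self.fc > 1 and 0 < self.fdr < 1 and 0 < self.go_alpha < 1
                and 0 < self.motif_p < 1):
            raise ValueError("thresholds out of range")

    def check_inputs(self):
        required = {"counts_a": self.counts_a, "counts_b": self.counts_b,
                    "samples": self.samples, "orthologs": self.orthologs}
        for name, path in required.items():
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"{name} input missing: {path}")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest dict.

    Stages with missing optional inputs (promoters/motifs/annotation/
    edges) are skipped; a stage failure aborts with the stage name.
    """
    cfg.check_inputs()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "xdiverge",
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {"fc": cfg.fc, "fdr": cfg.fdr, "go_alpha": cfg.go_alpha,
                       "motif_p": cfg.motif_p, "promoter_len": cfg.promoter_len},
        "stages": {},
    }

    @_stage("divergence")
    def _divergence():
        counts_a = read_counts(cfg.counts_a, cfg.samples)
        counts_b = read_counts(cfg.counts_b, cfg.samples)
        orthologs = read_ortholog_map(cfg.orthologs)
        qc = pd.concat([qc_replicate_correlation(counts_a),
                        qc_replicate_correlation(counts_b)], ignore_index=True)
        qc.to_csv(out / "qc_replicates.tsv", sep="\t", index=False, float_format="%.4f")
        model = DivergenceModel.from_counts(
            counts_a, counts_b, orthologs, cfg.control,
            list(cfg.timepoints) if cfg.timepoints else None,
            min_count=cfg.min_count, min_samples=cfg.min_samples,
        )
        res = model.fit(fc_threshold=cfg.fc, fdr_threshold=cfg.fdr)
        res.write_tsv(out / "divergence.tsv")
        manifest["stages"]["divergence"] = {
            "n_pairs_tested": int(res.table["pair_id"].nunique()),
            "n_divergent_union": len(res.divergent_pairs()),
            "per_timepoint": {
                tp: len(res.divergent_pairs(tp)) for tp in model.timepoints
            },
        }
        return res

    res = _divergence()
    divergent = res.divergent_pairs()
    universe = set(res.table["pair_id"])

    if cfg.annotation:
        @_stage("go_enrichment")
        def _go():
            annotation = read_annotation(cfg.annotation)
            table = enrich_terms(divergent, universe, annotation, alpha=cfg.go_alpha)
            table.to_csv(out / "go_enrichment.tsv", sep="\t", index=False,
                         float_format="%.6g")
            manifest["stages"]["go_enrichment"] = {
                "n_terms_tested": int(len(table)),
                "n_enriched": int(table["enriched"].sum()),
            }
        _go()

    if cfg.promoters_a and cfg.promoters_b and cfg.motifs:
        @_stage("tfbs_enrichment")
        def _tfbs():
            promoters_a = read_fasta(cfg.promoters_a)
            promoters_b = read_fasta(cfg.promoters_b)
            pfms = read_jaspar(cfg.motifs)
            hits_a = scan_promoter_set(promoters_a, pfms, threshold=cfg.motif_p)
            hits_b = scan_promoter_set(promoters_b, pfms, threshold=cfg.motif_p)
            hits_a.to_csv(out / "hits_a.tsv", sep="\t", index=False, float_format="%.6g")
            hits_b.to_csv(out / "hits_b.tsv", sep="\t", index=False, float_format="%.6g")
            pairs = res.model.counts.pair_genes
            presence = build_presence(hits_a, hits_b, pairs,
                                      set(promoters_a), set(promoters_b))
            scope = None
            if cfg.scope:
                scope = set(Path(cfg.scope).read_text().split())
            table = enrich_tfbs(presence, divergent, scope=scope, alpha=0.05)
            table.to_csv(out / "tfbs_enrichment.tsv", sep="\t", index=False,
                         float_format="%.6g")
            manifest["stages"]["tfbs_enrichment"] = {
                "n_motifs": int(len(table)),
                "n_hits_a": int(len(hits_a)),
                "n_hits_b": int(len(hits_b)),
                "n_enriched": int(table["enriched"].sum()),
            }
        _tfbs()

    if cfg.edges:
        @_stage("subnetwork")
        def _net():
            edges = pd.read_csv(cfg.edges, sep="\t")
            nodes = divergent
            _, summary = extract_subnetwork(edges, set(nodes))
            manifest["stages"]["subnetwork"] = summary
        _net()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def write_synthetic_inputs(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a full synthetic input bundle on disk.

    Writes counts/sample-sheet/ortholog TSVs, promoter FASTAs, a
    JASPAR-format motif file, the annotation TSV and the truth tables;
    returns the path map.
    """
    from .motifs import write_jaspar

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_all(cfg)
    paths = {
        "counts_a": out / "counts_A.tsv",
        "counts_b": out / "counts_B.tsv",
        "samples": out / "samples.tsv",
        "orthologs": out / "orthologs.tsv",
        "promoters_a": out / "promoters_A.fa",
        "promoters_b": out / "promoters_B.fa",
        "motifs": out / "motifs.jaspar",
        "annotation": out / "annotation.tsv",
        "truth_divergent": out / "truth_divergent.tsv",
        "truth_placements": out / "truth_placements.tsv",
    }
    bundle["counts_a"].to_frame().to_csv(paths["counts_a"], sep="\t")
    bundle["counts_b"].to_frame().to_csv(paths["counts_b"], sep="\t")
    pd.DataFrame(
        [dataclasses.asdict(s) for s in bundle["samples"]]
    ).to_csv(paths["samples"], sep="\t", index=False)
    pairs = pd.DataFrame(
        [p.split("|") for p in cfg.pair_ids], columns=["gene_a", "gene_b"]
    )
    pairs.to_csv(paths["orthologs"], sep="\t", index=False)
    write_fasta(bundle["promoters_a"], paths["promoters_a"])
    write_fasta(bundle["promoters_b"], paths["promoters_b"])
    write_jaspar(bundle["motifs"], paths["motifs"])
    bundle["annotation"].to_csv(paths["annotation"], sep="\t", index=False)
    truth = bundle["truth"]
    truth.divergent.to_csv(paths["truth_divergent"], sep="\t", index=False)
    truth.placements.to_csv(paths["truth_placements"], sep="\t", index=False)
    return paths
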