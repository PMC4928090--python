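"""TSS and promoter extraction.

The TSS of a gene is taken as the first base of the 5' UTR of its
canonical transcript (for a minus-strand transcript that is its maximum
coordinate). The promoter is the 1 kb immediately upstream of the TSS in
gene orientation, excluding the TSS base itself, truncated at contig
edges. Coordinates are 0-based half-open internally (BED dialect on
disk).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = ["extract_tss", "read_tss_bed", "extract_promoters", "read_fasta", "write_fasta"]

log = logging.getLogger(__name__)


def extract_tss(gff3_path: str | Path) -> pd.DataFrame:
    """TSS table from a GFF3 file: columns gene_id, contig, strand, tss.

    One TSS per gene, from the canonical transcript (the transcript
    tagged ``canonical`` in its attributes, else the longest). The TSS is
    the start of the first 5' UTR record when UTRs are annotated,
    otherwise the transcript's own 5' end. Genes whose canonical
    transcript has neither UTR nor exon records are skipped with a log
    message.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        transcripts = list(db.children(gene, level=1))
        transcripts = [t for t in transcripts if t.featuretype in ("mRNA", "transcript")]
        if not transcripts:
            log.info("gene %s skipped: no transcripts", gene_id)
            continue
        canonical = [
            t for t in transcripts
            if "canonical" in {tag.lower() for v in t.attributes.get("tag", []) for tag in v.split(",")}
            or t.attributes.get("canonical", ["0"])[0] == "1"
        ]
        tx = canonical[0] if canonical else max(transcripts, key=lambda t: t.end - t.start)
        utrs = [u for u in db.children(tx, level=1) if u.featuretype == "five_prime_UTR"]
        exons = [e for e in db.children(tx, level=1) if e.featuretype == "exon"]
        source = utrs or exons or [tx]
        if not (utrs or exons) and tx.featuretype not in ("mRNA", "transcript"):
            log.info("gene %s skipped: no UTR/exon records", gene_id)
            continue
        # gffutils keeps GFF3 1-based inclusive coords; convert to 0-based
        if tx.strand == "-":
            tss = max(f.end for f in source) - 1
        else:
            tss = min(f.start for f in source) - 1
        rows.append({"gene_id": gene_id, "contig": tx.seqid, "strand": tx.strand, "tss": tss})
    return pd.DataFrame(rows, columns=["gene_id", "contig", "strand", "tss"])


def read_tss_bed(path: str | Path) -> pd.DataFrame:
    """TSS table from a BED file of transcript (or TSS point) intervals.

    Plus strand: TSS = chromStart; minus strand: TSS = chromEnd - 1.
    The BED name field is the gene id.
    """
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 6:
        raise ValueError("BED input needs 6 columns (strand required)")
    bed = bed.iloc[:, :6]
    bed.columns = ["contig", "start", "end", "gene_id", "score", "strand"]
    if not bed["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be + or -")
    tss = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1)
    return pd.DataFrame(
        {"gene_id": bed["gene_id"], "contig": bed["contig"],
         "strand": bed["strand"], "tss": tss}
    )


def extract_promoters(
    genome: str | Path | dict[str, str],
    tss_table: pd.DataFrame,
    length: int = 1000,
) -> dict[str, str]:
    """Upstream ``length`` bases per gene, in gene orientation.

    Plus strand: genome[tss-length : tss); minus strand: reverse
    complement of genome[tss+1 : tss+1+length). The TSS base itself is
    excluded; promoters truncated at contig edges are logged. Missing
    contigs raise.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
        contigs = {name: fa[name] for name in fa.keys()}
        sizes = {name: len(fa[name]) for name in fa.keys()}
    else:
        contigs = {k: v.upper() for k, v in genome.items()}
        sizes = {k: len(v) for k, v in contigs.items()}
    out: dict[str, str] = {}
    for row in tss_table.itertuples(index=False):
        if row.contig not in contigs:
            raise KeyError(f"contig {row.contig!r} not in genome")
        size = sizes[row.contig]
        if not (0 <= row.tss < size):
            raise ValueError(f"TSS {row.tss} outside contig {row.contig!r} (len {size})")
        if row.strand == "+":
            start = max(0, row.tss - length)
            seq = str(contigs[row.contig][start:row.tss])
        elif row.strand == "-":
            end = min(size, row.tss + 1 + length)
            seq = str(Seq(str(contigs[row.contig][row.tss + 1:end])).reverse_complement())
        else:
            raise ValueError(f"bad strand {row.strand!r} for gene {row.gene_id}")
        if len(seq) < length:
            log.info("promoter of %s truncated to %d bases at contig edge",
                     row.gene_id, len(seq))
        out[str(row.gene_id)] = seq.upper()
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
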