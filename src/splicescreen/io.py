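"""Readers and writers for the pipeline's on-disk artifacts.

Genome as FASTA, annotation as GFF3 (1-based inclusive, converted to the
internal 0-based half-open convention at parse time via gffutils), junction
counts / sample sheets / domain and truth tables as TSV, single-cell reads
as FASTQ with the barcode embedded in the read name, and the cell x junction
matrix as MatrixMarket with sidecar index files.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import io as scipy_io
from scipy import sparse

from .coords import TranscriptModel
from .screen import CellJunctionMatrix


# -- FASTA / FASTQ ----------------------------------------------------------


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


# -- GFF3 -------------------------------------------------------------------


def write_gff3(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    for t in transcripts:
        gs, ge = t.span
        feats = [("gene", gs, ge, f"ID={t.gene_id}")]
        feats.append(("mRNA", gs, ge, f"ID={t.transcript_id};Parent={t.gene_id}"))
        for i, (s, e) in enumerate(t.exons):
            feats.append(("exon", s, e, f"ID={t.transcript_id}.e{i};Parent={t.transcript_id}"))
        for i, (s, e) in enumerate(t.cds):
            attrs = f"ID={t.transcript_id}.c{i};Parent={t.transcript_id}"
            if t.protein_id:
                attrs += f";protein_id={t.protein_id}"
            feats.append(("CDS", s, e, attrs))
        for ftype, s, e, attrs in feats:
            lines.append(
                "\t".join(
                    [t.contig, "splicescreen", ftype, str(s + 1), str(e), ".", t.strand, ".", attrs]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def transcripts_from_gff3(path: str | Path) -> list[TranscriptModel]:
    """Parse mRNA features with their exons/CDS into transcript models."""
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    out = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        protein_id = None
        for f in db.children(mrna, featuretype="CDS"):
            pid = f.attributes.get("protein_id")
            if pid:
                protein_id = pid[0]
                break
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        out.append(
            TranscriptModel(
                transcript_id=mrna.id,
                gene_id=gene_id,
                contig=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
                cds=tuple(cds),
                protein_id=protein_id,
            )
        )
    return sorted(out, key=lambda t: t.transcript_id)


# -- tables -----------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=True)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_peptide_db(peptides: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(peptides) + "\n")


def read_peptide_db(path: str | Path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


def read_serotypes(path: str | Path) -> dict[str, list[str]]:
    df = read_table(path)
    return {
        pid: sorted(sub["allele"].astype(str)) for pid, sub in df.groupby("patient_id")
    }


# -- sparse cell x junction matrix -----------------------------------------


def write_cell_matrix(matrix: CellJunctionMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    m = sparse.csr_matrix(matrix.counts.to_numpy())
    scipy_io.mmwrite(str(prefix.with_suffix(".mtx")), m)
    prefix.with_suffix(".barcodes.txt").write_text("\n".join(matrix.counts.index) + "\n")
    prefix.with_suffix(".junctions.txt").write_text(
        "\n".join(map(str, matrix.counts.columns)) + "\n"
    )


def read_cell_matrix(prefix: str | Path, cell_types: pd.Series) -> CellJunctionMatrix:
    prefix = Path(prefix)
    m = scipy_io.mmread(str(prefix.with_suffix(".mtx"))).toarray().astype(int)
    barcodes = prefix.with_suffix(".barcodes.txt").read_text().split()
    junctions = prefix.with_suffix(".junctions.txt").read_text().split()
    counts = pd.DataFrame(m, index=barcodes, columns=junctions)
    return CellJunctionMatrix(counts=counts, cell_types=cell_types)


# -- BED --------------------------------------------------------------------


def write_hits_bed(hits: pd.DataFrame, path: str | Path) -> None:
    """Motif hits as BED6: 0-based half-open, score = bits x 100 rounded."""
    with open(path, "w") as fh:
        for _, r in hits.iterrows():
            fh.write(
                f"{r['contig']}\t{int(r['start'])}\t{int(r['end'])}\t"
                f"{r['motif_id']}\t{int(round(100 * r['score']))}\t{r['strand']}\n"
            )
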