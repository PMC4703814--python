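"""Reading and writing the pipeline's file formats.

FASTQ (Sanger Phred+33) and FASTA go through Biopython's SeqIO; barcode
maps, truth tables, QC ledgers and OTU tables are plain TSV via pandas.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .readqc import AmpliconRead

__all__ = [
    "read_fastq", "write_fastq", "read_fasta", "write_fasta",
    "read_fasta_qual",
    "read_barcode_map", "write_barcode_map",
    "read_truth", "write_truth",
    "write_otu_table", "read_otu_table",
    "write_phylip", "write_sparse_triples", "write_membership",
]


def read_fastq(path) -> list[AmpliconRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(AmpliconRead(
            id=rec.id, nucleotides=str(rec.seq),
            qualities=list(rec.letter_annotations["phred_quality"]),
        ))
    return reads


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.nucleotides), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = (
            r.qualities if r.qualities is not None else [40] * len(r.nucleotides)
        )
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_qual(fasta_path, qual_path) -> list[AmpliconRead]:
    """Paired FASTA + QUAL input (the classic pyrosequencing layout)."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    quals = {rec.id: rec.letter_annotations["phred_quality"]
             for rec in SeqIO.parse(str(qual_path), "qual")}
    return [AmpliconRead(id=rid, nucleotides=seq,
                         qualities=list(quals[rid]) if rid in quals else None)
            for rid, seq in seqs.items()]


def write_phylip(dm, path) -> None:
    """Square lower+upper ("phylip"-style) distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.matrix):
            fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def write_sparse_triples(table: pd.DataFrame, path) -> None:
    """OTU table as (site, otu, count) triples, zeros omitted."""
    with open(path, "w") as fh:
        fh.write("site\totu\tcount\n")
        for site in table.index:
            row = table.loc[site]
            for otu in table.columns[row.to_numpy() > 0]:
                fh.write(f"{site}\t{otu}\t{int(row[otu])}\n")


def write_membership(assignment, rep_index, read_ids, dm_labels, path) -> None:
    """Per-read OTU membership list (read_id, otu)."""
    with open(path, "w") as fh:
        fh.write("read_id\totu\n")
        for rid, r in zip(read_ids, rep_index):
            fh.write(f"{rid}\tOTU{assignment.assignment[dm_labels[int(r)]]}\n")


def read_barcode_map(path) -> dict[str, str]:
    """TSV of (barcode, site) -> {barcode: site}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["barcode", "site"],
                     dtype=str)
    return dict(zip(df["barcode"], df["site"]))


def write_barcode_map(barcodes: dict[str, str], path) -> None:
    """``barcodes`` maps site -> barcode (as built by the simulator)."""
    with open(path, "w") as fh:
        for site, bc in barcodes.items():
            fh.write(f"{bc}\t{site}\n")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="read_id")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def write_otu_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_otu_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="site")
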