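"""Readers and writers for the standard interchange formats.

The pipeline consumes a reference genome (FASTA) with gene models
(GFF3, 1-based inclusive), one VCF v4.2 per MA line, and a line
metadata table (TSV); it emits the same formats plus plain TSV/JSON
result tables.  Parsing goes through Biopython (FASTA), gffutils
(GFF3) and cyvcf2 (VCF).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .core import GeneModel, LineMetadata, MutationRecord, ReferenceBundle

PathLike = Union[str, os.PathLike]

METADATA_COLUMNS = [
    "line_id",
    "group",
    "dish_id",
    "transfers",
    "divisions_per_transfer",
    "total_divisions",
    "mean_depth",
    "analyzable_sites",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: PathLike) -> Dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ----------------------------------------------------------------- GFF3

def read_gff3(path: PathLike) -> List[GeneModel]:
    """Gene models from a GFF3 file: genes with CDS children (via mRNA)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        cds = sorted(
            db.children(gene, featuretype="CDS", order_by="start"),
            key=lambda f: f.start,
        )
        if not cds:
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                cds_intervals=tuple((f.start, f.end) for f in cds),
            )
        )
    return genes


def write_gff3(
    genes: Sequence[GeneModel], sequences: Dict[str, str], path: PathLike
) -> None:
    lines = ["##gff-version 3"]
    for name, seq in sequences.items():
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
        lines.append(
            "\t".join(
                [g.chromosome, "mawgs", "gene", str(g.start), str(g.end), ".",
                 g.strand, ".", f"ID={g.gene_id}"]
            )
        )
        mrna = f"{g.gene_id}.t1"
        lines.append(
            "\t".join(
                [g.chromosome, "mawgs", "mRNA", str(g.start), str(g.end), ".",
                 g.strand, ".", f"ID={mrna};Parent={g.gene_id}"]
            )
        )
        # phase accumulates along the coding strand
        order = list(g.cds_intervals)
        if g.strand == "-":
            order = order[::-1]
        cum = 0
        phases = {}
        for (s, e) in order:
            phases[(s, e)] = (3 - cum % 3) % 3
            cum += e - s + 1
        for j, (s, e) in enumerate(g.cds_intervals, start=1):
            lines.append(
                "\t".join(
                    [g.chromosome, "mawgs", "CDS", str(s), str(e), ".", g.strand,
                     str(phases[(s, e)]), f"ID={mrna}.cds{j};Parent={mrna}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_reference(fasta: PathLike, gff3: Optional[PathLike] = None) -> ReferenceBundle:
    sequences = read_fasta(fasta)
    genes = read_gff3(gff3) if gff3 is not None else []
    return ReferenceBundle(sequences=sequences, genes=genes)


# ------------------------------------------------------------------ VCF

def write_vcf(
    records: Sequence[MutationRecord],
    sequences: Dict[str, str],
    path: PathLike,
) -> None:
    lines = ["##fileformat=VCFv4.2"]
    for name, seq in sequences.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in sorted(records, key=lambda r: (r.chromosome, r.position)):
        lines.append(
            f"{r.chromosome}\t{r.position}\t.\t{r.ref_allele}\t{r.alt_allele}"
            "\t.\tPASS\t."
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: PathLike, line_id: Optional[str] = None) -> List[MutationRecord]:
    """Mutation records from one per-line VCF; ``line_id`` defaults to the
    file stem."""
    if line_id is None:
        line_id = Path(path).stem
    out: List[MutationRecord] = []
    for v in VCF(str(path)):
        alts = v.ALT or []
        for alt in alts:
            out.append(
                MutationRecord(
                    line_id=line_id,
                    chromosome=v.CHROM,
                    position=v.POS,
                    ref_allele=v.REF,
                    alt_allele=alt,
                )
            )
    return out


def read_vcf_dir(vcf_dir: PathLike) -> Dict[str, List[MutationRecord]]:
    """All ``*.vcf`` files of a directory, keyed by line id (file stem)."""
    out: Dict[str, List[MutationRecord]] = {}
    for p in sorted(Path(vcf_dir).glob("*.vcf")):
        out[p.stem] = read_vcf(p)
    return out


# ------------------------------------------------------------- metadata

def write_metadata(lines: Sequence[LineMetadata], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "line_id": m.line_id,
                "group": m.group,
                "dish_id": m.dish_id,
                "transfers": m.transfers,
                "divisions_per_transfer": m.divisions_per_transfer,
                "total_divisions": m.total_divisions,
                "mean_depth": m.mean_depth,
                "analyzable_sites": m.analyzable_sites,
            }
            for m in lines
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: PathLike) -> List[LineMetadata]:
    df = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return [
        LineMetadata(
            line_id=str(row.line_id),
            group=str(row.group),
            dish_id=str(row.dish_id),
            transfers=int(row.transfers),
            divisions_per_transfer=int(row.divisions_per_transfer),
            total_divisions=int(row.total_divisions),
            mean_depth=float(row.mean_depth),
            analyzable_sites=int(row.analyzable_sites),
        )
        for row in df.itertuples()
    ]
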