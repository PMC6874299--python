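"""Readers/writers for the plain-text and TIFF interchange formats."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import ALIGNMENT_COLUMNS, CountVector, EventTable, GenomeAnnotation, GroundTruth


def read_counts_csv(path) -> list[CountVector]:
    """CSV with columns cell_id, gene, condition, count -> CountVectors."""
    df = pd.read_csv(path)
    df[["gene", "condition"]] = df[["gene", "condition"]].fillna("")
    out = []
    for (gene, condition), grp in df.groupby(["gene", "condition"], sort=False):
        out.append(CountVector(counts=grp["count"].to_numpy(), gene=str(gene),
                               condition=str(condition)))
    return out


def write_counts_csv(cv: CountVector, path) -> None:
    pd.DataFrame(
        {
            "cell_id": np.arange(cv.n_cells),
            "gene": cv.gene,
            "condition": cv.condition,
            "count": cv.counts,
        }
    ).to_csv(path, index=False)


def read_alignments_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"umi": str}, keep_default_na=False)
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    return df


def write_alignments_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> GenomeAnnotation:
    """TSV: gene, chrom, strand, tss, end3 (+ optional chrom_length column)."""
    df = pd.read_csv(path, sep="\t")
    lengths = {}
    if "chrom_length" in df.columns:
        lengths = df.groupby("chrom")["chrom_length"].first().astype(int).to_dict()
        df = df.drop(columns=["chrom_length"])
    return GenomeAnnotation(genes=df, chrom_lengths=lengths)


def write_annotation_tsv(ann: GenomeAnnotation, path) -> None:
    df = ann.genes.copy()
    if ann.chrom_lengths:
        df["chrom_length"] = df["chrom"].map(ann.chrom_lengths)
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_events_csv(path, meta: dict | None = None) -> EventTable:
    return EventTable(events=pd.read_csv(path), meta=meta or {})


def write_events_csv(table: EventTable, path, meta_path=None) -> None:
    table.events.to_csv(path, index=False)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(table.meta, indent=1, sort_keys=True))


def write_ground_truth(gt: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(gt.to_json_dict(), indent=1, sort_keys=True))


def write_bedgraph(track: dict, path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in track.items():
            nz = np.flatnonzero(arr)
            for p in nz:
                fh.write(f"{chrom}\t{p}\t{p + 1}\t{arr[p]:.6g}\n")
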