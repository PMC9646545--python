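"""Readers and writers for the plain-text formats the pipeline exchanges.

Genomic coordinates are 0-based, half-open (BED convention) everywhere.
All tables are tab-separated text so every stage is independently runnable
and diffable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]
BED5_COLUMNS = ["chrom", "start", "end", "peak_id", "score"]
BEDGRAPH_COLUMNS = ["chrom", "start", "end", "value"]


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    """Write a genes x samples matrix; first column is the gene/probe ID."""
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "tissue"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing required columns: {sorted(missing)}")
    return meta.set_index("sample_id")


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_bed6(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    return genes


def write_bed6(genes: pd.DataFrame, path) -> None:
    genes[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed5(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED5_COLUMNS)


def write_bed5(peaks: pd.DataFrame, path) -> None:
    peaks[BED5_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(arrays: dict[str, np.ndarray], path) -> None:
    """Run-length encode per-base arrays into 4-column bedGraph intervals."""
    records = []
    for chrom in arrays:
        values = np.asarray(arrays[chrom], dtype=float)
        if values.size == 0:
            continue
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [values.size]])
        records.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "value": values[starts]}
            )
        )
    pd.concat(records, ignore_index=True).to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph into per-base arrays covering the declared genome.

    Positions absent from the file get value 0, matching the convention that
    the genome-wide mean includes uncovered bases.
    """
    table = pd.read_csv(path, sep="\t", header=None, names=BEDGRAPH_COLUMNS)
    arrays = {chrom: np.zeros(size, dtype=float) for chrom, size in chrom_sizes.items()}
    for chrom, start, end, value in table.itertuples(index=False):
        if chrom not in arrays:
            raise ValueError(f"bedGraph chromosome {chrom!r} absent from declared genome")
        arrays[chrom][int(start): int(end)] = value
    return arrays


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"} <= set(ann.columns):
        # two-column headerless form
        ann = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"], dtype=str)
    return ann[["gene_id", "term_id"]]


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)
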