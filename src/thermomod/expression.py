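"""Expression matrix handling: reading, probe collapsing, z-score normalization.

The pipeline consumes matrices that are already normalized on a log-like
scale (e.g. RMA for microarray, log of library-size-normalized counts for
RNA-seq).  This module turns those into the per-gene z-scored "normalized
transcription levels" used for clustering and profile plots, where each
value expresses relative up-/down-regulation against the gene's mean across
all samples.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import read_metadata_tsv

logger = logging.getLogger(__name__)

#: Controlled vocabulary of temperature categories.  Extensible: unknown
#: labels are accepted with a warning so that binding-assay condition sets
#: (e.g. 17C/27C/37C) can flow through the same metadata structures.
CONDITION_VOCABULARY = frozenset(
    {
        "freezing",
        "cold",
        "low_ambient",
        "normal",
        "high_ambient",
        "heat_shock",
        "heat_shock_recovery",
    }
)


class NormalizedMatrix(NamedTuple):
    """Per-gene z-scored matrix plus the genes that were constant (all-zero rows)."""

    values: pd.DataFrame
    constant_genes: list[str]


def read_expression(matrix_path, metadata_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an expression TSV (rows = genes/probes, header = sample IDs) and metadata.

    Every sample in the matrix header must appear in the metadata; offenders
    are listed in the error.  Non-numeric cells are a hard error with their
    location.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "gene_id"
    for col in matrix.columns:
        if not np.issubdtype(matrix[col].dtype, np.number):
            bad = matrix[pd.to_numeric(matrix[col], errors="coerce").isna()].index
            raise ValueError(
                f"non-numeric expression values in sample {col!r}, e.g. gene {bad[0]!r}"
            )
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated row identifiers in expression matrix: {dup[:5]}")
    metadata = read_metadata_tsv(metadata_path)
    missing = [s for s in matrix.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing}")
    unknown = sorted(set(metadata["condition"]) - CONDITION_VOCABULARY)
    if unknown:
        logger.warning("conditions outside the standard vocabulary: %s", unknown)
    aligned = metadata.loc[matrix.columns]
    aligned.index.name = "sample_id"
    return matrix, aligned


def collapse_probes(matrix: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene by the arithmetic mean.

    ``probe_map`` needs columns ``probe_id`` and ``gene_id``.  Probes absent
    from the map are dropped (count logged); an empty intersection is an
    error.
    """
    if not {"probe_id", "gene_id"} <= set(probe_map.columns):
        raise ValueError("probe_map must have columns probe_id and gene_id")
    mapping = probe_map.set_index("probe_id")["gene_id"]
    mapped = matrix.index.intersection(mapping.index)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix appears in the probe map")
    dropped = len(matrix) - len(mapped)
    if dropped:
        logger.info("dropping %d unmapped probe rows", dropped)
    sub = matrix.loc[mapped]
    collapsed = sub.groupby(mapping.loc[mapped].to_numpy()).mean()
    collapsed.index.name = "gene_id"
    return collapsed


def zscore_rows(
    matrix: pd.DataFrame, ddof: int = 1, group_by: pd.Series | None = None
) -> NormalizedMatrix:
    """Z-score each gene across samples: (x - mean) / sd with the sample SD (n-1).

    Constant rows become all zeros and are flagged rather than dropped.  With
    ``group_by`` (a per-sample label series, e.g. tissue), each group of
    samples is z-scored independently — this is how profiles from different
    tissues are re-normalized together for cross-tissue comparison.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    if group_by is not None:
        pieces, flagged = [], set()
        for _, cols in matrix.columns.to_series().groupby(group_by.loc[matrix.columns]):
            part = zscore_rows(matrix[cols.index], ddof=ddof)
            pieces.append(part.values)
            flagged.update(part.constant_genes)
        out = pd.concat(pieces, axis=1)[matrix.columns]
        return NormalizedMatrix(out, sorted(flagged))
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (values - mean) / sd
    z[constant] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return NormalizedMatrix(out, matrix.index[constant].tolist())
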