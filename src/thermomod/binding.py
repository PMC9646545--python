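"""TF DNA-binding occupancy analysis.

Coverage tracks (reads per base) are normalized by the genome-wide average
count so tracks from different sequencing depths are comparable: after
normalization the genome mean is 1 and a value of 3 means threefold the
average coverage.  Peaks are assigned to genes whose TSS lies within a
promoter window of the peak midpoint; per-gene occupancy around the TSS is
summarized as a strand-oriented meta-profile; and target tables across
assay conditions are combined into a binding classification:

* ``type_I``  — bound only in the designated specific condition
  (condition-specific binding, e.g. heat-shock-only);
* ``type_II`` — bound in every assayed condition (constitutive binding);
* ``other``   — any remaining bound pattern;
* ``none``    — bound nowhere.

Coordinates are 0-based half-open; the TSS of a minus-strand gene is
``end - 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BINDING_CLASSES = ("type_I", "type_II", "other", "none")


@dataclass
class CoverageTrack:
    """Per-base coverage over a declared genome, one array per chromosome."""

    arrays: dict[str, np.ndarray]

    @property
    def genome_length(self) -> int:
        return sum(a.size for a in self.arrays.values())

    @property
    def genome_mean(self) -> float:
        """Mean over every genome position, zero-coverage bases included."""
        return float(sum(a.sum() for a in self.arrays.values()) / self.genome_length)


class MetaProfile(NamedTuple):
    offsets: np.ndarray   # -window .. +window, upstream negative for every gene
    mean: np.ndarray      # mean normalized occupancy per offset
    n_genes: int          # genes included after neighbor-overlap exclusion
    n_excluded: int


def add_tss(genes: pd.DataFrame) -> pd.DataFrame:
    """Attach the TSS column: start for + strand, end-1 for - strand."""
    out = genes.copy()
    bad = ~out["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid strand values: {out.loc[bad, 'strand'].unique().tolist()}")
    if (out["start"] >= out["end"]).any():
        raise ValueError("gene intervals must satisfy start < end")
    if out["gene_id"].duplicated().any():
        raise ValueError("gene_ids must be unique")
    out["tss"] = np.where(out["strand"] == "+", out["start"], out["end"] - 1)
    return out


def normalize_coverage(track: CoverageTrack) -> CoverageTrack:
    """Divide every value by the genome-wide mean; output mean is 1."""
    mean = track.genome_mean
    if mean <= 0:
        raise ValueError("cannot normalize an all-zero coverage track")
    return CoverageTrack({c: a / mean for c, a in track.arrays.items()})


def assign_peaks(peaks: pd.DataFrame, genes: pd.DataFrame, window: int = 500) -> pd.DataFrame:
    """Assign each peak to the gene whose TSS is nearest its midpoint.

    A peak qualifies for a gene when its midpoint (floor of the interval
    centre) lies within ``[TSS - window, TSS + window]``, both ends
    inclusive.  Ties on distance break to the lexicographically smaller
    gene_id.  Peaks on chromosomes absent from the annotation are dropped
    with a logged count.  Returns one row per assigned peak
    (gene_id, peak_id, score, distance) — the per-gene best score is the max
    over its peaks.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    genes = add_tss(genes) if "tss" not in genes.columns else genes
    rows = []
    n_dropped = 0
    by_chrom = {c: g.sort_values(["tss", "gene_id"]) for c, g in genes.groupby("chrom")}
    for peak in peaks.itertuples(index=False):
        sub = by_chrom.get(peak.chrom)
        if sub is None:
            n_dropped += 1
            continue
        midpoint = (int(peak.start) + int(peak.end)) // 2
        dist = np.abs(sub["tss"].to_numpy() - midpoint)
        within = dist <= window
        if not within.any():
            continue
        best = np.min(dist[within])
        candidates = sub.loc[within][dist[within] == best]
        gene_id = candidates["gene_id"].min()  # lexicographic tie-break
        rows.append(
            {
                "gene_id": gene_id,
                "peak_id": peak.peak_id,
                "score": float(peak.score),
                "distance": int(best),
            }
        )
    if n_dropped:
        logger.info("dropped %d peaks on chromosomes absent from the annotation", n_dropped)
    return pd.DataFrame(rows, columns=["gene_id", "peak_id", "score", "distance"])


def best_scores(targets: pd.DataFrame) -> pd.Series:
    """Per-gene best (maximum) peak score from an assignment table."""
    if targets.empty:
        return pd.Series(dtype=float, name="score")
    return targets.groupby("gene_id")["score"].max()


def meta_profile(
    track: CoverageTrack, genes: pd.DataFrame, gene_set: Iterable[str], window: int = 500
) -> MetaProfile:
    """Average strand-oriented occupancy in a TSS-centred window over genes.

    For each gene the ``2*window + 1`` per-base values centred on its TSS are
    extracted and reversed for minus-strand genes, so negative offsets are
    always upstream.  Genes whose window intersects any other gene's body
    ``[start, end)`` are excluded (neighbor-overlap rule), as are genes whose
    window runs off the chromosome.
    """
    genes = add_tss(genes) if "tss" not in genes.columns else genes
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    indexed = genes.set_index("gene_id")
    unknown = [g for g in gene_set if g not in indexed.index]
    if unknown:
        raise KeyError(f"genes absent from the annotation: {unknown[:10]}")

    curves = []
    n_excluded = 0
    for g in gene_set:
        row = indexed.loc[g]
        chrom, tss = row["chrom"], int(row["tss"])
        lo, hi = tss - window, tss + window + 1
        arr = track.arrays.get(chrom)
        if arr is None or lo < 0 or hi > arr.size:
            n_excluded += 1
            continue
        neighbors = genes[(genes["chrom"] == chrom) & (genes["gene_id"] != g)]
        overlaps = (neighbors["start"] < hi) & (neighbors["end"] > lo)
        if overlaps.any():
            n_excluded += 1
            continue
        values = arr[lo:hi]
        if row["strand"] == "-":
            values = values[::-1]
        curves.append(values)
    if not curves:
        raise ValueError(
            f"no genes left after neighbor-overlap exclusion ({n_excluded} excluded)"
        )
    mean = np.mean(np.stack(curves), axis=0)
    return MetaProfile(np.arange(-window, window + 1), mean, len(curves), n_excluded)


def classify_binding(
    targets_by_condition: Mapping[str, Iterable[str]],
    specific_condition: str,
    universe: Iterable[str],
) -> pd.Series:
    """Classify each gene's binding pattern across assay conditions.

    ``targets_by_condition`` maps condition label -> bound gene set ("bound"
    means at least one assigned peak, regardless of score).  Requires >= 2
    conditions including ``specific_condition``.  Classes partition the
    universe.
    """
    conditions = list(targets_by_condition)
    if len(conditions) < 2:
        raise ValueError("classification needs target tables for >= 2 conditions")
    if specific_condition not in conditions:
        raise ValueError(
            f"specific condition {specific_condition!r} not among {conditions}"
        )
    sets = {c: set(targets_by_condition[c]) for c in conditions}
    out = {}
    for g in universe:
        bound_in = {c for c in conditions if g in sets[c]}
        if not bound_in:
            out[g] = "none"
        elif bound_in == set(conditions):
            out[g] = "type_II"
        elif bound_in == {specific_condition}:
            out[g] = "type_I"
        else:
            out[g] = "other"
    return pd.Series(out, name="binding_class")


def binding_class_table(
    classification: pd.Series, clusters: pd.Series, include_none: bool = False
) -> pd.DataFrame:
    """Cluster x binding-class contingency table for chi-squared enrichment."""
    frame = pd.DataFrame({"cluster": clusters, "class": classification.reindex(clusters.index)})
    if not include_none:
        frame = frame[frame["class"] != "none"]
    return pd.crosstab(frame["cluster"], frame["class"])


def multi_tf_targets(
    targets_by_tf: Mapping[str, Iterable[str]],
    scores_by_tf: Mapping[str, pd.Series] | None = None,
    expression: pd.DataFrame | None = None,
) -> dict:
    """Common vs TF-specific target sets across >= 2 TFs.

    ``common`` is the intersection of all target sets; ``specific[tf]`` are
    the genes targeted by that TF and no other.  When per-gene peak scores
    or an expression matrix are supplied, per-set score / mean-expression
    summaries are attached for rank-based comparison.
    """
    tfs = list(targets_by_tf)
    if len(tfs) < 2:
        raise ValueError("need target sets for >= 2 TFs")
    sets = {t: set(targets_by_tf[t]) for t in tfs}
    common = set.intersection(*sets.values())
    specific = {
        t: sets[t] - set.union(*(sets[o] for o in tfs if o != t)) for t in tfs
    }
    result = {"common": common, "specific": specific}
    if scores_by_tf is not None:
        result["scores"] = {
            "common": {t: scores_by_tf[t].reindex(sorted(common)).dropna() for t in tfs},
            "specific": {
                t: scores_by_tf[t].reindex(sorted(specific[t])).dropna() for t in tfs
            },
        }
    if expression is not None:
        result["expression"] = {
            "common": expression.reindex(sorted(common)).dropna(how="all"),
            "specific": {
                t: expression.reindex(sorted(specific[t])).dropna(how="all") for t in tfs
            },
        }
    return result


def score_by_condition(
    targets_by_condition: Mapping[str, pd.DataFrame], classification: pd.Series
) -> pd.DataFrame:
    """Per (binding class, condition) peak-score observations.

    ``targets_by_condition`` maps condition -> peak assignment table (from
    :func:`assign_peaks`).  Scores are the per-gene best scores.  Empty
    classes are omitted with a warning.  The long-format output feeds
    :func:`thermomod.clustering.wilcoxon_bonferroni` directly.
    """
    rows = []
    for cond, table in targets_by_condition.items():
        per_gene = best_scores(table)
        for gene, score in per_gene.items():
            cls = classification.get(gene, "none")
            rows.append({"condition": cond, "class": cls, "gene_id": gene, "score": score})
    out = pd.DataFrame(rows, columns=["condition", "class", "gene_id", "score"])
    present = set(out["class"])
    for cls in BINDING_CLASSES[:-1]:
        if cls not in present:
            logger.warning("binding class %s has no scored genes; omitted", cls)
    return out
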