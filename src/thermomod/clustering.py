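"""Ward clustering of z-scored profiles and follow-up group comparisons.

Genes are clustered on the Euclidean distance between their z-score
profiles with Ward's minimum-variance linkage, the dendrogram is cut into k
flat clusters, and labels are renumbered by descending cluster size so
label 1 is always the largest module.  Follow-up statistics operate on
pooled (gene, sample) observations — each dot one profile value — matching
how per-family distributions are usually compared across conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

#: Significance bands for star annotations on adjusted p-values.
STAR_BANDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for cut, symbol in STAR_BANDS:
        if p <= cut:
            return symbol
    return "ns"


@dataclass
class ClusterAssignment:
    labels: pd.Series                 # gene_id -> 1..k, ordered by descending size
    linkage: np.ndarray               # scipy linkage matrix (merge heights)
    k: int
    condition_means: pd.DataFrame     # cluster x condition mean z-score
    leaf_order: list[str]             # dendrogram leaf order for heatmap-ready output

    def genes(self, cluster: int) -> list[str]:
        return self.labels.index[self.labels == cluster].tolist()

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def ward_cluster(norm: pd.DataFrame, k: int, metadata: pd.DataFrame) -> ClusterAssignment:
    """Cluster gene z-score profiles into exactly k modules by Ward linkage."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(norm):
        raise ValueError(f"k={k} exceeds the number of genes ({len(norm)})")
    values = norm.to_numpy(dtype=float)
    link = hierarchy.linkage(values, method="ward")
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # renumber by descending size; ties break on the smaller raw label
    counts = pd.Series(raw).value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=norm.index, name="cluster")
    leaf_order = [norm.index[i] for i in hierarchy.leaves_list(link)]

    cond = metadata.loc[norm.columns, "condition"]
    rows = {}
    for c in range(1, k + 1):
        sub = norm.loc[labels == c]
        rows[c] = sub.T.groupby(cond).mean().mean(axis=1)
    condition_means = pd.DataFrame(rows).T
    condition_means.index.name = "cluster"
    return ClusterAssignment(labels, link, k, condition_means, leaf_order)


def choose_k_elbow(norm: pd.DataFrame, k_range=range(2, 11)) -> int:
    """Default k: the elbow of the within-cluster variance curve over k."""
    from .hvg import elbow_cutoff

    values = norm.to_numpy(dtype=float)
    link = hierarchy.linkage(values, method="ward")
    wss = []
    ks = [k for k in k_range if k <= len(norm)]
    for k in ks:
        raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
        total = 0.0
        for c in np.unique(raw):
            block = values[raw == c]
            total += ((block - block.mean(axis=0)) ** 2).sum()
        wss.append(total)
    res = elbow_cutoff(np.asarray(wss))
    return ks[res.index if not res.no_elbow else 0]


def condition_profile(
    norm: pd.DataFrame, metadata: pd.DataFrame, gene_set
) -> pd.DataFrame:
    """Per-condition mean/median/SD of normalized values over (gene, sample) pairs."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    unknown = [g for g in gene_set if g not in norm.index]
    if unknown:
        raise KeyError(f"genes absent from the matrix: {unknown[:10]}")
    cond = metadata.loc[norm.columns, "condition"]
    rows = []
    for c in pd.unique(cond):
        cols = norm.columns[(cond == c).to_numpy()]
        if len(cols) == 0:
            logger.warning("condition %s has no samples; omitted", c)
            continue
        values = norm.loc[gene_set, cols].to_numpy().ravel()
        rows.append(
            {
                "condition": c,
                "mean": float(values.mean()),
                "median": float(np.median(values)),
                "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
                "n_obs": int(values.size),
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def anova_tukey(norm: pd.DataFrame, metadata: pd.DataFrame, gene_set) -> pd.DataFrame:
    """One-way ANOVA over conditions then Tukey's HSD on all condition pairs.

    Observations are the pooled normalized values of ``gene_set`` members.
    Returns one row per condition pair with the mean difference, raw-scale
    family-wise adjusted p, and a leading ``anova`` row with the global F test.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    cond = metadata.loc[norm.columns, "condition"]
    obs, labels = [], []
    for c in pd.unique(cond):
        cols = norm.columns[(cond == c).to_numpy()]
        values = norm.loc[gene_set, cols].to_numpy().ravel()
        if values.size < 2:
            logger.warning("condition %s has <2 observations; dropped", c)
            continue
        obs.append(values)
        labels.extend([c] * values.size)
    if len(obs) < 2:
        raise ValueError("need at least 2 conditions with >=2 observations")
    f_stat, p_anova = stats.f_oneway(*obs)
    pooled = np.concatenate(obs)
    tukey = pairwise_tukeyhsd(pooled, np.array(labels), alpha=0.05)
    group_pairs = [
        (tukey.groupsunique[i], tukey.groupsunique[j])
        for i in range(len(tukey.groupsunique))
        for j in range(i + 1, len(tukey.groupsunique))
    ]
    rows = [
        {
            "comparison": "anova",
            "statistic": float(f_stat),
            "p_raw": float(p_anova),
            "p_adj": float(p_anova),
            "method": "one-way ANOVA",
            "stars": stars(float(p_anova)),
        }
    ]
    for (g1, g2), meandiff, p_adj in zip(
        group_pairs, tukey.meandiffs, tukey.pvalues
    ):
        p_adj = float(p_adj)
        rows.append(
            {
                "comparison": f"{g1} vs {g2}",
                "statistic": float(meandiff),
                "p_raw": p_adj,  # Tukey reports family-wise p only
                "p_adj": p_adj,
                "method": "Tukey HSD",
                "stars": stars(p_adj),
            }
        )
    return pd.DataFrame(rows)


def wilcoxon_bonferroni(
    groups: dict[str, np.ndarray], comparisons: list[tuple[str, str]]
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests with Bonferroni correction.

    The Bonferroni multiplier is the number of requested comparisons.  The
    exact null distribution is used for combined n <= 25 without ties;
    otherwise the normal approximation with continuity and tie correction.
    All-tied comparisons get p = 1 and a tie flag.
    """
    for name, values in groups.items():
        if len(np.asarray(values)) == 0:
            raise ValueError(f"group {name!r} is empty")
    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        x, y = np.asarray(groups[a], float), np.asarray(groups[b], float)
        pooled = np.concatenate([x, y])
        all_tied = np.all(pooled == pooled[0])
        has_ties = len(np.unique(pooled)) < pooled.size
        if all_tied:
            u, p, tie = float(len(x) * len(y) / 2), 1.0, True
        else:
            method = "exact" if (pooled.size <= 25 and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            u, p, tie = float(res.statistic), float(res.pvalue), has_ties
        # report the classical rank-sum W of the first group (W = U + n_a(n_a+1)/2)
        w = u + len(x) * (len(x) + 1) / 2
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "statistic": w,
                "p_raw": p,
                "p_adj": p_adj,
                "method": "Wilcoxon rank-sum, Bonferroni",
                "n_a": len(x),
                "n_b": len(y),
                "tied": tie,
                "stars": stars(p_adj),
            }
        )
    return pd.DataFrame(rows)
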