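"""Highly variable gene (HVG) selection.

A gene is called highly variable when it passes a dual criterion computed on
the pre-z-score normalized matrix: (1) its standard deviation across all
samples exceeds an SD cutoff, and (2) the -log10 p-value of a one-way ANOVA
across temperature-condition groups exceeds a significance cutoff.  Cutoffs
can be supplied (e.g. the conventional SD > 1 with -log10 p > 35 for a
deeply replicated shoot compendium, or > 10 for a smaller root set) or
derived from the elbow of the scree plot of each sorted statistic.

The ANOVA runs on raw normalized expression, never on z-scores: z-scoring
equalizes per-gene SD and would destroy the SD criterion.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Smallest positive normal double; p-values below it are clamped and flagged.
_P_FLOOR = np.finfo(float).tiny


class ElbowResult(NamedTuple):
    threshold: float
    index: int
    no_elbow: bool


def anova_scan(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-gene one-way fixed-effects ANOVA across condition groups, plus SD.

    Returns a table with columns ``sd``, ``p_anova``, ``neg_log_p`` and
    ``p_underflow``.  Conditions with fewer than 2 samples are dropped with a
    warning; fewer than 2 usable conditions is an error.  Genes with zero
    variance both within and between groups get p = 1.
    """
    groups_all = metadata.loc[matrix.columns].groupby("condition").groups
    usable = {c: idx for c, idx in groups_all.items() if len(idx) >= 2}
    dropped = sorted(set(groups_all) - set(usable))
    if dropped:
        logger.warning("dropping conditions with <2 samples: %s", dropped)
    if len(usable) < 2:
        raise ValueError("ANOVA needs at least 2 conditions with >=2 samples each")

    arrays = [matrix[list(idx)].to_numpy(dtype=float) for idx in usable.values()]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_res = stats.f_oneway(*arrays, axis=1)
    p = np.asarray(f_res.pvalue, dtype=float)

    # degenerate rows: no variance anywhere -> p = 1 (no evidence of effect)
    pooled = np.concatenate(arrays, axis=1)
    degenerate = pooled.std(axis=1) == 0
    p[degenerate] = 1.0
    p = np.nan_to_num(p, nan=1.0)

    underflow = p < _P_FLOOR
    p = np.clip(p, _P_FLOOR, 1.0)
    sd = matrix.to_numpy(dtype=float).std(axis=1, ddof=1)
    table = pd.DataFrame(
        {
            "sd": sd,
            "p_anova": p,
            "neg_log_p": -np.log10(p),
            "p_underflow": underflow,
        },
        index=matrix.index,
    )
    return table


def elbow_cutoff(values: np.ndarray) -> ElbowResult:
    """Locate the elbow of a descending-sorted scree curve.

    The elbow is the point of maximal perpendicular distance from the chord
    joining the first and last points of the curve (the standard
    parameter-free knee detector).  Ties break to the smallest index.  A
    perfectly linear curve has no elbow; index 0 is returned with
    ``no_elbow=True``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("elbow detection needs at least 3 values")
    if np.any(np.diff(values) > 0):
        raise ValueError("values must be sorted in descending order")
    n = values.size
    x = np.arange(n, dtype=float)
    # distance from (x_i, y_i) to the line through (0, y_0) and (n-1, y_{n-1})
    dx, dy = n - 1.0, values[-1] - values[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * x - dx * (values - values[0])) / norm
    tol = 1e-9 * max(1.0, float(np.ptp(values)))
    if dist.max() <= tol:  # perfectly linear curve: no elbow exists
        return ElbowResult(float(values[0]), 0, True)
    best = int(np.argmax(dist))  # argmax returns the first maximum: smallest index
    return ElbowResult(float(values[best]), best, False)


def select_hvgs(
    table: pd.DataFrame,
    cutoff_sd: float | None = None,
    cutoff_neg_log_p: float | None = None,
) -> pd.DataFrame:
    """Apply the dual strict-inequality filter; derive absent cutoffs by elbow.

    Adds columns ``is_hvg``, ``cutoff_sd`` and ``cutoff_neg_log_p``.  Raising
    either cutoff can only shrink the selection.
    """
    if cutoff_sd is None:
        cutoff_sd = elbow_cutoff(np.sort(table["sd"].to_numpy())[::-1]).threshold
        logger.info("elbow-derived SD cutoff: %.4g", cutoff_sd)
    if cutoff_neg_log_p is None:
        cutoff_neg_log_p = elbow_cutoff(
            np.sort(table["neg_log_p"].to_numpy())[::-1]
        ).threshold
        logger.info("elbow-derived -log10 p cutoff: %.4g", cutoff_neg_log_p)
    if not (np.isfinite(cutoff_sd) and np.isfinite(cutoff_neg_log_p)):
        raise ValueError("cutoffs must be finite")
    out = table.copy()
    out["is_hvg"] = (out["sd"] > cutoff_sd) & (out["neg_log_p"] > cutoff_neg_log_p)
    out["cutoff_sd"] = cutoff_sd
    out["cutoff_neg_log_p"] = cutoff_neg_log_p
    n = int(out["is_hvg"].sum())
    if n == 0:
        logger.warning("cutoffs (SD>%.3g, -log10 p>%.3g) select no genes", cutoff_sd, cutoff_neg_log_p)
    else:
        logger.info("selected %d HVGs of %d genes", n, len(out))
    return out
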