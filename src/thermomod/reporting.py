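"""Bookkeeping arithmetic for cluster sizes and multi-set overlaps.

Small, exact helpers that keep the counts reported alongside figures
honest: cluster sizes must sum to the HVG total, and overlap percentages
are rounded the way they are quoted in text (nearest whole percent).
"""

from __future__ import annotations


def cluster_size_summary(sizes: dict[str, int]) -> dict:
    """Total HVGs and per-cluster fractions from a label -> size mapping."""
    if any(s < 0 for s in sizes.values()):
        raise ValueError("cluster sizes must be non-negative")
    total = sum(sizes.values())
    fractions = {k: (s / total if total else 0.0) for k, s in sizes.items()}
    return {"total": total, "sizes": dict(sizes), "fractions": fractions}


def overlap_percent(overlap: int, set_size: int) -> float:
    """Overlap as a percentage of the set, rounded to the nearest percent."""
    if set_size <= 0:
        raise ValueError("set size must be positive")
    if not 0 <= overlap <= set_size:
        raise ValueError("overlap must lie between 0 and the set size")
    return round(100.0 * overlap / set_size)


def overlap_report(pairs: dict[str, tuple[int, int]]) -> dict[str, float]:
    """Batch form: label -> (overlap, set size) mapped to rounded percentages."""
    return {label: overlap_percent(k, n) for label, (k, n) in pairs.items()}
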