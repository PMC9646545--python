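"""Synthetic temperature-transcriptomics data with planted ground truth.

The generator emulates the statistical structure of an integrated
temperature transcriptome compendium: replicated samples across seven
temperature categories, gene modules with condition-specific mean shifts on
a log-like expression scale, background genes with no condition effect,
per-sample batch offsets, and TF-binding coverage tracks with triangular
peaks planted at the promoters of designated target genes in either one
condition (condition-specific binding) or all conditions (constitutive
binding).

Every output is a pure function of (config, seed): the same config produces
bit-identical matrices, tracks, and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven temperature categories of the integrated compendium, ordered
#: cold-to-hot with post-stress recovery last.
CONDITIONS = (
    "freezing",
    "cold",
    "low_ambient",
    "normal",
    "high_ambient",
    "heat_shock",
    "heat_shock_recovery",
)

#: Planted module activity patterns: condition -> shift multiplier.  Cluster 1
#: is a heat-shock module, cluster 2 a cold/freezing module, cluster 3 an
#: ambient-temperature module, cluster 4 a freezing-suppressed module.
DEFAULT_CLUSTER_PATTERNS = (
    {"heat_shock": 1.0, "heat_shock_recovery": 0.5},
    {"freezing": 1.0, "cold": 1.0},
    {"low_ambient": 1.0, "high_ambient": 1.0},
    {"freezing": -1.0},
)


class ConfigurationError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure simulation.

    Expression values live on a log-like scale (as after RMA or a log of
    normalized counts), so effects and noise are additive.
    """

    n_genes: int = 2000
    cluster_sizes: tuple[int, ...] = (100, 100, 100, 100)
    conditions: tuple[str, ...] = CONDITIONS
    replicates: int = 3
    effect_size: float = 3.0           # mean shift of a module in its active conditions
    noise_sd: float = 0.5              # within-condition SD
    batch_sd: float = 0.3              # per-sample scalar offset SD
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0
    # genome / binding parameters
    genome_length: int = 5_000_000
    n_chromosomes: int = 2
    gene_length: int = 500
    intergenic_spacing: int = 1400     # bp between gene end and next gene start
    close_pair_fraction: float = 0.1   # fraction of genes placed < 2*promoter_halfwidth apart
    promoter_halfwidth: int = 500
    peak_halfwidth: int = 250
    peak_height: float = 10.0          # fold over background coverage
    type_I_height_factor: float = 2.0  # condition-specific peaks vs constitutive ones
    background_coverage: float = 5.0   # mean reads per base off-peak
    binding_conditions: tuple[str, ...] = ("17C", "27C", "37C")
    specific_condition: str = "37C"
    tfs: tuple[str, ...] = ("HSFA1a",)
    bound_fraction: float = 0.5        # fraction of a donor cluster carrying planted binding
    # annotation parameters
    planted_term_fraction: float = 0.8
    background_term_rate: float = 0.02
    n_background_terms: int = 20

    def __post_init__(self):
        if self.n_genes <= 0 or self.replicates <= 0:
            raise ConfigurationError("n_genes and replicates must be positive")
        if any(s <= 0 for s in self.cluster_sizes):
            raise ConfigurationError("cluster sizes must be positive")
        if sum(self.cluster_sizes) > self.n_genes:
            raise ConfigurationError(
                f"planted cluster sizes sum to {sum(self.cluster_sizes)} "
                f"> n_genes={self.n_genes}"
            )
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.specific_condition not in self.binding_conditions:
            raise ConfigurationError("specific_condition must be one of binding_conditions")


@dataclass
class GroundTruth:
    """Planted structure: what the downstream analysis should recover."""

    cluster_of: dict[str, str] = field(default_factory=dict)       # gene -> "cluster_k" | "background"
    binding_type: dict[str, dict[str, str]] = field(default_factory=dict)  # tf -> gene -> type
    term_cluster: dict[str, str] = field(default_factory=dict)     # term -> planted cluster
    specific_condition: str = ""

    def genes_in_cluster(self, label: str) -> list[str]:
        return [g for g, c in self.cluster_of.items() if c == label]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_expression(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a genes x samples expression matrix with planted modules.

    Returns ``(matrix, metadata, truth)``.  Each planted module adds
    ``effect_size`` (times its per-condition multiplier) to its member genes
    in the module's active conditions; background genes carry no condition
    effect.  Gaussian noise and a per-sample scalar batch offset are added
    on top.
    """
    rng = _rng(config, 1)
    genes = _gene_ids(config.n_genes)
    sample_ids, condition_of_sample = [], []
    for cond in config.conditions:
        for r in range(config.replicates):
            sample_ids.append(f"{cond}_r{r + 1}")
            condition_of_sample.append(cond)
    n_samples = len(sample_ids)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    values = np.tile(baseline[:, None], (1, n_samples))

    truth = GroundTruth(specific_condition=config.specific_condition)
    start = 0
    for k, size in enumerate(config.cluster_sizes):
        pattern = DEFAULT_CLUSTER_PATTERNS[k % len(DEFAULT_CLUSTER_PATTERNS)]
        members = genes[start: start + size]
        for g in members:
            truth.cluster_of[g] = f"cluster_{k + 1}"
        shift = np.array([pattern.get(c, 0.0) for c in condition_of_sample])
        values[start: start + size, :] += config.effect_size * shift[None, :]
        start += size
    for g in genes[start:]:
        truth.cluster_of[g] = "background"

    values += rng.normal(0.0, config.noise_sd, size=values.shape)
    values += rng.normal(0.0, config.batch_sd, size=n_samples)[None, :]

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    metadata = pd.DataFrame(
        {
            "condition": condition_of_sample,
            "tissue": "shoot",
            "study": "synthetic",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return matrix, metadata, truth


def _plant_binding_truth(config: SimulationConfig, truth: GroundTruth) -> None:
    """Designate type_I / type_II target genes per TF.

    Condition-specific (type_I) targets are drawn from the heat module
    (cluster_1), constitutive (type_II) targets from the cold module
    (cluster_2), mirroring the condition-specific vs constitutive binding
    contrast the classifier is meant to detect.  Remaining genes are "none".
    """
    all_genes = sorted(truth.cluster_of)
    c1 = truth.genes_in_cluster("cluster_1")
    c2 = truth.genes_in_cluster("cluster_2")
    for tf in config.tfs:
        per_gene = {g: "none" for g in all_genes}
        n1 = max(1, int(round(config.bound_fraction * len(c1)))) if c1 else 0
        n2 = max(1, int(round(config.bound_fraction * len(c2)))) if c2 else 0
        for g in c1[:n1]:
            per_gene[g] = "type_I"
        for g in c2[:n2]:
            per_gene[g] = "type_II"
        truth.binding_type[tf] = per_gene


def simulate_genome_and_binding(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, dict[str, dict[str, dict[str, np.ndarray]]], dict[str, dict[str, pd.DataFrame]]]:
    """Lay genes on a toy genome and plant TF-binding coverage and peaks.

    Returns ``(genes_bed, coverage, peaks)`` where ``coverage[tf][condition]``
    maps chromosome -> per-base array and ``peaks[tf][condition]`` is a BED5
    table.  Coverage is a flat background plus a symmetric triangular bump of
    height ``peak_height * background_coverage`` centred on the TSS of every
    gene bound in that condition; condition-specific bumps are
    ``type_I_height_factor`` times taller.  Peak scores are the bump heights.
    """
    if not truth.binding_type:
        _plant_binding_truth(config, truth)
    rng = _rng(config, 2)
    genes = sorted(truth.cluster_of)
    chrom_len = config.genome_length // config.n_chromosomes
    chrom_sizes = {f"chr{i + 1}": chrom_len for i in range(config.n_chromosomes)}

    # Place genes sequentially; a configurable fraction sit closer than
    # 2*promoter_halfwidth to their neighbour to exercise the meta-profile
    # overlap-exclusion rule downstream.
    rows = []
    chrom_idx, pos = 0, config.promoter_halfwidth + config.peak_halfwidth
    close = rng.random(len(genes)) < config.close_pair_fraction
    strands = np.where(rng.random(len(genes)) < 0.5, "+", "-")
    for i, g in enumerate(genes):
        spacing = (
            config.promoter_halfwidth // 2 if close[i] else config.intergenic_spacing
        )
        if i > 0:
            pos += spacing
        if pos + config.gene_length + config.promoter_halfwidth >= chrom_len:
            chrom_idx += 1
            pos = config.promoter_halfwidth + config.peak_halfwidth
            if chrom_idx >= config.n_chromosomes:
                raise ConfigurationError(
                    "genome too short for requested gene count and spacing"
                )
        rows.append(
            {
                "chrom": f"chr{chrom_idx + 1}",
                "start": pos,
                "end": pos + config.gene_length,
                "gene_id": g,
                "score": 0,
                "strand": strands[i],
            }
        )
        pos += config.gene_length
    genes_bed = pd.DataFrame(rows)

    tss = np.where(
        genes_bed["strand"].to_numpy() == "+",
        genes_bed["start"].to_numpy(),
        genes_bed["end"].to_numpy() - 1,
    )
    gene_chrom = genes_bed["chrom"].to_numpy()
    gene_index = {g: i for i, g in enumerate(genes_bed["gene_id"])}

    hw = config.peak_halfwidth
    triangle = 1.0 - np.abs(np.arange(-hw, hw + 1)) / hw  # peak 1 at centre, 0 at edges

    coverage: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    peaks: dict[str, dict[str, pd.DataFrame]] = {}
    for tf in config.tfs:
        coverage[tf], peaks[tf] = {}, {}
        per_gene = truth.binding_type[tf]
        for cond in config.binding_conditions:
            arrays = {c: np.full(n, config.background_coverage) for c, n in chrom_sizes.items()}
            peak_rows = []
            for g in genes:
                btype = per_gene[g]
                bound = (btype == "type_II") or (
                    btype == "type_I" and cond == config.specific_condition
                )
                if not bound:
                    continue
                factor = config.type_I_height_factor if btype == "type_I" else 1.0
                height = config.peak_height * config.background_coverage * factor
                i = gene_index[g]
                centre = int(tss[i])
                arrays[gene_chrom[i]][centre - hw: centre + hw + 1] += height * triangle
                peak_rows.append(
                    {
                        "chrom": gene_chrom[i],
                        "start": centre - hw,
                        "end": centre + hw + 1,
                        "peak_id": f"{tf}_{cond}_{g}",
                        "score": height,
                    }
                )
            coverage[tf][cond] = arrays
            peaks[tf][cond] = pd.DataFrame(
                peak_rows, columns=["chrom", "start", "end", "peak_id", "score"]
            )
    return genes_bed, coverage, peaks


def simulate_annotation(config: SimulationConfig, truth: GroundTruth) -> tuple[pd.DataFrame, GroundTruth]:
    """Assign functional terms: one planted term per module plus random terms.

    A planted term covers ``planted_term_fraction`` of its module and occurs
    elsewhere at ``background_term_rate``; background terms are assigned at
    random so that a null query recovers nothing.
    """
    rng = _rng(config, 3)
    genes = sorted(truth.cluster_of)
    pairs = []
    clusters = sorted({c for c in truth.cluster_of.values() if c != "background"})
    for c in clusters:
        term = f"TERM_{c}"
        truth.term_cluster[term] = c
        members = truth.genes_in_cluster(c)
        n_in = int(round(config.planted_term_fraction * len(members)))
        for g in members[:n_in]:
            pairs.append((g, term))
        others = [g for g in genes if truth.cluster_of[g] != c]
        hit = rng.random(len(others)) < config.background_term_rate
        for g, h in zip(others, hit):
            if h:
                pairs.append((g, term))
    for t in range(config.n_background_terms):
        term = f"TERM_bg{t:02d}"
        hit = rng.random(len(genes)) < 0.05
        for g, h in zip(genes, hit):
            if h:
                pairs.append((g, term))
    annotation = pd.DataFrame(pairs, columns=["gene_id", "term_id"])
    return annotation, truth


def ground_truth_table(truth: GroundTruth) -> pd.DataFrame:
    """Flatten the ground truth into a per-gene TSV-ready table."""
    genes = sorted(truth.cluster_of)
    table = pd.DataFrame({"gene_id": genes, "cluster": [truth.cluster_of[g] for g in genes]})
    for tf, per_gene in truth.binding_type.items():
        table[f"binding_{tf}"] = [per_gene[g] for g in genes]
    return table
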