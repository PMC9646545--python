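"""Config-driven end-to-end orchestration.

Stages exchange plain-text files (TSV/BED/bedGraph) so each one is
independently runnable; a JSON manifest records package versions, the
config hash, the cutoffs actually applied, and the counts at every stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, binding, clustering, enrichment, expression, hvg, io, simulate

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Config problems detected before any computation."""


@dataclass
class RunConfig:
    expression: str = ""
    metadata: str = ""
    probe_map: str | None = None
    annotation: str | None = None
    genes_bed: str | None = None
    chrom_sizes: str | None = None
    coverage: dict = field(default_factory=dict)   # tf -> condition -> bedGraph path
    peaks: dict = field(default_factory=dict)      # tf -> condition -> BED5 path
    group_by: str | None = None                    # metadata column defining z-score groups
    cutoff_sd: float | None = None
    cutoff_neg_log_p: float | None = None
    auto_elbow: bool = True
    k: int | None = None                           # None -> elbow of within-cluster variance
    enrichment_method: str = "BH"
    window: int = 500
    specific_condition: str = "37C"
    seed: int = 0
    outdir: str = "thermomod_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def validate(self) -> None:
        if not self.expression or not self.metadata:
            raise ValidationError("expression and metadata paths are required")
        paths = [self.expression, self.metadata]
        for p in (self.probe_map, self.annotation, self.genes_bed, self.chrom_sizes):
            if p:
                paths.append(p)
        for tf_map in (self.coverage, self.peaks):
            for cond_map in tf_map.values():
                paths.extend(cond_map.values())
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ValidationError(f"missing input files: {missing}")
        if self.peaks and not self.genes_bed:
            raise ValidationError("peak analysis needs a genes_bed annotation")
        if self.coverage and not self.chrom_sizes:
            raise ValidationError("coverage analysis needs a chrom_sizes table")
        if not self.auto_elbow and (self.cutoff_sd is None or self.cutoff_neg_log_p is None):
            raise ValidationError("fixed cutoffs requested but not both provided")


def _read_chrom_sizes(path) -> dict[str, int]:
    table = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(table["chrom"], table["length"].astype(int)))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "thermomod_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config_hash": config.digest(),
        "seed": config.seed,
        "counts": {},
        "warnings": 0,
        "stages": [],
    }
    config.to_yaml(outdir / "config.yaml")

    counter = _WarningCounter()
    logging.getLogger("thermomod").addHandler(counter)
    try:
        # --- expression_core ---
        matrix, metadata = expression.read_expression(config.expression, config.metadata)
        if config.probe_map:
            probe_map = pd.read_csv(config.probe_map, sep="\t", dtype=str)
            matrix = expression.collapse_probes(matrix, probe_map)
        manifest["counts"]["genes"] = int(matrix.shape[0])
        manifest["counts"]["samples"] = int(matrix.shape[1])
        manifest["stages"].append("expression_core")

        # --- hvg_selection ---
        table = hvg.anova_scan(matrix, metadata)
        table = hvg.select_hvgs(
            table,
            cutoff_sd=config.cutoff_sd,
            cutoff_neg_log_p=config.cutoff_neg_log_p,
        )
        table.to_csv(outdir / "hvg_table.tsv", sep="\t", index_label="gene_id")
        hvgs = table.index[table["is_hvg"]].tolist()
        manifest["counts"]["hvgs"] = len(hvgs)
        manifest["cutoffs"] = {
            "sd": float(table["cutoff_sd"].iloc[0]),
            "neg_log_p": float(table["cutoff_neg_log_p"].iloc[0]),
        }
        manifest["stages"].append("hvg_selection")
        if not hvgs:
            raise RuntimeError("hvg_selection selected no genes; cannot cluster")

        # --- clustering_stats ---
        group_by = metadata[config.group_by] if config.group_by else None
        norm = expression.zscore_rows(matrix.loc[hvgs], group_by=group_by).values
        k = config.k if config.k is not None else clustering.choose_k_elbow(norm)
        assignment = clustering.ward_cluster(norm, k, metadata)
        assignment.labels.to_csv(outdir / "clusters.tsv", sep="\t", index_label="gene_id")
        assignment.condition_means.to_csv(outdir / "cluster_condition_means.tsv", sep="\t")
        norm.loc[assignment.leaf_order].to_csv(
            outdir / "heatmap_matrix.tsv", sep="\t", index_label="gene_id"
        )
        manifest["counts"]["clusters"] = int(k)
        manifest["k_selection"] = "configured" if config.k is not None else "elbow"
        manifest["counts"]["cluster_sizes"] = {
            str(c): int(s) for c, s in assignment.sizes().items()
        }
        manifest["stages"].append("clustering_stats")

        # --- enrichment ---
        if config.annotation:
            annotation = io.read_annotation_tsv(config.annotation)
            background = set(matrix.index)
            for c in range(1, k + 1):
                res = enrichment.fisher_enrich(
                    assignment.genes(c), annotation, background,
                    method=config.enrichment_method,
                )
                res.to_csv(outdir / f"enrichment_cluster_{c}.tsv", sep="\t", index=False)
            manifest["stages"].append("enrichment")

        # --- binding_analysis ---
        if config.peaks:
            genes_bed = binding.add_tss(io.read_bed6(config.genes_bed))
            chrom_sizes = (
                _read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
            )
            classifications = {}
            for tf, cond_paths in config.peaks.items():
                targets = {}
                target_rows = []
                for cond, path in cond_paths.items():
                    assigned = binding.assign_peaks(
                        io.read_bed5(path), genes_bed, window=config.window
                    )
                    targets[cond] = set(assigned["gene_id"])
                    assigned.insert(0, "condition", cond)
                    assigned.insert(0, "tf", tf)
                    target_rows.append(assigned)
                pd.concat(target_rows, ignore_index=True).to_csv(
                    outdir / f"targets_{tf}.tsv", sep="\t", index=False
                )
                cls = binding.classify_binding(
                    targets, config.specific_condition, universe=matrix.index
                )
                cls.to_csv(outdir / f"binding_class_{tf}.tsv", sep="\t",
                           index_label="gene_id")
                classifications[tf] = cls
                contingency = binding.binding_class_table(cls, assignment.labels)
                if contingency.shape[0] >= 2 and contingency.shape[1] >= 2:
                    chisq = enrichment.chisq_class_enrichment(contingency)
                    manifest.setdefault("chisq", {})[tf] = {
                        "statistic": chisq.statistic, "p": chisq.p, "dof": chisq.dof,
                    }
                if chrom_sizes and tf in config.coverage:
                    for cond, cov_path in config.coverage[tf].items():
                        track = binding.normalize_coverage(
                            binding.CoverageTrack(io.read_bedgraph(cov_path, chrom_sizes))
                        )
                        profiles = []
                        for c in range(1, k + 1):
                            members = [
                                g for g in assignment.genes(c)
                                if g in set(genes_bed["gene_id"])
                            ]
                            if not members:
                                continue
                            try:
                                prof = binding.meta_profile(
                                    track, genes_bed, members, window=config.window
                                )
                            except ValueError:
                                continue
                            profiles.append(pd.DataFrame({
                                "cluster": c, "offset": prof.offsets,
                                "mean_occupancy": prof.mean, "n_genes": prof.n_genes,
                            }))
                        if profiles:
                            pd.concat(profiles, ignore_index=True).to_csv(
                                outdir / f"metaprofile_{tf}_{cond}.tsv",
                                sep="\t", index=False,
                            )
            manifest["counts"]["binding_classes"] = {
                tf: {k_: int(v) for k_, v in cls.value_counts().items()}
                for tf, cls in classifications.items()
            }
            manifest["stages"].append("binding_analysis")
    except (ValidationError, ValueError, KeyError, RuntimeError) as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "input validation"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc
    finally:
        logging.getLogger("thermomod").removeHandler(counter)

    manifest["warnings"] = counter.count
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


def make_demo(outdir, seed: int = 0, config: simulate.SimulationConfig | None = None) -> RunConfig:
    """Write a self-contained synthetic dataset plus a ready-to-run config.

    Defaults: ~2000 genes with four planted modules of 100, seven
    temperature conditions x 3 replicates, and two TFs assayed in three
    binding conditions.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = simulate.SimulationConfig(seed=seed, tfs=("TF_heat", "TF_cold"))
    matrix, metadata, truth = simulate.simulate_expression(config)
    genes_bed, coverage, peaks = simulate.simulate_genome_and_binding(config, truth)
    annotation, truth = simulate.simulate_annotation(config, truth)

    io.write_expression_tsv(matrix, outdir / "expression.tsv")
    io.write_metadata_tsv(metadata, outdir / "metadata.tsv")
    io.write_bed6(genes_bed, outdir / "genes.bed")
    io.write_annotation_tsv(annotation, outdir / "annotation.tsv")
    simulate.ground_truth_table(truth).to_csv(
        outdir / "ground_truth.tsv", sep="\t", index=False
    )
    chrom_len = config.genome_length // config.n_chromosomes
    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for i in range(config.n_chromosomes):
            fh.write(f"chr{i + 1}\t{chrom_len}\n")

    cov_paths: dict = {}
    peak_paths: dict = {}
    for tf in config.tfs:
        cov_paths[tf], peak_paths[tf] = {}, {}
        for cond in config.binding_conditions:
            cov_path = outdir / f"coverage_{tf}_{cond}.bedGraph"
            io.write_bedgraph(coverage[tf][cond], cov_path)
            peak_path = outdir / f"peaks_{tf}_{cond}.bed"
            io.write_bed5(peaks[tf][cond], peak_path)
            cov_paths[tf][cond] = str(cov_path)
            peak_paths[tf][cond] = str(peak_path)

    run = RunConfig(
        expression=str(outdir / "expression.tsv"),
        metadata=str(outdir / "metadata.tsv"),
        annotation=str(outdir / "annotation.tsv"),
        genes_bed=str(outdir / "genes.bed"),
        chrom_sizes=str(outdir / "chrom_sizes.tsv"),
        coverage=cov_paths,
        peaks=peak_paths,
        cutoff_sd=None,
        cutoff_neg_log_p=None,
        auto_elbow=True,
        k=len(config.cluster_sizes),
        specific_condition=config.specific_condition,
        seed=seed,
        outdir=str(outdir / "results"),
    )
    run.to_yaml(outdir / "run_config.yaml")
    return run
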