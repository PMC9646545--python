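"""Generate a synthetic temperature-transcriptome dataset with planted structure.

Four gene modules respond to distinct temperature regimes (heat shock,
cold/freezing, ambient, freezing-suppressed); the rest of the genome is
background.  The ground truth returned alongside is what the downstream
analysis is expected to recover.
"""

from thermomod.simulate import SimulationConfig, simulate_expression

config = SimulationConfig(seed=0, n_genes=1000, cluster_sizes=(50, 50, 50, 50))
matrix, metadata, truth = simulate_expression(config)

print(f"expression matrix: {matrix.shape[0]} genes x {matrix.shape[1]} samples")
print(f"conditions: {', '.join(metadata['condition'].unique())}")

sizes = {}
for cluster in sorted(set(truth.cluster_of.values())):
    sizes[cluster] = len(truth.genes_in_cluster(cluster))
print(f"planted modules: {sizes}")

heat = truth.genes_in_cluster("cluster_1")
heat_cols = metadata.index[metadata["condition"] == "heat_shock"]
normal_cols = metadata.index[metadata["condition"] == "normal"]
shift = matrix.loc[heat, heat_cols].mean().mean() - matrix.loc[heat, normal_cols].mean().mean()
print(f"heat module: mean heat-shock vs normal shift = {shift:.2f} log-units "
      f"(planted effect size {config.effect_size})")
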