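"""Cluster z-scored HVG profiles into temperature-response modules.

Ward's minimum-variance linkage on Euclidean distances between per-gene
z-score profiles, cut into k flat clusters; each cluster's mean z-score per
condition summarizes its temperature response.  Tukey's HSD then tests
which condition pairs differ for a module of interest.
"""

from thermomod.clustering import anova_tukey, ward_cluster
from thermomod.expression import zscore_rows
from thermomod.hvg import anova_scan, select_hvgs
from thermomod.simulate import SimulationConfig, simulate_expression

config = SimulationConfig(seed=0)
matrix, metadata, truth = simulate_expression(config)
table = select_hvgs(anova_scan(matrix, metadata))
hvgs = table.index[table["is_hvg"]].tolist()

norm = zscore_rows(matrix.loc[hvgs]).values
assignment = ward_cluster(norm, k=4, metadata=metadata)
print(f"cluster sizes (largest first): {assignment.sizes().to_dict()}")
print("mean z-score per condition (rows = clusters):")
print(assignment.condition_means.round(2).to_string())

heat_cluster = max(
    range(1, 5), key=lambda c: assignment.condition_means.loc[c, "heat_shock"]
)
results = anova_tukey(norm, metadata, assignment.genes(heat_cluster))
contrast = results[results["comparison"].str.contains("heat_shock") &
                   results["comparison"].str.contains("normal")].iloc[0]
print(f"heat module (cluster {heat_cluster}), heat_shock vs normal: "
      f"Tukey adjusted p = {contrast['p_adj']:.2e} {contrast['stars']} "
      f"(mean z difference {contrast['statistic']:.2f})")
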