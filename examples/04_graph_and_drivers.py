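"""Velocity graph, embedding arrows, and driver-gene ranking.

Builds the cell-to-cell velocity graph on confidence-filtered genes,
projects velocities as 2-D arrows onto an embedding, and ranks genes by
positive correlation with pseudotime.
"""

import numpy as np

import velogcn as vg
from velogcn.evaluate import continuity_scores

ds, truth = vg.simulate_population(300, 20, 2, noise_sd=0.1, seed=3)
ds, graph = vg.preprocess(
    ds, vg.PreprocessConfig(n_top_genes=20, n_pcs=20, k_neighbors=30, normalize_target="none")
)
state, _ = vg.train(ds, graph, vg.ModelConfig(seed=3), vg.ObjectiveConfig(epochs=100), seed=3)
velocity = vg.compute_velocity(vg.forward_rates(ds, graph, state), ds)

# confidence filter: continuity score, correlation score, u~s regression residual
targets = vg.candidate_target_probabilities(ds, graph, velocity, "forward")
cont = continuity_scores(ds, velocity, targets)
corr = vg.correlation_score(velocity, ds)
genes_used = vg.gene_confidence_filter(ds, cont, corr, vg.GeneFilterConfig())
print(f"confidence filter kept {genes_used.size}/{ds.n_genes} genes")

vgraph = vg.velocity_graph(ds, velocity, graph, genes_used)
print(f"velocity graph: {vgraph.weights.nnz} edges, weights in "
      f"[{vgraph.weights.data.min():.2f}, {vgraph.weights.data.max():.2f}]")

# project onto the first two PCs as a stand-in embedding
embedding = ds.pca[:, :2]
arrows = vg.project_velocity(vgraph, embedding, sigma=0.05)
print(f"embedding arrows: mean norm {np.linalg.norm(arrows, axis=1).mean():.3f}")

drivers = vg.rank_driver_genes(ds, top_n=5)
print("top driver genes by pseudotime correlation:")
print(drivers.to_string(index=False))
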